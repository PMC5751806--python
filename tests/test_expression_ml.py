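import numpy as np
import pandas as pd
import pytest

from ale.errors import ExpressionError
from ale.expression_ml import (
    ExpressionMatrix,
    MLConfig,
    TrainedModel,
    anova_f,
    collapse_probes,
    combine_labels,
    dummy_baseline,
    knn_impute,
    maybe_log_transform,
    normalize_chain,
    predict,
    quantile_normalize,
    select_features,
    train,
)
from ale.synthetic import ExpressionSpec, gen_expression


def make_matrix(values, features=None, samples=None, series=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    series = series or {s: f"e{i % 2}" for i, s in enumerate(samples)}
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), pd.Series(series)
    )


# probe collapse -------------------------------------------------------------

def test_collapse_probes_argmax_and_ties():
    m = make_matrix(
        [[3.0, 3.2], [5.0, 5.0], [2.0, 2.0], [2.0, 2.0]],
        features=["pA", "pB", "pD", "pC"],
    )
    pmap = {"pA": "G1", "pB": "G1", "pC": "G2", "pD": "G2"}
    out = collapse_probes(m, pmap)
    assert list(out.data.index) == ["G1", "G2"]
    assert out.data.loc["G1"].tolist() == [5.0, 5.0]  # higher mean probe wins
    assert out.data.loc["G2"].tolist() == [2.0, 2.0]  # tie -> smaller probe id (pC)
    # identity when one probe per gene
    one = collapse_probes(m, {"pA": "GA", "pB": "GB", "pC": "GC", "pD": "GD"})
    assert one.data.shape == m.data.shape
    with pytest.raises(ExpressionError):
        collapse_probes(m, {"none": "G"})


def test_collapse_probes_equals_bruteforce_oracle():
    rng = np.random.default_rng(3)
    probes = [f"p{i:02d}" for i in range(12)]
    genes = [f"G{i}" for i in rng.integers(0, 3, size=12)]
    pmap = dict(zip(probes, genes))
    m = make_matrix(rng.normal(7, 1, size=(12, 5)), features=probes)
    out = collapse_probes(m, pmap)
    for gene in sorted(set(genes)):
        cands = [p for p in probes if pmap[p] == gene]
        best = min(cands, key=lambda p: (-m.data.loc[p].mean(), p))
        assert np.array_equal(out.data.loc[gene].to_numpy(), m.data.loc[best].to_numpy())


# quantile normalization -----------------------------------------------------

def test_quantile_normalize_hand_example():
    m = make_matrix([[1, 4], [2, 5], [3, 6]])
    out = quantile_normalize(m).data.to_numpy()
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    assert np.allclose(out, expected)


def test_quantile_normalize_ties_get_mean_reference():
    # col0 has a tie at value 1 occupying ranks 1-2; reference = [1.5, 2.5, 4]
    m = make_matrix([[1, 2], [1, 5], [3, 4]])
    out = quantile_normalize(m).data.to_numpy()
    assert np.allclose(out[:, 0], [2.0, 2.0, 4.0])
    assert np.allclose(out[:, 1], [1.5, 4.0, 2.5])


def test_quantile_normalize_invariants():
    rng = np.random.default_rng(0)
    m = make_matrix(rng.normal(7, 2, size=(50, 8)))
    out = quantile_normalize(m).data.to_numpy()
    sorted_cols = np.sort(out, axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-9)
    identical = make_matrix(np.tile(rng.normal(7, 1, size=(20, 1)), (1, 4)))
    assert np.allclose(quantile_normalize(identical).data, identical.data)


def test_quantile_normalize_single_sample_is_identity():
    m = make_matrix([[1.0], [5.0]], series={"s0": "e0"})
    assert np.allclose(quantile_normalize(m).data, m.data)


# knn imputation -------------------------------------------------------------

def test_knn_impute_identity_without_missing():
    m = make_matrix([[1, 2], [3, 4]])
    assert np.allclose(knn_impute(m, 5).data, m.data)


def test_knn_impute_hand_toy():
    # samples s0=[1,1,1], s1=[2,2,2], s2=[10,10,NaN]; the 2 nearest samples
    # to s2 over observed genes are s0 and s1 -> imputed value mean(1,2)=1.5
    m = make_matrix([[1, 2, 10], [1, 2, 10], [1, 2, np.nan]])
    out = knn_impute(m, 2)
    assert out.data.loc["g2", "s2"] == pytest.approx(1.5)
    # degenerate k >= n_samples-1: mean of all other samples observing g2
    out_big = knn_impute(m, 50)
    assert out_big.data.loc["g2", "s2"] == pytest.approx(1.5)


def test_knn_impute_drops_all_missing_gene(caplog):
    m = make_matrix([[1, 2, 3], [np.nan, np.nan, np.nan], [4, np.nan, 6]])
    out = knn_impute(m, 1)
    assert list(out.data.index) == ["g0", "g2"]
    assert not np.isnan(out.data.to_numpy()).any()


# feature selection ----------------------------------------------------------

def test_anova_f_matches_closed_form():
    # gene g0: classes a=[1,2], b=[5,7]
    # between MS = 20.25, within MS = 1.25 -> F = 16.2 (= pooled t squared)
    m = make_matrix([[1, 2, 5, 7]], samples=["s0", "s1", "s2", "s3"])
    labels = pd.Series({"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
    f = anova_f(m, labels)
    assert f["g0"] == pytest.approx(16.2)
    t = (6.0 - 1.5) / np.sqrt(1.25 * (1 / 2 + 1 / 2))
    assert f["g0"] == pytest.approx(t**2)


def test_select_features_variance_filter_and_ranking():
    rng = np.random.default_rng(1)
    noise = rng.normal(0, 1, size=8)
    m = make_matrix(
        [
            [0, 0, 0, 0, 1, 1, 1, 1],  # perfect separator
            noise,  # pure noise
            [3] * 8,  # constant: removed by the variance filter
        ],
        features=["sep", "noise", "const"],
        samples=[f"s{i}" for i in range(8)],
    )
    labels = pd.Series({f"s{i}": "a" if i < 4 else "b" for i in range(8)})
    cfg = MLConfig(n_features=2, min_class_size=1)
    selected = select_features(m, labels, cfg)
    assert selected[0] == "sep"
    assert "const" not in selected
    # fewer survivors than requested -> all survivors returned
    assert select_features(m, labels, MLConfig(n_features=10, min_class_size=1)) == ["sep", "noise"]


def test_select_features_tie_break_prefers_smaller_id():
    m = make_matrix(
        [[0, 0, 1, 1], [0, 0, 1, 1]], features=["gB", "gA"], samples=list("wxyz")
    )
    labels = pd.Series(dict(zip("wxyz", "aabb")))
    assert select_features(m, labels, MLConfig(n_features=1, min_class_size=1)) == ["gA"]


def test_selected_genes_recover_planted_informative_genes():
    ds = gen_expression(ExpressionSpec(n_genes=400, n_samples=120, n_series=6, seed=5))
    planted = {g for genes in ds.informative_genes.values() for g in genes}
    mat = normalize_chain(ds.matrix)
    selected = set(select_features(mat, ds.labels, MLConfig(n_features=100)))
    assert len(selected & planted) >= len(planted) / 2


# training and prediction ----------------------------------------------------

@pytest.fixture()
def separable():
    rng = np.random.default_rng(2)
    n = 40
    X = rng.normal(7, 0.5, size=(30, n))
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    X[0, y == "b"] += 5.0
    samples = [f"s{i}" for i in range(n)]
    m = make_matrix(X, samples=samples)
    return m, pd.Series(y, index=samples)


def test_train_predict_separable(separable):
    m, y = separable
    cfg = MLConfig(n_features=5, min_class_size=2, seed=0)
    model = train(m, y, "sex", cfg)
    probs, pred = predict(model, m)
    assert (pred == y).all()
    assert (probs.max(axis=1) > 0.5).all()
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_train_determinism_and_order_invariance(separable):
    m, y = separable
    cfg = MLConfig(n_features=5, min_class_size=2, seed=0)
    model1 = train(m, y, "sex", cfg)
    model2 = train(m, y, "sex", cfg)
    assert np.array_equal(model1.coef, model2.coef)
    perm = np.random.default_rng(4).permutation(len(y))
    shuffled = m.copy_with(m.data.iloc[:, perm])
    model3 = train(shuffled, y.iloc[perm], "sex", cfg)
    _, p_orig = predict(model1, m)
    _, p_perm = predict(model3, m)
    assert (p_orig == p_perm).all()


def test_predict_midpoint_probability_half():
    # symmetric 2-class toy: a sample exactly between the class centroids
    m = make_matrix([[0, 0, 4, 4]], samples=["a1", "a2", "b1", "b2"])
    y = pd.Series({"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
    model = train(m, y, "sex", MLConfig(n_features=1, min_class_size=1))
    mid = make_matrix([[2.0]], features=["g0"], samples=["mid"], series={"mid": "e"})
    probs, _ = predict(model, mid)
    assert probs.loc["mid", "a"] == pytest.approx(0.5, abs=1e-3)


def test_train_input_validation(separable):
    m, y = separable
    with pytest.raises(ExpressionError, match="age"):
        train(m, y, "age", MLConfig(min_class_size=2))
    with pytest.raises(ExpressionError):
        train(m, pd.Series("a", index=y.index), "sex", MLConfig(min_class_size=2))
    with pytest.raises(ExpressionError, match="floor"):
        train(m, y, "sex", MLConfig(min_class_size=100))


def test_predict_missing_genes_named_error(separable):
    m, y = separable
    model = train(m, y, "sex", MLConfig(n_features=5, min_class_size=2))
    dropped = m.copy_with(m.data.drop(index=model.selected_genes[0]))
    with pytest.raises(ExpressionError, match=model.selected_genes[0]):
        predict(model, dropped)


def test_model_json_round_trip(separable, tmp_path):
    m, y = separable
    model = train(m, y, "sex", MLConfig(n_features=5, min_class_size=2))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = TrainedModel.load(path)
    assert loaded.classes == model.classes
    assert loaded.selected_genes == model.selected_genes
    assert np.allclose(loaded.coef, model.coef)
    p1, _ = predict(model, m)
    p2, _ = predict(loaded, m)
    assert np.allclose(p1.to_numpy(), p2.to_numpy())


# chain ----------------------------------------------------------------------

def test_maybe_log_transform_heuristic():
    linear = make_matrix([[100.0, 2000.0], [1.0, 3.0]])
    assert maybe_log_transform(linear).data.max().max() < 30
    logged = make_matrix([[7.0, 8.0], [6.0, 5.0]])
    assert np.allclose(maybe_log_transform(logged).data, logged.data)


def test_chain_idempotent_on_clean_data():
    ds = gen_expression(
        ExpressionSpec(n_genes=200, n_samples=40, n_series=4, missing_rate=0.0, seed=6)
    )
    once = normalize_chain(ds.matrix)
    twice = normalize_chain(once)
    assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-9)


# dummy baseline and label combination ---------------------------------------

def test_dummy_baseline_behaviour():
    one_class = dummy_baseline(pd.Series(["x"] * 5), seed=0)
    m = make_matrix(np.zeros((2, 10)))
    assert (one_class.predict(m) == "x").all()
    rng = np.random.default_rng(8)
    y = pd.Series(rng.choice(["a", "b"], size=2000))
    big = ExpressionMatrix(
        pd.DataFrame(np.zeros((1, 2000)), columns=[f"s{i}" for i in range(2000)]),
        pd.Series({f"s{i}": "e" for i in range(2000)}),
    )
    dummy = dummy_baseline(y.set_axis(big.sample_ids), seed=1)
    acc = (dummy.predict(big).to_numpy() == y.to_numpy()).mean()
    assert 0.45 < acc < 0.55


@pytest.mark.parametrize(
    "text, ml, thr, expected",
    [
        ("male", ("female", 0.99), 0.5, "male"),  # text always wins
        (None, ("liver", 0.8), 0.5, ("liver", 0.8)),
        (None, ("liver", 0.4), 0.5, None),
        (None, None, 0.5, None),
    ],
)
def test_combine_labels(text, ml, thr, expected):
    assert combine_labels(text, ml, thr) == expected
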