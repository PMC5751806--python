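"""Synthetic fixtures: metadata corpora, toy ontologies, expression matrices.

Everything the pipeline consumes can be generated here with known ground
truth, so the whole system is testable without downloading a byte of GEO.
Three generators:

* :func:`gen_toy_ontology` — a rooted DAG of pseudo-word terms (with
  occasional diamonds and synonyms), serialized as valid OBO.
* :func:`gen_metadata` — sample records whose free text encodes sex, age
  and tissue labels at configurable rates, using a versioned template
  inventory shared with the extractors' pattern vocabulary.  Two template
  families ("implicit" parentheticals and misspelled units) are adversarial:
  the precision-first extractors must NOT fire on them, which guards
  against the generator and the extractor overfitting to each other.
* :func:`gen_expression` — log-scale Gaussian intensities with
  class-informative genes, per-series random intercepts (so experiment
  stratification matters) and missing values.

Default rates follow what large-scale GEO curation reports: ~86% of samples
carry tissue information in their text but only ~26% sex and ~21% age, and
human gold-standard ages average ~47 (SD ~22) years.

All generators are deterministic functions of their spec's ``seed``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .expression_ml import ExpressionMatrix
from .metadata_model import SampleMetadata, serialize_characteristics
from .text_labels import UNIT_TO_YEARS
from .tissue_ontology import OntologyGraph, load_obo

# pseudo-word syllables for ontology term names: distinctive, never English,
# so planted ontology words cannot collide with filler text
_SYLLABLES = ["zor", "vek", "quu", "lom", "bax", "nir", "tev", "gos", "pya", "dru", "wif", "kel"]

_FILLER = [
    "cells", "treated", "control", "baseline", "profile", "expression",
    "cohort", "replicate", "untreated", "vehicle", "timepoint", "biological",
    "total", "sorted", "cultured", "primary", "passage", "stimulated",
]

_UNIT_ABBR = {"years": "y", "months": "mo", "weeks": "wk", "days": "d"}
_UNIT_TYPO = {"years": "yaers", "months": "monhts", "weeks": "weekss", "days": "dyas"}


# ---------------------------------------------------------------------------
# toy ontology

@dataclass
class ToyOntology:
    graph: OntologyGraph
    obo_text: str
    depths: dict[str, int]  # generator's own depth bookkeeping
    synonyms: dict[str, list[str]]


def _pseudo_word(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        word = "".join(rng.choice(_SYLLABLES, size=3))
        if word not in used:
            used.add(word)
            return word


def gen_toy_ontology(
    n_terms: int = 30,
    n_synonyms: int = 1,
    diamond_prob: float = 0.2,
    seed: int = 0,
) -> ToyOntology:
    """Generate a rooted DAG with unique pseudo-word names and synonyms.

    Term i > 0 gets one uniformly chosen earlier term as its primary parent;
    with probability *diamond_prob* a second, distinct earlier parent is
    added, creating diamonds.  Depths are tracked independently of the
    ontology code (min over parents + 1), so loaders can be checked against
    the generator's own bookkeeping.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    ids = [f"BTO:{i:07d}" for i in range(n_terms)]
    names = [_pseudo_word(rng, used) for _ in range(n_terms)]
    synonyms = {
        ids[i]: [_pseudo_word(rng, used) for _ in range(n_synonyms)]
        for i in range(n_terms)
    }
    parents: dict[str, list[str]] = {ids[0]: []}
    depths: dict[str, int] = {ids[0]: 0}
    for i in range(1, n_terms):
        first = int(rng.integers(0, i))
        plist = [ids[first]]
        if i >= 2 and rng.random() < diamond_prob:
            second = int(rng.integers(0, i))
            if second != first:
                plist.append(ids[second])
        parents[ids[i]] = plist
        depths[ids[i]] = min(depths[p] for p in plist) + 1
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: toy-tissue\n")
    for i, tid in enumerate(ids):
        buf.write(f"\n[Term]\nid: {tid}\nname: {names[i]}\n")
        for syn in synonyms[tid]:
            buf.write(f'synonym: "{syn}" RELATED []\n')
        for p in parents[tid]:
            buf.write(f"is_a: {p}\n")
    obo_text = buf.getvalue()
    graph = load_obo(io.StringIO(obo_text))
    return ToyOntology(graph=graph, obo_text=obo_text, depths=depths, synonyms=synonyms)


# ---------------------------------------------------------------------------
# metadata corpus

@dataclass
class CorpusSpec:
    """What the metadata generator plants, and how often.

    ``label_presence`` is the fraction of samples whose TEXT encodes each
    label (every sample always has a latent true label); the defaults are
    the rates observed across GEO.  ``phrasing_weights`` picks the template
    family used when a label is encoded.
    """

    n_samples: int = 500
    n_series: int = 25
    label_presence: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.26, "age": 0.21, "tissue": 0.86}
    )
    phrasing_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sex": {"explicit": 0.50, "abbreviated": 0.25, "numeric": 0.15, "implicit": 0.10},
            "age": {"explicit": 0.50, "abbreviated": 0.15, "unit_in_key": 0.20,
                    "misspelled": 0.10, "implicit": 0.05},
            "tissue": {"explicit": 0.50, "synonym": 0.25, "source": 0.25},
        }
    )
    age_mean_years: float = 46.7
    age_sd_years: float = 21.6
    organism: str = "Homo sapiens"
    seed: int = 0

    def __post_init__(self) -> None:
        for lt, frac in self.label_presence.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"label_presence[{lt!r}] must be in [0,1]")


@dataclass(frozen=True)
class Template:
    label_type: str
    family: str
    field: str  # characteristics | description | source_name | title
    key: str
    template: str
    extractable: bool


def load_templates() -> list[Template]:
    text = resources.files("ale").joinpath("data/templates.tsv").read_text(encoding="utf-8")
    out = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.append(
            Template(
                label_type=row["label_type"],
                family=row["family"],
                field=row["field"],
                key=row["key"],
                template=row["template"],
                extractable=row["extractable"] == "1",
            )
        )
    return out


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def _render(template: Template, ctx: dict[str, str]) -> str:
    return template.template.format(**ctx)


def gen_metadata(
    spec: CorpusSpec, ontology: ToyOntology | None = None
) -> tuple[list[SampleMetadata], pd.DataFrame]:
    """Generate a metadata corpus plus its ground-truth table.

    The truth table has one row per (sample, label type) with the true
    value (sex category / age in years / tissue term id), whether and where
    the text encodes it, the template family used, and whether that family
    is one the extractors are expected to parse (``extractable``).
    """
    rng = np.random.default_rng(spec.seed)
    if ontology is None:
        ontology = gen_toy_ontology(seed=spec.seed + 1)
    templates = load_templates()
    by_type_family: dict[tuple[str, str], list[Template]] = {}
    for t in templates:
        by_type_family.setdefault((t.label_type, t.family), []).append(t)
    term_ids = sorted(ontology.graph.terms)
    records: list[SampleMetadata] = []
    truth_rows: list[dict[str, object]] = []
    unit_names = list(UNIT_TO_YEARS)
    unit_weights = np.array([0.6, 0.2, 0.1, 0.1])
    for i in range(spec.n_samples):
        sample_id = f"GSM{100000 + i}"
        series_idx = i * spec.n_series // spec.n_samples
        series_id = f"GSE{1000 + series_idx}"
        sex = "male" if rng.random() < 0.5 else "female"
        age_years = float(np.clip(rng.normal(spec.age_mean_years, spec.age_sd_years), 0.0, 95.0))
        tissue = term_ids[int(rng.integers(0, len(term_ids)))]
        unit = str(rng.choice(unit_names, p=unit_weights))
        # rendered numbers are rounded; the truth records what was written
        age_in_unit = round(age_years / UNIT_TO_YEARS[unit], 1)
        ctx = {
            "sex": sex,
            "sex_abbr": "M" if sex == "male" else "F",
            "sex_01": "1" if sex == "male" else "0",
            "age_value": _format_number(age_in_unit),
            "age_int": str(int(round(age_years))),
            "age_unit": unit,
            "age_unit_abbr": _UNIT_ABBR[unit],
            "age_unit_typo": _UNIT_TYPO[unit],
            "tissue_name": ontology.graph.terms[tissue].name,
            "tissue_synonym": (ontology.synonyms[tissue] or [ontology.graph.terms[tissue].name])[0],
        }
        pairs: list[tuple[str, str]] = []
        description_parts = [f"Total RNA profile, replicate {i % 3 + 1}."]
        source_parts: list[str] = []
        title_parts = [f"Sample {i}", str(rng.choice(_FILLER)), str(rng.choice(_FILLER))]
        truth_age = age_years
        for label_type in ("sex", "age", "tissue"):
            encoded = bool(rng.random() < spec.label_presence[label_type])
            family = ""
            field_used = ""
            extractable = False
            if encoded:
                weights = spec.phrasing_weights[label_type]
                families = list(weights)
                probs = np.array([weights[f] for f in families], dtype=float)
                family = str(rng.choice(families, p=probs / probs.sum()))
                options = by_type_family[(label_type, family)]
                tpl = options[int(rng.integers(0, len(options)))]
                rendered = _render(tpl, ctx)
                key_rendered = tpl.key.format(**ctx)
                field_used = tpl.field
                extractable = tpl.extractable
                if tpl.field == "characteristics":
                    pairs.append((key_rendered, rendered))
                elif tpl.field == "description":
                    description_parts.append(rendered)
                elif tpl.field == "source_name":
                    source_parts.append(rendered)
                elif tpl.field == "title":
                    title_parts.append(rendered)
            if label_type == "age":
                if encoded and family in {"explicit", "unit_in_key", "misspelled"}:
                    truth_age = age_in_unit * UNIT_TO_YEARS[unit]
                elif encoded and family in {"abbreviated", "implicit"}:
                    truth_age = float(int(round(age_years)))
                truth_value: object = truth_age
            elif label_type == "sex":
                truth_value = sex
            else:
                truth_value = tissue
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "series_id": series_id,
                    "label_type": label_type,
                    "value": truth_value,
                    "encoded": encoded,
                    "family": family,
                    "field": field_used,
                    "extractable": extractable,
                }
            )
        if rng.random() < 0.5:
            pairs.append(("protocol", str(rng.choice(_FILLER))))
        records.append(
            SampleMetadata(
                sample_id=sample_id,
                series_id=series_id,
                platform_id="GPL96",
                organism=spec.organism,
                molecule="total RNA",
                title=" ".join(title_parts),
                description=" ".join(description_parts),
                source_name={1: " ".join(source_parts) if source_parts else "cultured material"},
                characteristics_raw={1: serialize_characteristics(pairs)},
            )
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# expression matrices with planted labels

@dataclass
class ExpressionSpec:
    """Gaussian log-intensity generator with class-informative genes.

    Baseline intensities are N(7, ``noise_sd``) on the log2 scale; the
    ``n_informative`` genes are split round-robin across classes and shifted
    up by ``effect_size`` in samples of their class.  Every (series, gene)
    pair receives a shared N(0, ``series_sd``) intercept so that samples of
    one experiment are correlated — exactly the structure that makes
    experiment-stratified cross-validation necessary.  With
    ``series_class_purity`` > 0, classes also cluster by series (each series
    draws a majority class that each sample adopts with that probability),
    which is what makes non-stratified CV leak.
    """

    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 1.0  # log2-units shift for informative genes
    noise_sd: float = 1.0
    series_sd: float = 0.5
    missing_rate: float = 0.02
    n_samples: int = 500
    n_series: int = 25
    class_distribution: dict[str, float] = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5}
    )
    series_class_purity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.n_informative >= self.n_genes:
            raise ValueError("n_informative must be < n_genes")


@dataclass
class ExpressionDataset:
    matrix: ExpressionMatrix
    labels: pd.Series  # sample -> class
    series: pd.Series  # sample -> series
    informative_genes: dict[str, list[str]]  # class -> its shifted genes


def gen_expression(
    spec: ExpressionSpec, labels: pd.Series | None = None
) -> ExpressionDataset:
    """Generate a labeled expression dataset; see :class:`ExpressionSpec`.

    If *labels* (sample -> class) is given it overrides the internal label
    sampling and its index defines the sample ids."""
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_distribution)
    probs = np.array([spec.class_distribution[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    if labels is not None:
        sample_ids = list(labels.index)
        n = len(sample_ids)
    else:
        n = spec.n_samples
        sample_ids = [f"S{i:05d}" for i in range(n)]
    series_idx = np.array([i * spec.n_series // n for i in range(n)])
    series_ids = [f"GSE{1000 + j}" for j in series_idx]
    if labels is None:
        series_class = rng.choice(classes, p=probs, size=spec.n_series)
        y = np.where(
            rng.random(n) < spec.series_class_purity,
            series_class[series_idx],
            rng.choice(classes, p=probs, size=n),
        )
        labels = pd.Series(y, index=sample_ids)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    values = rng.normal(7.0, spec.noise_sd, size=(spec.n_genes, n))
    series_effect = rng.normal(0.0, spec.series_sd, size=(spec.n_series, spec.n_genes))
    values += series_effect[series_idx].T
    informative: dict[str, list[str]] = {c: [] for c in classes}
    for g in range(spec.n_informative):
        cls_ = classes[g % len(classes)]
        informative[cls_].append(gene_ids[g])
        values[g, (labels.to_numpy() == cls_)] += spec.effect_size
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        # never blank out a full gene row
        full = mask.all(axis=1)
        mask[full, 0] = False
        values = np.where(mask, np.nan, values)
    data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    series = pd.Series(series_ids, index=sample_ids)
    matrix = ExpressionMatrix(data, series, is_gene_level=True)
    return ExpressionDataset(
        matrix=matrix, labels=labels, series=series, informative_genes=informative
    )
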