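# Methods

## Problem and model

`ale` assigns three labels to GEO-style expression samples — sex (binary),
age (nonnegative, in years), tissue (a term of an OBO ontology) — using the
sample's free-text metadata first and its expression vector as a fallback.
The guiding assumption is asymmetric costs: a *wrong* label poisons every
downstream analysis (including the classifier's own training set, which is
built from text-extracted labels), while a *missing* label merely shrinks
the usable sample set.  Both stages are therefore tuned to abstain rather
than guess.

## Text extraction

**Field search order.**  `characteristics` (parsed key–value pairs),
`description`, `source_name`, `title`, then any extra columns.  Within the
characteristics block, pairs whose key names the label (`sex`/`gender`,
`age`, `tissue|organ|cell type|source`) are inspected before the others,
and channel 1 before channel 2 (one-color arrays dominate GEO; the choice
is otherwise arbitrary).  The first field class that yields a label
terminates the search, so a later contradictory field is never read.

**Sex.**  A token vocabulary shipped as data
(`src/ale/data/patterns.tsv`): male/m/man, female/f/woman at confidence
1.0; the 0/1 numeric coding (1 = male) at confidence 0.5 and only when the
surrounding key is an explicit sex/gender key — a bare digit in free text
is never a sex.  Single-letter tokens likewise require the explicit key.
Both "male" and "female" evidence in one field is a contradiction: no
label, warning logged.

**Age.**  Three accepted shapes: `age: <num> <unit>`, unit-in-key
`age (<unit>): <num>`, and bare `age: <num>`.  Unit synonyms:
y/yr/yrs/year(s) → years; mo/mos/mon/month(s) → months; w/wk(s)/week(s) →
weeks; d/day(s) → days.  A unit in the value wins over one in the key.  A
trailing alphabetic token that is *not* a known unit rejects the candidate
outright (no default-unit fallback): "age: 42 yaers" yields no label
rather than 42 years, the precision-first reading of misspelled units.
Conversion constants: months = 1/12 year, days = 1/365.25 year (Julian),
weeks = 7/365.25.  A bare number takes the species default — years, or
months when the organism string contains "mus" or "rattus" — and the label
is flagged `unit_was_default`.  Converted ages outside [0, 120] years
(configurable; 0 kept so neonates survive) are discarded with a warning.
Implicit phrasings ("patient X (34, F, non-smoker)") are deliberately not
matched.

**Tissue.**  All non-obsolete term names and synonyms (every scope:
EXACT/RELATED/NARROW/BROAD, scope recorded) form a dictionary scanned with
an Aho–Corasick automaton (`ale/_aho.py`, verified against a naive
quadratic scan in the tests).  Defaults: case-insensitive, patterns shorter
than 3 characters dropped, matches must be delimited by non-alphanumerics
("cap" never fires inside "capsule"); raw substring mode is available but
off, since ontologies are full of short ambiguous synonyms.  Among all hits
in the first yielding field, the term of minimal depth (shortest is_a path
to a root; a diamond takes the shorter side) is selected — general terms
are less informative but far less often wrong.  Ties break to the longer
matched surface string, then the smallest term id, so selection is
deterministic.  Matching is exact: "ovarian" does not map to "ovary"; fuzzy
matching is out of scope.

## Expression-based prediction

Normalization chain: log2(x+1) if the matrix maximum exceeds 30 (heuristic,
overridable); probes collapse to genes by keeping each gene's
highest-mean probe (ties to the smallest probe id); KNN imputation with
k = 5 in sample space (nan-Euclidean distances over mutually observed
genes; a gene observed by no neighbour falls back to its mean; all-missing
genes are dropped); then between-array quantile normalization, with ties
within a sample receiving the mean of their tied reference values.
Imputation runs *before* quantile normalization because ranks are
ill-defined on incomplete columns; on complete data the chain is idempotent
to 1e-9.

Training: genes with variance ≤ 0 are removed (threshold configurable),
the 100 genes with the largest one-way ANOVA F against the label are kept
(ties to the smaller gene id), and one L2-regularized logistic regression
(C = 1, lbfgs, max 1000 iterations) is fitted per class one-vs-rest.
Feature selection happens inside `train`, so cross-validation selects on
training folds only.  Prediction normalizes the per-class sigmoids to sum
to one and reports the argmax (ties to the first class in model order).
Classes need at least 10 training samples by default (configurable floor).
Age is *not* predicted from expression — the API reserves the label type
and rejects it — because continuous age regression is a different problem
with much weaker signal than sex (X/Y-chromosome genes) or tissue.

Text and ML labels combine by precedence: a text label always wins; an ML
label is accepted only when its probability reaches the threshold
(default 0.5).  The chance reference is a dummy classifier that samples
from the training label distribution, ignoring expression; its macro AUC
(one-vs-rest per class, unweighted mean) sits at 0.5 up to sampling noise.

## Evaluation

Folds are assigned to whole series: largest series first into the currently
smallest fold, ties shuffled deterministically under the seed.  This greedy
packing is not provably optimal but matches the exhaustive optimum on the
small instances where that can be enumerated.  Non-stratified folding is
implemented solely to measure the leakage it causes.

Precision excludes abstentions from its denominator; recall counts them as
misses.  Micro averaging pools predictions; macro averaging is the
unweighted mean over classes, skipping classes whose precision is undefined
(never predicted) and flagging them.  Top-M restriction (default M = 25
with a ≥ 10-sample support floor, both configurable) scores only the most
frequent true classes.  Age error is MAD and MSE in years plus the fraction
of pairs within 1/12 year.  Tissue errors are profiled as the distribution
of undirected is_a shortest-path lengths between predicted and true terms,
against the distances of uniformly sampled term pairs; the one-sided
Mann–Whitney U test quantifies whether predictions sit closer than chance.

## Synthetic data

The generators define the conditions every end-to-end claim is tested
under.

* **Metadata corpora.**  Label presence defaults to the rates observed
  across GEO metadata: tissue 86%, sex 26%, age 21%; true ages are drawn
  from N(46.7, 21.6²) years truncated to [0, 95], matching the reported
  gold-standard mean.  Phrasings are drawn from a versioned template table
  (`src/ale/data/templates.tsv`) covering explicit key–value, abbreviated,
  numeric-coded, unit-in-key, implicit-parenthetical and misspelled-unit
  families.  The last two are adversarial: they are planted but must never
  be extracted, which keeps the generator and the extractors honestly
  decoupled.  The truth table records, per sample and label, what was
  planted, where, and whether its family is parsable — so expected recall
  is computable exactly.
* **Toy ontologies.**  Rooted DAGs over unique pseudo-word names (never
  English, so they cannot collide with filler text), with occasional
  double parents (diamonds) and synonyms; serialized as valid OBO and
  reloaded through the production parser.  The generator tracks depths
  independently of the graph code.
* **Expression.**  Log-scale Gaussian intensities, baseline N(7, noise_sd²)
  with noise_sd = 1; 20 informative genes out of 2000 split across classes
  and shifted by 1.0 log2-unit in their class; per-(series, gene) random
  intercepts of SD 0.5 over 25 series of 500 samples; 2% missing entries.
  The effect size is of the order of a strongly sex-dimorphic transcript,
  and the series intercepts make stratification matter.  For the leakage
  demonstration, series are single-class (purity 1.0), intercept SD is
  raised to 2.0 and the effect lowered to 0.3 over 300 samples in 15
  series — conditions under which naive CV saturates while stratified CV
  barely beats chance.  Counts, probe-level artifacts and platform effects
  are not simulated; passing tests show the pipeline's logic is correct
  under the stated generative model, not that real-GEO performance numbers
  transfer.

All generators are bit-reproducible under their seed.

## Numerical and design notes

* Quantile-normalization tie rule: averaging the reference values over a
  tie group keeps the map single-valued and order preserving.
* `VarianceThreshold` semantics follow "strictly greater survives", so the
  default 0.0 removes exactly the constant genes.
* The dummy AUC uses sampled one-hot predictions, not the (constant) class
  priors, so it fluctuates around 0.5 instead of sitting at it by
  construction.
* Distances between terms in different ontology components are infinite
  and surface as an `inf` histogram bin rather than being silently dropped.
* Problem sizes in the test suite and acceptance script (hundreds of
  samples, ≤ 2000 genes, 10-fold CV) are chosen so every end-to-end claim
  re-runs in seconds while keeping the effects being demonstrated
  unambiguous at those sizes.

## Known limitations

* Extraction recall is bounded by the template/vocabulary inventory;
  implicit and misspelled phrasings are never recovered (by design).
* Exact string matching misses inflected tissue forms ("ovarian").
* No DAG-based probabilistic sharing between related ontology terms;
  tissue is scored as flat single-label multiclass.
* Non-human support is limited to the default-age-unit hook.
* Joint quantile normalization assumes one platform per input matrix.
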