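# Methods

This note documents the statistical model behind `metaprior`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Problem setting

The pipeline screens for metabolic genes that separate estrogen-receptor
negative from positive breast tumors consistently across several expression
cohorts, then ranks them by how little they have been studied. Its inputs are
per-study feature-by-sample abundance matrices (transcripts, proteins,
metabolites) with binary ERneg/ERpos labels, a gene→EC annotation map,
pathway membership sets, compound fingerprints and reactant pairs, and a
per-gene publication-count table.

## Per-study differential model

Each feature is tested independently per cohort:

- **Mann–Whitney U** (metabolites, proteins): two-sided; exact enumeration of
  the U null distribution when the pooled sample size is ≤ 12 and there are
  no ties, otherwise the normal approximation with mid-rank tie correction
  and continuity correction. The exact path refuses ties by design — the
  approximation handles them.
- **Welch t** (transcripts): two-sided on log2 abundances, Satterthwaite
  degrees of freedom. This is a deliberate stand-in for moderated microarray
  statistics (limma-style empirical Bayes shrinkage is out of scope); at the
  group sizes simulated here (≥ 15 per arm) the two give very similar raw
  p-values, but counts of significant transcripts in small cohorts will
  differ somewhat from a moderated analysis.
- **Fold change**: arithmetic group means on the linear scale,
  FC = mean(ERneg)/mean(ERpos); a geometric-mean variant is exposed as an
  option since intensity data are often summarized either way. Direction is
  `up` for FC > 1 and `down` for FC < 1; `unchanged` only at exactly 1, and
  significance never gates the stored direction (consumers apply their own
  alpha).
- **Prevalence filter** (proteomics): a feature is kept when observed in at
  least `min_per_group` (default 6) samples of *either* group. The
  either-group reading is intentional: a protein seen only in one phenotype
  is biologically the most interesting kind of presence/absence signal.
- No multiple-testing correction is applied at this stage; downstream
  consumers receive raw p-values, and the meta-analysis is the instrument
  that separates signal from noise across studies.

Untestable features (fewer than two observations in a group, non-positive
group mean) are skipped with a logged reason rather than failing a run, and
the skip list travels with the result table.

In `summarize_counts`, `altered = up + down` among features with raw p <
alpha; a significant feature with FC exactly 1 (a measure-zero event for
these tests) would not be counted.

## Metabolic-gene selection

A gene is metabolic when at least one of its EC numbers survives the
exclusion rules (the inclusive reading: such a gene does transform small
molecules, whatever else it does). The default exclusion list —
protein kinases (2.7.10–2.7.13), peptidases (3.4), RNA/DNA polymerases and
reverse transcriptase (2.7.7.6/7/49), topoisomerases (5.6.2), tRNA ligases
(6.1.1), ribonucleases (3.1.26/27), nucleic-acid motor ATPases (3.6.4) and
the RING E3 ubiquitin transferase (2.3.2.27) — ships as an editable YAML so
a curated list can replace it. Prefix matching is field-wise ("3.4" matches
3.4.21.5 but not 3.40.1.1). Selection is monotone in the rule list and
idempotent; both properties are tested.

## KS meta-analysis

For a gene measured in n studies with raw p-values p₁,…,pₙ, the one-sided
statistic D⁺ = maxᵢ(i/n − p₍ᵢ₎) (floored at 0) measures how far the
empirical CDF of the p-values exceeds the Uniform(0,1) CDF — i.e. enrichment
of small p-values, the signature of consistent differential expression. The
meta p-value is the exact finite-sample tail (Birnbaum–Tingey/Smirnov):

P(D⁺ ≥ d) = d · Σ_{j=0}^{⌊n(1−d)⌋} C(n,j) (d + j/n)^{j−1} (1 − d − j/n)^{n−j}

with the closed-form corner P(D⁺ ≥ d) = (1−d)ⁿ when ⌊n(1−d)⌋ = 0. The exact
tail is essential: n is at most the number of studies (≤ 10 here), where the
asymptotic KS distribution is badly wrong, and consistent signals produce
tails of order 1e-15 that only the exact sum resolves. The implementation is
cross-checked in the tests against an independent reference implementation
and against 10⁶-draw Monte-Carlo.

Choices:

- **One-sided D⁺** is the default (small-p enrichment is the scientific
  question); a two-sided mode exists behind a flag.
- **min_studies = 3** by default. With n = 1 the statistic degenerates to
  D⁺ = 1 − p and the meta p-value to p itself — well-defined but not a
  meta-analysis; genes below the floor are reported separately as
  "insufficient evidence", never silently dropped.
- **No study-size weighting**: each study contributes one p-value.
- Ties in the final ranking are broken lexicographically by gene symbol, so
  rankings are reproducible.

Under a global null the meta p-value is uniform, so the meta-analysis is
calibrated (verified: rejection fraction at 0.05 stays inside a 3σ binomial
band); no effect-size combination (Fisher, Stouffer, random-effects) is
attempted.

## Pathway over-representation

Per pathway, the overlap k between the selected set (size n) and the
pathway's members within the measured universe (size K of N) is tested with
the hypergeometric upper tail P(X ≥ k); BH correction runs across tested
pathways. The universe is the measured, post-filter feature set per omics —
conservative relative to a whole-genome universe. Pathways with no universe
member are reported as untested; universe features in no pathway are counted
and reported as unmapped.

The multi-omics mode maps protein ids to gene symbols (and metabolite ids
into the same namespace) and, by default, pools the mapped ids into one test
per pathway; an alternative per-omics mode tests each layer separately and
combines p-values by Fisher's method. Both are provided because either
pooling or combining is defensible; neither is asserted as canonical. In
both modes each pathway carries support flags — which omics contribute at
least one overlapping selected member — reproducing the three-color
semantics (all three layers / genes+proteins / genes only).

## Biochemical network

Enzymes are nodes: EC numbers appear in the graph as their own node kind,
because three of the five edge classes (gene–enzyme, protein–enzyme,
compound–enzyme) terminate at an enzyme. The remaining classes connect
metabolites: curated reactant pairs (rpair), and chemical similarity when
the Tanimoto coefficient of the two structural fingerprints is strictly
greater than the threshold (default 0.7; a pair at exactly 0.7 gets no
edge). Two all-zero fingerprints get similarity 0, not 1, so unannotated
compounds cannot form spurious cliques. Where both an rpair and a
chemical-similarity edge would connect the same pair, the biochemical edge
wins.

Node attributes (fold change, raw p, direction) come from the differential
tables; entities without a record get neutral attributes (FC 1, p 1,
unchanged) with a warning. Construction is a pure function of its inputs:
nodes and edges are inserted in sorted order.

Communities come from greedy modularity maximization run per connected
component (components are never merged), with deterministic label order.
This is a pragmatic, seedable stand-in for interactive community-detection
plugins; the labeling function is trivially pluggable.

Exports: GraphML (round-trip safe for all attributes, verified by test) and
SIF plus node/edge attribute TSVs. Rendering hints are materialized as
attributes: node size 20·(1+|log2 FC|), color red/blue/grey by direction.

## Literature counts and prioritization

Counts use the fixed query template `"<SYMBOL>" AND "breast cancer"`
(untagged fields). Offline fixture mode is the test and default path; live
NCBI eutils mode caches to disk and marks retrieval failures as
*unavailable* — never a fabricated 0, and unavailable genes are excluded
from the under-studied set. A gene is under-studied when its count is
strictly below the threshold (default 5). The final table takes the top-n
genes by meta p-value (default 50), attaches single-cohort gene/protein
p-values where measured (absent proteomics entries render as `-`), and is
stable under input row order.

## Synthetic-data generator

`synthio` emulates the statistical structure of a ten-study ERneg/ERpos
compendium:

- **Abundance model**: per feature f, log2 value = μ_f + δ_f·I[ERneg] + σ·ε,
  ε ~ N(0,1), reported on the linear scale. Baselines μ_f ~ N(8, 2²)
  (log2-intensity-like). δ_f = ±effect_size·σ for a Bernoulli(frac_diff)
  subset of features, 0 otherwise; a feature is *differential* iff its
  effect is nonzero, so effect_size = 0 is a global null.
- **Shared truth**: differential genes and their directions are the same in
  every study (the meta-analysis assumes cross-study consistency); an
  optional per-study effect-size jitter multiplier (default 0) relaxes this.
- **Panels**: each study measures a seeded random subset of
  panel_overlap·n_genes genes (default 0.8), so per-gene study counts are
  Binomial(n_studies, overlap).
- **Proteomics missingness**: missing-completely-at-random at missing_rate
  (default 0.1); an MNAR switch makes low-abundance cells up to twice as
  likely to be missing. Proteins inherit the truth of the gene they encode
  (protein Pk ↔ gene Gk).
- **Annotations**: 10% of genes get small-molecule ECs from a pool of
  common intermediary-metabolism enzymes, 5% get excluded-class ECs, and
  every fifth metabolic gene also carries an excluded EC (the mixed case the
  selection rule must handle). Pathways partition the gene universe with
  metabolites spread across them; reactant pairs chain metabolites sharing a
  pathway; fingerprints are random bitsets (128 bits, density 0.2).
- **Literature counts** ~ NegativeBinomial(size 0.35, mean 25) — heavily
  overdispersed with ≈ 20% zeros, matching the long-tailed shape of
  per-gene publication counts — drawn independently of the truth table so
  that significant-but-under-studied genes exist by construction.
- Defaults (10 studies, 1000 genes, 200 proteins, 100 metabolites, 30 vs 30
  samples, 10% differential at a 1σ log2 effect) are the package's study
  conditions: large enough for stable calibration and recovery statistics,
  small enough that the entire test suite and acceptance script run in
  minutes on one core.

What the generator does **not** emulate: batch effects, probe-level
microarray structure, raw spectra, correlated features, study-size
heterogeneity (all studies share one design), and platform-specific
normalization artifacts. Passing tests therefore demonstrate statistical
correctness and calibration of the pipeline's machinery under its own
model — not robustness to the messiness of real cohort data.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.SeedSequence((seed, stream,
  index))`, so every artifact is a pure function of the configuration and
  identical configs give byte-identical output files.
- Exact Mann–Whitney switches to the approximation at pooled n > 12 or any
  tie; the Birnbaum–Tingey sum is evaluated in double precision (n ≤ 10
  keeps every term well-conditioned) and clamped to [0, 1].
- Welch t with zero variance in both groups returns p = 1 for equal means,
  p = 0 otherwise.
- Validation failures on inputs (p-values outside [0,1], inconsistent
  hypergeometric counts, malformed EC numbers, fingerprint length
  mismatches) raise immediately; per-feature data problems (too few
  observations, non-positive means) skip the feature with a logged reason.
- EC exclusion prefixes match field-wise on the dot-separated EC fields.

## Known limitations

- The Welch stand-in means transcript significance counts are approximate
  relative to moderated-statistics pipelines, especially below ~10 samples
  per arm.
- The per-gene KS test treats studies as exchangeable; systematically
  different study sizes or qualities are not modeled or weighted.
- The pooled multi-omics enrichment mixes namespaces after id-mapping;
  pathway-size inflation by metabolite members is not corrected beyond the
  universe restriction.
- Live PubMed counts drift over time and depend on indexing; they are not a
  stable quantity, which is why fixture mode is the reproducible path.
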