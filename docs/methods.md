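# Methods

## Model and training design

The scorer is a binary L2-regularised logistic regression distinguishing
proxy-benign (label 0) from proxy-deleterious (label 1) variants. The proxy
framing replaces curated pathogenic/benign sets: derived alleles that
survived in the human lineage stand in for benign variation, matched
simulated variants for deleterious variation. The fitted linear predictor is
the raw deleteriousness score; no probability calibration is applied because
only the ranking is consumed downstream.

The design matrix concatenates five column groups — annotation features
`X`, ordered base-substitution indicators, SNV-reachable amino-acid
exchange indicators, missingness indicators `W`, and consequence ×
annotation interactions over a designated set `D`. With the shipped default
schema the group sizes are 222 / 12 / 189 / 14 / 592 = 1029 columns.
Feature order is the schema-declared order within each group (numerics in
their configured order, one-hot levels in level order, interactions
category-major over the `D` order). A fixed, recorded order — rather than
re-sorting alphabetically — keeps weight vectors comparable across runs
while preserving the conventional ordering of the interaction set.

### Schema conventions

The model definition fixes the totals (222 X features from 90 numeric + 12
categorical annotations; 16 consequence categories; 37-member `D`) but not
every name or cardinality. Conventions adopted here:

* The variant consequence is one of the 12 categorical annotations, with 16
  levels (stop-gained, stop-lost, missense, synonymous, canonical-splice,
  splice-site, intronic, 5utr, 3utr, upstream, downstream, regulatory,
  noncoding-change, intergenic, frameshift, inframe). This makes "every row
  has exactly one consequence one-hot" a structural property of the X
  block. An "unknown" consequence is not a level; callers reassign such
  variants to `synonymous` upstream.
* The other 11 categoricals carry opaque levels with cardinalities
  6 × 11 + 5 × 10 = 116, so 90 + 16 + 116 = 222. Only the totals matter for
  the model; real annotation sources are out of scope and all annotation
  columns are treated as opaque numbers/categories.
* Each `W` indicator covers a named annotation group
  (e.g. `SpliceAI` covers the four SpliceAI submodel columns) and fires
  when the entire group is undefined. Missing numeric values impute to 0;
  the indicator, not the zero, carries the missingness information.

### Amino-acid exchange enumeration

The exchange set is produced by brute force over all 64 codons × 9
single-base mutants of the standard genetic code, alphabet = 20 amino acids
plus stop. A pair (ref, alt) is included whenever some codon change
produces it, *including* synonymous self-pairs (ref, ref): a synonymous
single-base change exists for 19 of the 21 symbols (Met and Trp are
single-codon), giving 189 = 170 non-synonymous + 19 self-pairs. This is the
convention under which the canonical count of 189 holds; enumerations that
drop self-pairs give 170.

### Splice feature preprocessing

* **Masking.** Within donor and acceptor independently: predicted splice
  gain at an annotated site, and predicted splice loss away from any
  annotated site, are set to 0. Rationale: a "gain" where a site already
  exists (or a loss where none exists) shows no class specificity and only
  adds noise. Masking is idempotent; site annotation is an exact position
  match against the supplied donor/acceptor table.
* **Derived-allele swap.** Proxy-benign variants are scored with ref/alt
  reversed (the upstream models require ref to match the genome), so their
  gain and loss scores trade places; the swap is applied first and masking
  after the swap.
* **MMSplice deltas.** Per submodel, alt − ref for proxy-deleterious and
  plain scoring; ref − alt for proxy-benign. Positive differences are set
  to 0, so the stored features are ≤ 0 and encode predicted splice-element
  weakening only. The features are kept non-positive rather than negated;
  the regression absorbs the sign.
* **Imputation.** Variants not covered by either splice model get all-zero
  splice features with the `SpliceAI` missingness indicator set. Splice
  blocks attach to a variant only when gene identifiers agree (a block
  without a gene matches any); unmatched blocks are dropped before
  imputation.

Standalone combined scores for benchmarking: the four SpliceAI submodels
collapse by maximum; MMAI = MMSplice/sd_mm + SpliceAI/sd_ai with the
benchmark-set standard deviations sd_mm = 0.5291, sd_ai = 0.1206; MMAIpsi
adds reference-allele percent-spliced-in normalised by sd_psi = 0.0622.
These SDs are constants of the benchmark data set, not tunables.

### Fitting

Continuous columns (numeric annotations and interaction products) are
standardised with training-set mean/SD; indicator columns stay raw.
Regularisation strength is selected from a small grid
(C ∈ {0.01, 0.1, 1, 10}) by log-loss on a 25% stratified held-out split,
then refit on everything. Solver: lbfgs, tolerance 1e-6; failure to
converge raises rather than warns. Classes are used as provided — the
training design is balanced by construction, so no reweighting is applied.
Reported coefficients are on the standardised-column scale, recorded in the
model artifact together with the transforms so scoring is exact.

### PHRED-like scaling

A raw score's rank against a reference score distribution (descending; ties
share the worst rank; scores above the whole reference get rank 1) maps to
−10·log10(rank/N). The reference distribution is an explicit argument — in
production it would be all possible genomic SNVs; in examples and tests it
is whatever score set the caller supplies.

## Evaluation statistics

* auPRC integrates precision over recall by trapezoid; auROC is the
  rank-sum probability (verified in tests against exhaustive Mann–Whitney
  pair counting with ties worth one half).
* Δpsi classification: a variant is splice-disrupting when
  |psi_alt − psi_ref| strictly exceeds 0.5 (alternative thresholds 0.7,
  0.3, 0.1, and a two-sided mode — sdv if > 0.5, no-sdv if < 0.1,
  intermediate excluded — are supported). Δpsi is taken as the absolute
  change.
* Frequency bins: singleton iff AC = 1; otherwise frequent iff
  MAF ≥ 0.001, else rare. The boundary MAF = 0.001 is unassigned by the
  strict >/< formulation; it goes to frequent so the bins always partition.
* Enrichment: threshold = linear-interpolation percentile of the score
  distribution of the analysed category; expected count per bin = bin size
  × overall fraction above threshold; ratio = observed/expected.
  Count conservation makes bin-size-weighted ratios average to 1 at any
  threshold. CIs are percentile bootstrap (2.5/97.5) over variants
  resampled with replacement, 1000 iterations by default (fewer in
  time-bounded null-calibration loops).
* Multi-predictor comparisons support both missing-score policies:
  excluding variants any predictor leaves unscored, or interpreting
  missing as benign (score 0).

## Synthetic data

The generators emulate the *structure* of the real inputs, not their
biology:

* **Training sets.** Plain numeric annotations are standard Gaussians
  (per-name mean/SD overridable); labels are Bernoulli with probability
  sigmoid(intercept + x·w) for configurable sparse weights, giving
  ~balanced classes at intercept 0 and closed-form class-conditional means
  for tests. Splice blocks are generated with class-dependent asymmetry —
  proxy-deleterious variants near splice sites receive elevated
  masking-surviving scores, proxy-benign blocks are emitted in
  reversed-allele orientation — so the full mask/swap/delta/impute path is
  exercised, and preprocessing (not the generator) produces the final
  features. Missingness is missing-completely-at-random per indicator
  group.
* **Reporter-assay-like sets.** A latent disruption effect drives both the
  psi drop and (noisily) the splice scores; psi values are logit-normal and
  clipped to [0,1]; default sdv prevalence matches the real assay's
  ≈ 1050/27,733 ≈ 3.8%. As score noise grows the scores decouple from the
  labels and any classifier's auPRC falls to prevalence.
* **Frequencies.** Allele counts are log-normal with a singleton floor over
  a 2 × 15,708-chromosome sample, giving a gnomAD-like majority of
  singletons; a coupling parameter pushes high-scoring variants toward low
  counts to reproduce singleton enrichment qualitatively.

What passing tests show is therefore that the *machinery* is correct and
calibrated under its stated assumptions — not that real-genome performance
numbers are reproduced, which would require the genome-scale annotation and
training resources that are out of scope here.

## Problem sizes

Parameter recovery runs at n = 50,000 simulated variants on a compact
schema (24 numeric annotations including the nine splice features, 4
consequence categories, |D| = 5, ~100 columns); the full 1029-column schema
is exercised structurally (layout identities, encoding) rather than in the
large fit, which keeps the whole acceptance run around half a minute while
preserving the statistical content of the recovery check. Null calibration
of the enrichment bootstrap uses 100 repetitions of n = 2000 variants with
200 bootstrap iterations each.

## Known limitations

* Annotation values are opaque; no genome, transcript model, or external
  resource is read, and the real provenance of the ~100 annotations is out
  of scope.
* The splice-site table uses exact position matching; windowed matching
  (e.g. canonical ±2 dinucleotides) would need a preprocessed table.
* Running the SpliceAI/MMSplice networks is out of scope; their scores are
  inputs.
* The synthetic generators make no attempt at sequence realism (mutation
  rates, linkage, codon usage); they provide known ground truth, not
  biology.
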