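# Methods

## The classification problem and the model

The endpoint is binary: is a compound a substrate (+1) or a nonsubstrate
(−1) of human wild-type BCRP?  Because the transporter is polyspecific —
ligands can be recognized at more than one binding site — the substrate
class is a *union* of regions in descriptor space.  A single linear
discriminant cannot express an OR of half-spaces, which motivates the
ensemble architecture:

1. **Random subspaces.** Descriptors are organized into named blocks
   (constitutional, topological, connectivity, …).  A pool is a random
   combination of whole blocks whose total size lands within ±20% of a
   target (default 200).  Training each model on a different pool
   decorrelates the ensemble members; drawing whole blocks (rather than
   random descriptors) keeps each pool chemically coherent.
2. **Stepwise forward selection.** Within a pool, descriptors are selected
   by forward MLR on the ±1 class dummy: at each step the candidate with
   the largest F-to-enter is added, provided its entry p-value is below
   `alpha_enter` (default 0.05) and its tolerance — 1 − R² against the
   already-selected descriptors — is at least `tolerance_min` (default 0.1,
   swept 0.1–0.5).  Selection stops at `max_steps` (default 10, swept
   10–15) or when another predictor would push the cases-to-predictors
   ratio below 11.  Selection and the final fit are deliberately different
   procedures (MLR selects, LDA fits), so the selected set is not tuned to
   the discriminant geometry.
3. **LDA.** The discriminant is the pooled-covariance two-class solution
   with equal priors: coefficients `a = S⁻¹(μ₊ − μ₋)`, intercept placing
   the `df = 0` boundary at the midpoint of the projected class means.
   Substrates tend to positive `df`.  Equal priors are appropriate because
   the training set is built balanced by the partition stage.
4. **Fusion.** Every 2-model pair is fused per compound by MAX or AVE of
   the raw `df` values.  Pairs are ranked by ascending false-positive count
   on the external test set (FP = substrate predicted nonsubstrate), then
   by descending high-specificity partial AUC, then total AUC, then pair
   identity.  Scores are fused unstandardized; `df` scales are only loosely
   comparable across models and no standardization step is part of the
   procedure — a documented caveat, and per-model z-scoring is available to
   callers who want it.

### Decision conventions

- Class call: substrate iff `df > 0`; a `df` exactly 0 is called
  nonsubstrate.  The tie goes against the compound because the intended use
  is a discard filter: passing a substrate through (an FP in the screening
  orientation) is the costly error.
- Confusion summaries always state their positive class.  In screening
  reports the positives are the *nonsubstrates* (the compounds being
  sought), so Se is the nonsubstrate recovery rate and Sp the substrate
  rejection rate.

## Dataset partition

Clustering runs separately within substrates and nonsubstrates.  Stage 1 is
complete-linkage agglomerative clustering on 1 − Tanimoto similarity of
RDKit path fingerprints, cut at a configurable similarity floor (default
0.35) — an open, exactly reproducible stand-in for approximate
maximum-common-substructure library clustering; the MCS-size floor of the
original procedure maps onto the similarity cutoff.  For descriptor-space
data without SMILES the same hierarchy is built on Euclidean distance over
the nine z-scored property descriptors, cut at the median pairwise
distance.  Stage 2 refines the labels by a Hartigan-style single-point
improvement loop on the nine normalized properties: on convergence *no*
single-point reassignment can decrease the total within-cluster squared
distance (a guarantee plain Lloyd iteration does not give), and the
refinement never increases the objective it starts from.  Stage 3 draws
round-half-to-even(fraction × cluster size) compounds per cluster into the
test set — 50% for substrate clusters, 25% for nonsubstrate clusters —
with singleton clusters kept in training so rare scaffolds remain available
to the models.  Normalization is z-scoring over the compounds being
clustered; the rounding rule and singleton policy are this package's
choices where the original procedure is silent.

## Validation protocols

- **Randomization:** 50 label scrambles; the full stepwise+LDA pipeline is
  rebuilt per scramble (descriptor re-selection included — the stronger
  null), and the scrambled-label training accuracy distribution is
  reported.  A real structure–class relationship shows the true model well
  above this null.
- **Leave-group-out CV:** each round removes a stratified group of 10
  (class ratio preserved within ±1), rebuilds, and predicts the removed
  compounds; 50 rounds.  The sampler prefers compounds not yet removed, so
  full coverage of the training set is achieved by construction and the
  report carries a coverage flag.
- **External validation:** the untouched test set from the partition stage.

## ROC and early-recognition statistics

The ROC machinery is nonparametric throughout.  AUC is the trapezoid area
of the empirical curve (ties produce diagonal segments) and equals the
Mann–Whitney U statistic with ties counted ½.  Variances and the
covariance of paired AUCs use placement values (the DeLong structural
components), and two paired curves are compared with
`z = (AUC_A − AUC_B)/√(Var_A + Var_B − 2·Covar_AB)` against a standard
normal.  Partial AUC over a specificity band [sp_lo, 1] is the
unnormalized trapezoid area (a perfect classifier scores `1 − sp_lo`),
with the curve linearly interpolated at the band edge; uncertainty comes
from a stratified bootstrap (default n = 2000) that resamples hits and
non-hits separately so every replicate preserves the original group
sizes, with percentile 2.5/97.5 confidence limits.  Two-curve pAUC
differences are tested by the paired stratified bootstrap.

Early-recognition metrics are computed on a ranking whose hits are the
known nonsubstrates, ordered by ascending discriminant value:

- **AUCc**, the accumulation-curve area, is computed by the same
  threshold sweep as the ROC curve, which makes the identity
  `ROC AUC = AUCc/R_i − R_a/(2·R_i)` hold to machine precision on every
  ranking, ties included (`R_a` = hit ratio, `R_i = 1 − R_a`).
- **EF** uses an integer selection `n = ⌊x·N⌋` (default x = 0.10, or an
  explicit n); published EF values exist under more than one selection
  convention, so every report prints the one used.
- **RIE/BEDROC** use exponential rank weights `exp(−α·r/N)` with α = 20 by
  default (the convention of the metric's source); α is printed in every
  output.  RIE has random expectation 1; BEDROC is RIE rescaled to [0, 1].
- A **saturation caveat** is attached whenever the library hit ratio
  exceeds 0.2: once hits saturate the early list the exponential metrics
  compress and lose resolution, which is exactly why campaigns are
  evaluated on decoy-diluted libraries (hit ratio < 0.05) rather than on
  the bare test set.

## Synthetic data generator

The generator emulates the features of the real problem the method
actually depends on, at study scale (262 compounds; 164-compound balanced
training set):

- **Block structure:** 12 blocks × 72 descriptors, within-block
  equicorrelation 0.3 via a shared block factor (compound descriptors from
  one family are correlated in practice).
- **Polyspecific labels:** two site rules, each a deterministic linear
  threshold on the descriptors, joined by OR.  A rule concentrates weight
  `effect_size/√n_inf` on 3 informative descriptors (drawn independent of
  the block factor) and spreads a weak residual weight, totalling
  `0.3/effect_size`, over a diffuse 12-descriptor background — the site
  recognizes a few dominant features plus a faint general-property
  contribution.  `effect_size` (default 1.5) therefore sets how strongly
  the informative descriptors stand out, and the stored ground truth
  (weights + thresholds) recomputes the noiseless labels exactly.
- **Calibration:** each rule's threshold is the empirical quantile making
  it fire at rate `p = 1 − √(1 − balance)`; the rules are independent, so
  the OR hits the target substrate fraction (default 0.6, matching a
  substrates-heavy curated dataset).
- **Noise:** labels flip independently with probability `label_noise`
  (default 0.05), standing in for inter-laboratory assay disagreement and
  curation error.
- **Decoys:** putative substrates are rejection-sampled from the same
  process conditional on a rule firing, flagged `putative`, and counted as
  non-hits during screening (the conservative reading — some may actually
  be nonsubstrates, so measured enrichment is a lower bound).

What the generator does **not** emulate: real descriptor marginals (all
Gaussian here), realistic SMILES (descriptor-space generation only — a
small hand-written SMILES fixture exercises molecule-based code paths),
scaffold clustering structure, activity cliffs, or any relationship between
blocks and chemistry.  Passing tests on these data show the *pipeline*
behaves as specified (selection guards hold, ensembles beat individual
models on OR-structured classes, protocols are calibrated); they do not
certify accuracy on real BCRP data, which requires real descriptors and a
curated dataset.

## Numerical and design choices

- Stepwise ties on F-to-enter break lexicographically by descriptor name;
  selection is fully deterministic given matrix, labels and config.
- Zero-variance descriptors are skipped with a log entry; non-finite
  descriptor values are imputed with the training-set median (LDA needs
  dense matrices); near-constant descriptors are removed when the modal
  value covers > 95% of training rows or the scaled variance is < 1e−8,
  judged on training rows only.
- Descriptor CSVs round-trip at 12 significant digits; block manifests are
  JSON sidecars.
- A singular pooled covariance raises an error naming the collinear
  descriptors rather than silently regularizing.
- The paired z-test degenerates when the two score vectors are nearly
  identical (almost no hit/non-hit pair changes order, the statistic is
  discrete and the test ultra-conservative); calibration checks therefore
  use nulls with jitter at a meaningful fraction of the score scale.
- All randomness flows through explicit integer seeds; there is no global
  random state, and pipeline runs are reproducible from config + seed.

## Problem sizes used in the automated checks

The statistical suites run at study scale but reduced ensemble width: the
ensemble-advantage experiment uses 164 compounds (85/79), 12 blocks and 20
pools over 20 seeds; z-test calibration uses 2,000 Monte-Carlo replicates
of 100 compounds; metric identities run on 1,000 random rankings and
exhaustive rankings up to N = 8.  These sizes are the package's choice of
the smallest scales at which the properties are statistically meaningful.

## Known limitations

- The two discriminants in an ensemble are fused on raw, unstandardized
  `df` scales (see above).
- The fingerprint/complete-linkage stand-in reproduces the *role* of
  MCS-based library clustering, not its cluster boundaries; an exact-MCS
  backend would be a drop-in replacement behind the same interface.
- Stepwise forward selection is greedy and admits suboptimal subsets by
  construction; best-subset search is out of scope (combinatorially
  infeasible at pool size ~200).
- BEDROC values across libraries are comparable only at matched `α·R_a`;
  reports print N, A, R_a and α for that reason.
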