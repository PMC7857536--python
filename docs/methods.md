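# Methods

## The measurement model

`protstab` analyzes pulsed-SILAC time courses from exponentially
dividing cells. Before the pulse, two cultures are fully labeled with
light (L) and medium (M) lysine; at t = 0 the M medium is replaced by
heavy (H) medium. From then on the M-labeled protein pool can only
shrink, by proteolysis, while per-cell M intensity also falls because
cell division dilutes it. For one protein the normalized M/L intensity
ratio follows

    y(t) = A · exp(−t (λ_dil + λ_deg)) + B

with λ_dil = ln2 / t_cc (t_cc the generation time, default 60 min),
λ_deg the first-order degradation rate, A the normalized ratio at t = 0
and B a constant offset attributed to label recycling. The half-life of
a degradable protein is t½ = ln2 / λ_deg. All internal times are
minutes; the default sampling schedule is 0, 15, 60, 120, 180 and
240 min.

Because measured M/L and H/L ratios should sum to one but in practice
deviate slightly, each time point is rescaled by a single constant so
that M/L + H/L = 1 exactly. A time point with a missing H/L value is
used unnormalized with a warning; duplicate time points are averaged.

## Stable vs degradable: nested models and LRT

Two nested bounded least-squares models are fitted per protein
(`scipy.optimize.least_squares`, trust-region reflective): a
dilution-only model with λ_deg fixed at 0, and the full model with
λ_deg free. Boxes: A ∈ [0.75, 1.25], B ∈ [0, 0.4],
λ_deg ∈ [0, 100·λ_dil]. Initialization is deterministic — A₀ from the
first observed ratio, B₀ from the last, λ_deg,0 = λ_dil/10 — with two
further fixed starts; for the full model one start sits at λ_deg = 0 so
the full-model RSS can never exceed the reduced-model RSS.

The fits are compared on the likelihood scale using the concentrated
Gaussian log-likelihood ℓ = −(n/2)(ln(2π·RSS/n) + 1) (the standard
bridge between least squares and likelihood-ratio testing; identical to
R's `logLik` for `nls` objects). The statistic 2(ℓ_full − ℓ_reduced),
clipped at zero, is referred to χ²₁; p-values are Benjamini–Hochberg
corrected across proteins, q ≥ 0.05 means stable. Proteins with
R² < 0.8 in *both* models are discarded, as are series with fewer than
four observations, fewer than two identifying peptides, or ambiguous
peptide evidence.

Two numerical caveats are deliberate and documented rather than
"corrected":

* **Small-sample inflation.** With only six observations the χ²₁
  reference is anti-conservative: the exact small-sample analog of the
  statistic is n·ln(1 + F/(n−p)) with an F(1, n−3) distribution, which
  puts ≈ 19% of null mass beyond the 3.84 cutoff; the λ_deg ≥ 0
  boundary (half the null mass lands exactly at 0) halves this to
  roughly 9–11%, which is what the calibration run in
  `scripts/acceptance.py` measures. This matches the behavior of the
  standard `lrtest`-on-`nls` recipe at this design and is inherited by
  any reanalysis using it; the BH correction downstream operates on
  these raw p-values.
* **Perfect-fit guard.** On noiseless data both models reach RSS at
  machine precision and the likelihood ratio of numerical noise is
  meaningless; when both RSS values fall below 10⁻¹²·n the statistic is
  set to 0.

Rate estimation is information-limited: with six time points and ratio
noise of SD 0.02, slow decay (t½ ≈ 200 min ≈ 3·t_cc) is nearly
confounded with the offset B over a 240-min window, and the measured
median half-life error of the global least-squares optimum is ≈ 15%
(fast proteins: < 10%); the error scales roughly linearly with the
noise SD and vanishes without noise. This is a property of the
estimator at this design, not of the implementation — on simulated
series the fitted RSS is never worse than the RSS at the true
parameters.

## Slow vs fast: Gaussian mixture on log2 half-lives

Degradable proteins are split by a two-component normal mixture fitted
by EM to log₂ half-lives in minutes. The log₂-minute scale makes the
published component parameters (≈ N(7.64, 0.72), i.e. ≈ 200 min, and
≈ N(5.58, 2), i.e. ≈ 48 min) consistent with the reported fast-protein
half-life range, and half-life histograms are conventionally binned in
log₂ increments.

EM details: the primary initialization splits the sorted data at the
median; five seeded random restarts guard against local optima and the
best log-likelihood wins. Component variances are floored at 10⁻³ times
the data variance — the same role as `reg_covar` in scikit-learn —
which blocks the classic spike degeneracy of mixture likelihoods.
Components are reported in descending-mean order (slow first). The
log-likelihood is non-decreasing over iterations by construction and is
asserted per iteration.

Model choice (k = 1 vs k = 2) uses a parametric-bootstrap LRT: null
datasets are simulated from the fitted single Gaussian, the statistic
2(ℓ₂ − ℓ₁) is recomputed on each, and p = (r + 1)/(n_boot + 1). The EM
tolerance inside the bootstrap (10⁻⁶, 500 iterations, 2 restarts) is
applied identically to the observed and resampled statistics; mixing a
tightly converged observed statistic with loosely converged null
statistics would bias the test.

Observations go to the component with posterior probability above 0.5,
ties toward slow. One estimator caveat: at n ≈ 400 with an 18% wide
fast component, the fast-component mean carries a downward bias of
≈ 0.2 log₂ units with a sampling SD of ≈ 0.6 (the narrow slow component
absorbs ambiguous mid-range points); the slow-component mean is
unbiased to within 0.1. Finally, a fast-assigned protein whose
half-life exceeds every slow-assigned half-life is relabeled stable:
such proteins sit in the extreme right tail and are captured by the
fast component only because of its large variance. This generalizes a
manual curation step into an explicit rule.

## The 188-feature table

Feature blocks, in fixed order: disorder (4), network summaries (6),
node embedding (128), physicochemistry (10), connectivity-normalized
physicochemistry (10), position-2 residue indicators (20), position-2
group indicators (5), degron motifs (5). Widths sum to 188 and the
assembly asserts it.

* Disorder calls are an input (per-residue binary strings from any
  external predictor); features are the disordered fraction and counts
  of maximal disordered runs (all, ≥ 30 aa, ≥ 50 aa). Missing disorder
  yields NaN sentinels, median-imputed inside classifier training
  folds.
* Physicochemical values come from Biopython's `ProteinAnalysis`
  (molecular weight, Lobry aromaticity, Guruprasad instability index,
  isoelectric point, Kyte–Doolittle GRAVY, Vihinen flexibility, length,
  helix/turn/sheet-favoring fractions). Sequences shorter than the
  9-residue flexibility window get sentinel 0 with a warning.
* The per-degree block divides each physicochemical feature by
  (degree + 1); the pseudo-neighbor keeps it defined for isolated
  nodes.
* Position-2 features encode the residue after the initiator Met (the
  N-end-rule position) as one-hot indicators and as the five-group
  partition aliphatic IVL / aromatic FYWH / charged KRDE / tiny GACS /
  diverse TMQNP.
* Degron motifs are anchored presence indicators: N-terminal NM1
  (polar, T-or-φ, φ, basic, φ), NM2 (Met, basic, φ, φ, φ, X₅, φ) and
  NM3 (φ, X, polar, X, polar, X, basic, polar), and C-terminal CM1
  (…LAA) and CM2 (…RRKKAI, both SsrA-tag-like ClpXP signals). The
  residue classes φ = AVLIMFWY, basic = KRH, polar = STNQCYHG follow
  the ClpXP motif literature and are configurable, since reasonable
  alternatives exist and change which sequences match. NM1/NM3 match at
  the first or the second residue (with or without the initiator Met,
  configurable); NM2 requires the Met.
* Network summaries per protein: degree, neighbor averages of pI,
  molecular weight and length, pooled neighbor disorder (total
  disordered residues across neighbors / total neighbor length), and an
  isolated-node flag. Isolated or absent proteins get sentinel 0
  averages, matching the zero convention of the embedding block.

The 128-dimensional node embedding is computed in-package: seeded
second-order random walks (walk length 80, 10 walks per node, return
and in-out parameters p = q = 1 by default, i.e. uniform walks),
windowed co-occurrence counts (window 10), positive pointwise mutual
information, and truncated SVD of the PPMI matrix scaled to the
symmetric factorization U·√Σ. PPMI factorization optimizes the same
objective family as skip-gram training on the walks while being exactly
reproducible under a fixed seed and single-threaded by construction.
Isolated nodes receive the zero vector; when the matrix rank is below
128 the trailing dimensions are zero-padded.

## Stability classification

Seven task setups over stable (S), slow-degrading (SD) and
fast-degrading (FD): FD×SD, FD×S, SD×S, FD×rest, SD×rest, S×rest and
the three-class task. The classifier is L1-regularized (LASSO) logistic
regression — liblinear for binary tasks, saga with multinomial loss for
the three-class task, where liblinear is unavailable. Performance is
AUC under 10 repeats of stratified 10-fold cross-validation; each
repeat's AUC is the mean over its folds, and the three-class task uses
the macro average of one-vs-rest AUCs.

Features are median-imputed and standardized *inside each training
fold*; an L1 penalty is scale-sensitive, so unscaled heterogeneous
features (molecular weight vs binary motifs) would be penalized
inconsistently. The penalty is chosen per outer fold by nested
stratified 5-fold CV over 20 log-spaced values of the inverse
regularization strength C ∈ [10⁻³, 10³], ties toward the stronger
penalty. Selection fits run under a reduced iteration cap (the AUC
ranking across the grid is insensitive to tail convergence; at large C
on near-separable folds the L1 optimum diverges slowly); the final
per-fold model uses the full cap.

The permutation null shuffles the class labels once per permutation
(class counts preserved exactly) and reruns a single 10-fold CV with
the same nested selection; the default is 100 permutations.
Real-vs-null significance is a one-sided Welch two-sample t-test of the
real repeat AUCs against the null AUCs — the two samples have different
sizes and variances, so a paired test is not applicable — with BH
adjustment across the seven tasks. Feature reports rank by mean
absolute standardized coefficient across all outer fits, ties
alphabetical.

All randomness derives from one master seed via `SeedSequence` spawning
(repeat seeds, fold seeds, permutation seeds).

## Group statistics

Continuous features across the three stability groups: one-way ANOVA
with Tukey's HSD post-hoc pairwise test (`statsmodels`
`pairwise_tukeyhsd`, which is Tukey–Kramer at unequal group sizes);
singleton groups are excluded with a warning; group means carry
normal-approximation 95% CIs. Binary motif features: Pearson chi-square
test of independence without continuity correction, with a warning when
any expected count falls below 5 and p = 1 for degenerate (zero
row/column) tables. Omnibus p-values are BH-adjusted jointly.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth per protein:

* **Half-lives** drawn from the two-component mixture on the log₂
  minute scale; defaults (7.64, 0.72) and (5.58, 2.0) with class counts
  set per cohort. Stable proteins have λ_deg = 0 exactly.
* **Trajectories** follow the decay equation with per-protein A ~
  U(0.85, 0.95) and B ~ U(0, 0.05). A + B ≤ 1 by construction, so the
  clean M/L and its complement H/L = 1 − M/L are valid proportions; the
  published pre-normalization M₀/L₀ scatter (≈ 1.02) refers to raw
  ratios, while A here is the post-normalization value, which cannot
  exceed 1. Observation noise is additive Gaussian (default SD 0.02) on
  both ratios independently, clipped to [0, 1]; each non-zero time
  point is dropped independently with probability 0.15 by default
  (t = 0 is always observed), mimicking peptides undetectable at some
  sampled time points.
* **Sequences** are iid uniform over the 20 residues with a fixed
  leading Met, lengths U{60, 600}; degron motifs can be planted at
  either terminus for feature tests. **Disorder strings** come from a
  two-state Markov chain (persistence 0.9, giving contiguous segments)
  with class-dependent stationary fractions (stable 5%, slow 8%, fast
  16%), encoding a mild disorder–instability association.
* **The interaction network** is preferential attachment (new nodes
  attach to m = 2 existing nodes with probability ∝ (degree + 1) ×
  class boost); the slow class gets boost 2 by default, making it
  stochastically more connected.

What the generator does *not* emulate: peptide-level quantification and
rollup, intensity-dependent or correlated noise, systematic (non-random)
missingness, label-incorporation kinetics, any mechanistic model of
recycling beyond the constant offset B, real interaction-network
topology beyond a degree-skewed random graph, and any sequence–feature
correlation beyond what is explicitly planted. Passing tests therefore
demonstrate correctness and calibration of the inference machinery
under the stated model, not robustness to the full complexity of real
MS data.

## Problem sizes

The test suite and `scripts/acceptance.py` use cohorts of 300–1,000
proteins, mixtures of n = 400, a 300 × 50 classifier design with 10 × 10
nested CV and a 10-permutation null, and 100–200 bootstrap resamples —
sizes at which every measured quantity (recovery error, calibration
rate, recovered means, AUCs) is stable to well within the asserted
margins while the full suite completes in minutes on one CPU.

## Known limitations

* The χ²₁ LRT reference is anti-conservative at six observations (see
  above); calls near the q = 0.05 boundary should be read accordingly.
* Slow half-lives (≳ 3 generations) are recovered with ≈ 15–20%
  relative error at the default noise level due to the B–λ_deg
  confound; extending the sampling window would be required to do
  better.
* The fast-component mixture mean is biased low by ≈ 0.2 log₂ units at
  n ≈ 400; component *assignments* (which depend on the posterior
  crossover, not the mean alone) are less affected.
* Disorder prediction is out of scope; the feature extractor consumes
  whatever per-residue calls it is given.
* The embedding is a PPMI/SVD factorization of walk co-occurrences, not
  SGD skip-gram; embeddings differ numerically from other node2vec
  implementations (only downstream, embedding-space structure is
  comparable).
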