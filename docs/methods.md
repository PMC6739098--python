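# Methods

This note records the statistical model behind `fcmlink`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

The response y is a per-sample functional-group concentration — HNA or LNA
cells per ml obtained by fixed-gate cytometry (or a productivity
measurement) — and the predictors are centered log-ratio (CLR) transformed
relative abundances of p taxa over n samples. The working model is sparse
and linear on the CLR scale:

    y_i = β₀ + Σ_{j ∈ S} β_j z_ij + ε_i,       |S| ≪ p,

and the scientific question is the support S, not the coefficients. Because
p > n, taxa are compositional and strongly correlated, and samples are
spatiotemporally blocked, support recovery uses stability selection with
the Randomized Lasso and all model assessment uses blocked cross-validation.

### Preprocessing

* Prevalence filter: keep taxon j iff it has ≥ `min_count` (5) reads in at
  least ⌈`min_fraction`·n⌉ samples (10%). Ceiling is used for the sample
  threshold; the filter runs at the OTU level before any aggregation.
* Rarefaction: uniform subsampling without replacement to an even depth
  (one multivariate-hypergeometric draw per sample); samples under the
  depth are dropped with a warning rather than erroring, so the caller sees
  exactly which samples left the analysis.
* CLR: zeros are replaced by δ = 1/p² and the row is *not* renormalized
  afterwards; then z_ij = ln x_ij − (1/p)Σ_k ln x_ik. Rows of z sum to zero
  by construction and the transform is invariant to positive rescaling of a
  row. Alternative zero-replacement schemes are out of scope.

### Randomized Lasso (stability selection)

For b = 1..B: draw ⌊n/2⌋ samples without replacement, draw per-variable
penalty multipliers w_j ∈ {α, 1} with probability ½ each, standardize the
predictor columns and the response *within the subsample*, and solve

    min_β ‖y′ − X′β‖² + λ Σ_j w_j |β_j|

for every λ on a fixed grid (default 100 log-spaced values in
[10⁻³, 10³]). The selection frequency per (λ, j) across the B fits is the
stability path; a taxon's RL score is the path maximum. Defaults: B = 500,
weakness α = 0.5.

Design notes:

* The objective carries no 1/(2n) factor; the soft-threshold level for
  coordinate j is λw_j/2, and β = 0 exactly once λ ≥ 2·max_j |x_jᵀy|.
  Because the score takes a maximum over a six-decade λ grid, results are
  robust to this convention.
* Standardizing the response inside each subsample is what makes a *fixed*
  λ grid meaningful: concentrations are O(10⁵–10⁶) cells/ml, and without
  unit variance on y the whole grid would sit far below the critical
  penalty, reducing the path to its λ→0 limit.
* Weakness is applied as the per-variable multiplier w_j (equivalently, a
  penalty drawn from {λ, λ/α} per variable).
* Tie-breaks in all rankings follow original column order, so runs are
  bit-reproducible for a fixed seed.

### The solver

The weighted Lasso is solved by cyclic coordinate descent on precomputed
Gram quantities (G = XᵀX, c = Xᵀy), which makes column-subset fits (for
recursive elimination) slicing operations rather than refits. Convergence
combines a maximum-coefficient-update tolerance (10⁻⁵ on standardized
scales for path fits; 10⁻⁸ for high-precision single fits) with a duality
gap bound relative to ‖y‖²; the gap test is what keeps the saturated
p > n end of the penalty path affordable. Warm starts run the path from
large to small penalties; an active-set sweep plus a full Karush-Kuhn-Tucker
pass admits violators. Zero-variance columns are assigned unit scale and
can never enter a model. Optima are verified in tests against closed forms
(orthonormal designs, the KKT zero bound, the unpenalized limit) and
against an independent reference implementation.

### Blocked evaluation: RCV² and RNCV²

Folds are pre-defined site-by-year groups (leave-one-group-out, LOGO),
which prevents spatiotemporal leakage. All reported performance is the
*pooled* R²: held-out predictions from every fold are concatenated and
scored as 1 − SSE/SST against the concatenated truth. Pooling is used for
both the flat (RCV²) and nested (RNCV²) schemes — per-group R² can be
undefined for small groups — and negative values are possible and
meaningful.

Within each training set the penalty is chosen on a per-training-set grid
of 400 log-spaced values spanning a 10⁻⁴ ratio below the critical penalty,
by pooled validation error over inner folds. Inner folds for penalty
selection are up to three group-blocked blocks (training groups dealt
round-robin), mirroring the common three-fold default for penalty tuning
while never splitting a group.

Recursive elimination ranks taxa by RL score, removes the lowest-ranked
(step 1 by default) and records RCV² at every retained size; the optimum is
*minimal-optimal*: the smallest size attaining the maximal RCV² (ties in
score broken by column order, ties in RCV² resolved toward fewer taxa).
Nested CV reruns the entire selection (stability selection + elimination)
inside every outer training set and predicts the held-out group with a
Lasso tuned on the selected subset. Inside nested CV the elimination uses a
geometric retained-size schedule (ratio 0.8) by default rather than
per-variable steps; the flat elimination keeps step 1. RL scores are
computed once per context and reused along the elimination path
(recomputation per step is available but not default).

### Boruta

Each iteration appends permuted "shadow" copies of the predictor columns,
fits a Random-Forest regressor (200 trees, p/3 candidate features per
split, minimum five samples per leaf, impurity importances) and records a
hit for every still-undecided variable whose importance exceeds the
maximum shadow importance. Hit counts are tested against Binomial(t, ½)
two-sided with a two-step correction (Benjamini-Hochberg across variables
plus a Bonferroni bound over the t tests performed on each variable);
significantly-high variables are confirmed, significantly-low ones
rejected and removed, the remainder end tentative. Default 300 iterations,
α = 0.05.

Two deliberate choices differ from common implementations and are worth
stating. First, the decision statistic is the binomial hit-count test, not
a t test on importances. Second, shadows are re-permuted copies of *all*
original columns every iteration, not only of the surviving ones: the
max-shadow reference must remain a maximum over a fixed number of noise
features, otherwise the hit bar collapses as variables are rejected and
late-surviving chance-correlated variables get confirmed against a handful
of shadows. With the fixed reference, pure-noise designs of the study's
shape confirm essentially nothing (this is asserted in the tests). The p/3
feature subsampling is interpreted against the original predictor count.

### Fingerprint correlations

Events are mapped to [0,1]² by asinh (cofactor 150, configurable) followed
by fixed min-max rescale; a polygon gate in this plane removes background
noise and a single fixed FL1 threshold splits cells into LNA/HNA. The
fingerprint is the exact Gaussian KDE (bandwidth 0.01 on the rescaled
scale, kernel factorized over channels) evaluated at the centers of a
128×128 grid and normalized to unit mass per sample, making bins
comparable across samples. Per bin and taxon, Kendall tau-b associates bin
density with relative abundance; constant bins are flagged NaN (undefined),
never zero. The normalization has a visible consequence that tests assert
explicitly: a region whose absolute density is static acquires a perfect
*negative* rank correlation with any taxon whose subregion grows, because
relative mass is conserved.

tau-b p-values use the large-sample normal approximation with tie-corrected
variance; an exact permutation p-value is available for n ≤ 8.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, with known
ground truth:

* **Community.** Per-taxon baseline log-abundances are Gaussian (SD 1.5 —
  log-normal abundances, realistic rank-abundance skew), shifted by
  site-by-year group effects (SD 0.15) and per-sample noise (SD 0.35);
  softmax gives the true composition; counts are multinomial at depth 9000
  (the upper end of typical even rarefaction depths). Groups are contiguous
  blocks of samples; defaults are 60 samples in 10 groups, 300 taxa.
* **Drivers.** Ten taxa per functional group (20% shared between the HNA
  and LNA sets) drawn from the dominant community members, echoing the
  observation that the taxa tracking cytometric populations tend to be
  abundant groups; dominance also keeps their CLR estimates nearly free of
  multinomial noise. Coefficients have magnitude Uniform(0.3, 0.6) and
  random sign. Drivers additionally co-vary as a guild: one latent
  per-sample factor per functional group loads on its drivers (SD 0.4)
  with the sign of each driver's effect. The response remains *exactly*
  linear in the driver CLRs; the factor only shapes the predictor
  covariance so that every driver is individually informative — without
  it, ten independent drivers sharing a fixed total signal are each
  statistically indistinguishable from the chance-correlation tail of ~290
  null taxa at n = 60, and no selection method could recover them.
* **Targets.** The default link is *identity*: the standardized linear
  index is scaled to cells/ml around a large baseline (4×10⁵ for HNA,
  3×10⁵ for LNA, 8×10⁴ per index SD; a floor at 10⁴ guards a ~5 SD tail).
  The noise SD is calibrated by bisection so that the *pooled
  leave-one-group-out* R² of the linear oracle (OLS of the response on the
  true driver CLR columns) hits a target, 0.6 by default — the same score
  the pipeline is judged by. A log link (log-linear response, positive by
  construction) is available; with multiplicative noise at comparable
  calibration the raw-scale pooled R² of even the oracle collapses, which
  is why the identity link is the default for raw-concentration responses.
* **Cytometry.** Three replicates per sample. Events per replicate are
  Poisson at the analysed volume (default 5 µl in the generator; the
  fingerprint studies use 20 µl) times the simulated concentration, drawn
  from a Gaussian mixture per threshold side: a broad base component, one
  tight subcomponent per driver placed on a shuffled lattice within its
  group's region (SD 0.04) with mixture weight proportional to the
  driver's relative abundance, plus ~5% background events outside the noise
  gate. Components are clipped to their side of the threshold, so gated
  counts recover the generating concentrations exactly up to Poisson noise.

What the generator does **not** emulate: instrument artefacts (spillover,
doublets, drift), phylogenetically structured effects, overdispersion
beyond group effects (a Dirichlet layer is not implemented), taxa whose
effect on cytometry is not mediated by abundance, and any nonlinear
taxon-response relationships. Passing tests therefore demonstrate that the
machinery recovers planted structure of the assumed form at realistic
sizes — not that real lakes satisfy those assumptions.

### Study conditions used by the tests and the acceptance script

The heavy checks run at n = 60, p = 300, 10 groups, 10 drivers, B = 100
subsample repeats (scaled down from the 500 default), oracle pooled R²
0.6. Fingerprint studies use 20 samples in 4 groups with *independent*
driver dynamics (guild factor 0): with strongly co-varying drivers the
max-|tau| bin of one driver can legitimately sit in a correlated driver's
subregion, so localization of the mapping machinery is only identifiable
when drivers fluctuate independently. Nested CV medians use 5 (calibrated)
and 3 (null) studies; Boruta validation 20 studies at 100 iterations;
the acceptance script uses slightly smaller multiplicities (its output
states each n).

## Known limitations

* With ~300 candidate taxa and 60 samples, a few null taxa are genuinely
  correlated with the response by chance (|r| up to ≈ 0.4). An
  all-relevant method *should* and does flag some of them: Boruta confirms
  0–3 such taxa per study even under the fixed shadow reference, and
  stability selection lets ≲1% of nulls cross score 0.5. This is a
  property of the sample size, not a defect of the implementations.
* RL scores from runs with B = 100 carry Monte-Carlo noise of roughly
  ±0.05–0.10 per score; rankings near the selection boundary move between
  seeds.
* The tau-b normal-approximation p-values are anti-conservative below
  n ≈ 10; use the exact option there.
* The FCS reader covers plain single-dataset FCS 3.0/3.1 list-mode files
  (float, double or fixed-width integer data); spillover matrices and
  multi-dataset files are out of scope.
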