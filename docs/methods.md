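# Methods notes

## The simulation model

`mimicbench` creates benchmarking data for differential abundance (DA)
testing by *editing* a count table rather than sampling one from a fitted
distribution. The rationale: taxonomic profiles from shotgun metagenomics or
16S sequencing are extremely sparse (60–95% zeros per sample), heavy-tailed
across features and overdispersed within features, and parametric simulators
that fail to reproduce these properties produce benchmark verdicts that do
not transfer to real studies. Editing real data sidesteps the modelling
problem: everything that is not edited keeps the empirical joint
distribution exactly.

### Signal implantation

For one simulated repetition with abundance scale *s* ≥ 1 and prevalence
shift *q* ∈ [0, 1]:

1. samples are split uniformly at random into two balanced mock groups;
2. `round(fraction · n_features)` features (default 10%) are selected
   uniformly — either from all features (`mode="all"`) or only from
   low-abundance features whose 75th count percentile is 0 (`mode="low"`);
3. **prevalence shift first**: for each selected feature,
   `round(q · #non-zero donor entries)` non-zero entries of the donor
   (non-target) group are exchanged with zero entries of the target group,
   capped by whichever side runs out ("if possible" semantics). The
   feature's total zero count over all samples is conserved;
4. **abundance scaling second**: non-zero target-group counts are multiplied
   by *s* and rounded half-up with a floor of 1.

The ordering (prevalence before abundance) is a deliberate choice the
underlying procedure leaves open: it guarantees that entries newly moved
into the target group also carry the abundance effect, so both effect types
point in the same direction. The rounding floor of 1 ensures scaling can
never silently change prevalence — otherwise the two effect types would be
conflated and the ground truth corrupted. Both policies are config-exposed
(`rounding=`).

Implanted features alternate their target group in sorted-id order
(`balanced=True`) so that the two groups keep near-identical library sizes
and no systematic compositional artifact is introduced. The one-sided
`implant_compositional` mode targets a single group and then rarefies each
sample whose total *increased* back to its original depth, deliberately
inducing spurious depletion of background features. (Samples whose totals
*decreased* — donors of prevalence exchanges — cannot be "rarefied up" and
are left as-is; with a pure abundance effect all totals are exactly
conserved.)

Each implanted feature's realized generalized fold change (gFC) is computed
on the final table; features with |gFC| < 0.001 are moved to the `rejected`
list and excluded from the ground truth. Note that at the null effect
(s = 1, q = 0) the realized gFC of a selected feature is sampling noise of
order 0.01–0.1, far above the 0.001 threshold, so null repetitions retain
their selected features as recorded (null) signals — they act as internal
negative controls, and the rejection rule in practice removes only
very-low-prevalence picks.

**Generalized fold change.** gFC = mean over the quantile grid
{0.05, 0.10, …, 0.95} of the per-group quantile differences of
log₁₀(relative abundance + 10⁻⁵), quantiles by linear interpolation
(type-7). Grid and pseudocount are conventions (the definition originates
in a meta-analysis context, not here) and are config-exposed; they are held
fixed for reproducibility.

### Confounding

`implant_confounder` repeats the implantation for an independent random
binary label on a feature set disjoint from the main truth.
`biased_resample` then draws n/2 cases and n/2 controls without
replacement, with the confounder-positive fraction (1+b)/2 among cases and
(1−b)/2 among controls (largest-remainder rounding). This mapping is chosen
because it makes the expected phi coefficient of the drawn subset equal *b*
exactly; infeasible quotas raise an error naming the limiting stratum and
the maximum feasible bias rather than silently rebalancing.

### Parametric comparison simulators

Multinomial (mean composition), uncorrelated negative binomial (per-feature
method-of-moments mean/dispersion; dispersion capped at 10⁸ when
variance ≤ mean) and Dirichlet (composition × concentration; draws scaled
by depth and rounded) simulators are included solely to demonstrate the
realism gap. The Dirichlet total concentration defaults to 100 (moderate
between-sample variation); it is not fixed by any reference and is
config-exposed. Correlation-aware variants are out of scope.

## The synthetic baseline

`generate_baseline` stands in for real cohort tables so the whole package
is testable offline. Model: per-feature log₁₀ means ~ Normal(0, 1.4)
(heavy-tailed rank-abundance curve); per-sample compositions are the
softmax of these log-means plus Normal(0, 1) per-entry noise; library
sizes are 10^Normal(4, 0.25) (≈ 3k–30k reads); counts are negative binomial
with size 0.5; extra zeros are masked with probability 0.3/(1+μ), so rare
features lose proportionally more entries. The defaults were chosen once to
give a mean post-filter sample sparsity ≈ 0.75, full mean–variance
overdispersion and a realistic depth spread, in the range shown for human
gut WGS profiles.

What the generator does *not* emulate: between-feature correlation
(taxon co-occurrence), phylogenetic structure, batch effects, and the
higher per-feature signal-to-noise of real cohorts. Consequently the
synthetic world is *harder* than real data for DA testing — per-repeat
discovery counts at the benchmark's effect sizes are small (recall ≈ 0.2 at
n = 200 for the Wilcoxon) — so green FDR results here say "the method does
not over-discover in a sparse overdispersed world", not "the method will
reach the same recall on a real cohort".

## DA tests: contracts and numerics

- All tests return one p-value per feature; features where a test cannot
  produce one (degenerate variance, all ties, non-converged fits) carry
  p = 1, which is also the convention for missing p-values before BH
  adjustment downstream.
- **Wilcoxon**: mid-ranks for ties; exact rank-sum enumeration when the
  pooled sample is ≤ 25 untied observations, otherwise normal approximation
  with tie-corrected variance and continuity correction. The stratified
  variant combines within-stratum centered rank sums with van-Elteren
  weights 1/(Nₛ+1); a single effective stratum delegates to the naive test.
- **Linear models**: shared-design OLS across features (the naive label
  F-test is algebraically the pooled t-test, F = t²); the fixed-covariate
  variant reports the label's partial t. The random-intercept variant fits
  statsmodels `MixedLM` per feature (REML) and reports Wald p-values from
  the normal approximation. The reference implementations use Satterthwaite
  degrees of freedom; Satterthwaite is not available in the installed stack
  and at the benchmark's sample sizes (n ≥ 50) the df correction is
  negligible for the label contrast. Non-convergence falls back to the
  fixed-effect p with a flag; a single-level covariate reduces to the naive
  model.
- **Moderated t**: per-feature residual variances are shrunk toward a
  common prior, s̃² = (d₀s₀² + d·s²)/(d₀+d), with (d₀, s₀²) estimated by
  moment-matching of log residual variances (trigamma inversion by Newton
  iteration, tolerance 1e-8); the moderated t has d₀+d df. d₀ → ∞ pools all
  variances; d₀ = 0 recovers the ordinary t.
- **ANCOM W**: Wᵢ counts features j ≠ i whose pairwise log-ratio differs
  between groups at the inner level 0.05. W ≥ 0.7·(m−1) maps linearly into
  (0, 0.05) ("discovery"), lower W linearly into [0.05, 1]; only the
  ordering and the 0.05/threshold anchors are contractual. Scores are
  flagged `is_pvalue=False` and bypass multiple-testing adjustment.
- Default transforms: rank/ECDF tests (Wilcoxon, KS) on TSS; moment-based
  tests (t, LM, moderated-t) on TSS.log (pseudocount 10⁻⁵ on relative
  abundances; clr uses +1 on counts). All overridable.

## Realism diagnostics

PERMANOVA uses Euclidean distances on log₁₀(TSS + 10⁻⁵), pseudo-F from
between/within squared-distance sums, and p = (1 + #{F_perm ≥ F}) / (1 +
n_perm). The real-vs-simulated classifier z-standardizes log₁₀ relative
abundances and scores an L1-penalized logistic regression (penalty chosen
by inner 3-fold CV over C ∈ {0.01, 0.1, 1, 10}) by repeated stratified
k-fold CV; the penalty grid is a design choice — the contract is only
"separable vs not".

**Twin-aware cross-validation.** Implantation output reuses the baseline's
sample ids, and at small effect sizes a simulated sample is (nearly)
identical to its real twin. If twins land on opposite sides of a CV split,
the model memorises the twin's class and scores the held-out copy
systematically wrongly, driving AUROC far *below* 0.5 even for perfectly
indistinguishable data. The classifier therefore uses grouped stratified
folds that keep same-id samples together; with exact duplicates this yields
AUROC 0.5 as it should. Parametric simulations have fresh ids and are
unaffected.

## Evaluation conventions

Discoveries are p_adj < 0.05 (strict); observed FDR is 0 when there are no
discoveries (a method that discovers nothing makes no false discoveries);
recall is undefined (an error) for an empty truth set. The FDR-sufficiency
flag marks a method insufficient when more than 10% of settings have mean
observed FDR above 10%; setting means aggregate over all repeats and
subsamples first.

## Known limitations (measured on the synthetic world)

- **KS null calibration.** The two-sample KS asymptotic p-value is strongly
  conservative on zero-heavy data (ties collapse the null distribution of
  D): at the null effect its fraction of raw p < 0.05 is ≈ 0.01 rather than
  ≈ 0.05. R's `ks.test` behaves identically (it warns about ties). The
  acceptance suite asserts the two-sided calibration band for every test
  and the KS case fails honestly.
- **Random-intercept model under strong confounding.** With a single binary
  confounder, REML frequently estimates the random-intercept variance at
  the τ² = 0 boundary for features whose confounder association is modest,
  collapsing the fit to the naive model; under bias 0.6 this admits
  confounder-correlated sampling noise and the observed FDR (≈ 0.14 vs
  ≈ 0.045 unconfounded, 25–50 repeats) exceeds twice its unconfounded
  value. lme4/lmerTest produce the same boundary estimates for 2-level
  grouping factors. The fixed-effect adjustment (label + confounder)
  controls FDR in the same setting (≈ 0.05), and the stratified Wilcoxon
  stays within the 2× band. The corresponding acceptance assertion fails
  honestly.
- Per-repeat observed FDR at these effect sizes rests on few discoveries
  (2–5), so single repeats are coarse; aggregate over many repeats (or pool
  discoveries) before drawing conclusions.
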