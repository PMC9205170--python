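# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Dose-response fitting

The four-parameter logistic (4PL) is fitted to replicate-mean viabilities by
bounded least squares (`scipy.optimize.curve_fit`, trust-region reflective).
Parameters and bounds: top and bottom in [0, 120] % (top above 100 absorbs
plate normalization drift), hill slope in [0.1, 10], IC50 within one decade
of the tested dose range. Initialization: top = max mean viability,
bottom = min, hill = 1, IC50 = dose nearest the half-range viability — a
standard robust start for 8-point screens. A fit is reported
`converged=False` with the IC50 *censored* at the maximal dose (100 µM on
the default grid) when the observed inhibition at the top dose stays below
50% or the optimizer fails or returns bottom ≥ top; this mirrors screens
that report IC50 "up to the highest tested dose" rather than extrapolating.

Emax is defined observationally as 100 − mean viability at the maximal dose,
floored at 0. AUC has no universal formula for dose-response curves; here it
is the trapezoid of viability normalized by the fitted top, over log₁₀ dose
rescaled to [0, 1], clipped to [0, 1]. This makes AUC comparable across dose
grids; it is one defensible choice among several and should not be compared
numerically against AUCs computed by other conventions.

Classification boundaries on log₁₀IC50 (µM) default to
(0.14, 0.57, 0.98, 1.24, 2.00) with half-open [low, high) intervals: a value
exactly at a shared endpoint belongs to the more resistant side's lower
category (0.57 → moderate). Values below 0.14 are still "strong" and above
2.00 still "non", so the map is total. All five boundaries are arguments.

ICx inversion solves the 4PL algebraically for the dose giving x% inhibition
relative to the fitted top; it raises when the curve's lower plateau leaves
less than x% attainable, which is the correct behavior when choosing
IC10–IC40 effective doses for combination partners on shallow curves.

## Xenograft %TGI

%TGI uses per-arm median volumes at baseline and endpoint. The formula is
growth-normalized: identical fold-growth in both arms gives exactly 0,
treated stasis exactly 100, regression > 100. The endpoint defaults to the
last day shared by both arms (configurable), medians of even mouse counts
are midpoints of the central pair, and a control arm with no net volume
change raises a degenerate-control error instead of returning an unstable
ratio. Responder status is the ≥ 50% rule only; inferential comparison of
growth curves (mixed models / repeated-measures ANOVA) is deliberately out
of scope.

## Differential expression and LOOCV consensus

Size factors are median-of-ratios: over features with positive counts in
every sample, each sample's factor is the arithmetic median of
count / geometric-row-mean. Note that scaling one library scales every
feature's geometric mean by the m-th root, so *absolute* factors are only
equivariant up to that common drift; factor ratios are exactly equivariant.

The per-fold DE engine is intentionally simple: a Wald-type two-sample t
(pooled variance, t reference with n₁+n₂−2 df) on log₂(normalized count + 1),
after excluding features with mean normalized count below 5. It is not a
negative-binomial shrinkage model; at n = 8 vs 8 with a planted |log₂FC| = 3
the two agree on what matters here (which features pass a FC ≥ 2,
adjusted p < 0.05 filter), but on real data with outlier counts or strong
mean–dispersion structure a dedicated NB model is more powerful. P-values
are Benjamini–Hochberg adjusted over the tested features.

Ranking is fully deterministic: ascending adjusted p, ties broken by
descending |log₂FC|, then feature id. Each leave-one-out fold takes the top
k (default 100) features *passing the DE filter* — the filter matters: the
persistent tail of near-significant null features is otherwise stable enough
across folds (15 of 16 samples shared) to contaminate the all-fold
intersection. The consensus is the intersection of all n fold lists.

Single-feature predictors are logistic regressions on log₂ normalized
expression with a mild ridge penalty (L2, strength 1e-4) so that completely
separated features — the expected situation for a perfect predictor —
retain finite coefficients. The score is leave-one-out classification
accuracy; note that LOOCV accuracy on *null* balanced data is pessimistically
biased below 0.5 (each held-out sample leaves training tilted against its
own class), so chance-level features score ≈ 0.3, not 0.5. Features with
constant raw counts are skipped: after normalization they echo library size
and would otherwise act as spurious predictors. The validation panel wraps
scikit-learn classifiers (logistic regression, random forest, k-NN, Gaussian
naive Bayes, decision tree, MLP, linear SVM), each standardized within the
training fold where scale-sensitive.

## Connectivity scoring

The enrichment statistic is the classic signed KS form: with t tag features
at 1-based ranks pos₁ < … < pos_t among n,
a = max_j(j/t − pos_j/n), b = max_j(pos_j/n − (j−1)/t), statistic = a if
a > b else −b. The combined raw score is (ks_up − ks_down)/2 when the two
statistics disagree in sign and 0 otherwise; scores are normalized so the
largest |mean raw| in the scored collection is ±100. Multiple instances of a
perturbagen are averaged with their spread reported. Exact antisymmetries
hold for the combined score (reversing every profile, or swapping the
query's up/down sets, negates scores); the single-tag-set statistic is
antisymmetric only up to the 1/n rank discreteness. Profiles covering less
than half of a tag set are excluded from scoring with a warning; partial
losses above that are dropped tag-wise with a warning. Candidate selection
intersects perturbagens scoring at or below the threshold (default −95) in
both query routes, ordered by mean score.

The reference collection in the bundled pipeline is synthetic: random
rankings plus planted "reverser" instances built by reversing the DE-signed
feature ranking with 2% rank jitter. It stands in for a real perturbagen
database structurally (rankings, multi-instance averaging, reversal
geometry) but carries no pharmacology.

## Concordance statistics

Confusion metrics come from the 2×2 collapse (OS/OR PDO class vs clinical
responder status); undefined metrics (empty margin) are reported as missing,
never as zero, and display rounding (one decimal of a percent) is separated
from stored full precision. Fisher's exact test is the standard two-sided
sum of hypergeometric probabilities ≤ that of the observed table. The
Cochran–Armitage trend test uses equally spaced integer scores over the
ordered categories, the population-variance (N-denominator) convention and
no continuity correction, reported one-sided; both choices are exposed.
Because the exact permutation null is discrete at n = 17, the asymptotic p
is validated to lie within the null's [P(T < T_obs), P(T ≤ T_obs)] bracket
and near the mid-p rather than against a single permutation quantile.

## Synthetic generators

Defaults encode the study design the pipeline targets: the 8-dose
oxaliplatin grid (0.03–100 µM) in four replicates; an 8 OR vs 8 OS count
matrix; xenografts with 5 mice per arm, initial volumes uniform in
80–100 mm³ and measurements at 3-day intervals over the dosing period; a
17-patient outcome cohort. Choices where no design value exists: viability
noise is additive Gaussian on the percent scale (default SD 5), clipped at
0 — adequate for fit-recovery testing though real CellTiter-Glo error is
closer to multiplicative; counts are negative binomial parameterized by
mean and dispersion α (variance µ + αµ², α = 0 degenerates to Poisson) with
per-feature baselines log-normal around 100 and library factors uniform in
[0.7, 1.4]; default dispersion is 0.1, a typical inter-line bulk RNA-seq
value, while planted-recovery checks use α = 0.01 where planted features
are near-deterministic separators; xenograft growth is exponential per arm
(control 0.12/day, treated 0.04/day) with multiplicative Gaussian noise
(CV 0.1). Every generator consumes an explicit scenario + seed through a
private RNG stream, so outputs are bitwise reproducible.

What the generators do not emulate — and therefore what green tests do not
establish about real data: mean–variance trends and outlier counts in
RNA-seq, correlated features, plate-position effects, tumor growth
deceleration (Gompertzian plateaus), informative dropout of mice, and any
real drug–gene connectivity.

## Problem sizes and determinism

The bundled test and demo scenarios are sized for single-CPU runs: 2,000
features × 16 samples for signature discovery (16 LOOCV folds), 50 random
truth draws for 4PL recovery, 20-profile connectivity collections, and a
10⁵-draw permutation null for the trend test. These sizes were chosen so
each property is measured with comfortable Monte-Carlo margin while the
whole suite stays fast. IC50 recovery under 5% noise is reported as a
per-draw check at the default seed; across seeds, the *maximum* error over
50 draws occasionally exceeds 25% when a shallow-slope draw (hill ≈ 0.8)
lands near the grid edge — the median error stays near 5%.

## Limitations

- The DE statistic is a simplified Wald t, not an NB shrinkage model; the
  consensus machinery is agnostic to the engine, which can be swapped.
- The real study's gene lists (36 DEGs / 33 DETs, 18 single-gene models)
  depend on the deposited sequencing data and are not reproduced here; the
  pipeline reproduces the *procedure* and its recovery behavior on planted
  ground truth.
- Connectivity scoring implements the documented KS statistic against
  user-supplied or synthetic profiles; it does not query any hosted
  perturbagen database.
- The trend and Fisher tests assume independent patients; clustered
  sampling (multiple PDOs per patient) would require adjustment.
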