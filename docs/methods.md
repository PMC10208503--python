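# Methods

## The causal model and its queries

The analysis assumes a structural causal model over twelve variables: a
latent early brain injury; the four neurological/physical impairment scores
it drives (spasticity, strength, selective motor control, dynamic motor
control); demographics (age, sex, height, mass); walking speed; the gait
deviation index (GDI); and net metabolic power. The bundled edge list
(`gaitcausal/data/study_dag.txt`) encodes: injury → each impairment; age and
sex → body size; age/height/mass → each impairment, speed, GDI and power;
each impairment → speed, GDI and power; speed → GDI and power only; GDI →
power. Walking speed deliberately has no other descendants, so its total
effect equals its direct effect. The exact arrow set of the original study
figure is not published; this reconstruction is the sparsest graph
consistent with the published prose and adjustment-set table, which it
reproduces exactly, and it ships as data so alternatives can be swapped in.

d-separation is decided by reachability on the moralized ancestral graph
(equivalent to path blocking; verified against a brute-force all-paths
oracle in the tests). Testable implications are a basis set: for each
non-adjacent observed pair, one statement with the smallest (then
lexicographically first) separating set of observed ancestors, capped at
size 8 with an explicit error if the cap ever binds. Minimal adjustment sets
for the *total* effect are found by smallest-first subset search over
observed non-descendants of the exposure, testing the backdoor criterion as
d-separation in the graph with the exposure's outgoing edges removed and
pruning supersets of hits; an empty result list signals "not identifiable by
covariate adjustment" (a valid empty set is returned as `[frozenset()]`).
Latent nodes are never admissible; mediators are never conditioned on.

## Summary scores

Polychoric correlations use the two-step estimator: thresholds from the
inverse normal of cumulative marginal proportions, then a bounded 1-D
maximization of the bivariate-normal cell log-likelihood, clipped to
±0.999. The 12×12 item matrix is estimated pairwise-complete and repaired
to the nearest positive semidefinite correlation matrix by eigenvalue
clipping with the unit diagonal restored. Scores are the first eigenvector
applied to centred/scaled integer item codes — not latent normal scores — a
simple, monotone and reproducible convention, computed for complete cases
only, standardized to mean 0 / SD 1, and oriented to correlate positively
with the mean item rating (higher spasticity score = more spastic, higher
strength score = stronger). Net metabolic power is
`20.1 J/mL O₂ × (VO₂,walk − VO₂,rest)`; a negative value is returned with a
warning rather than dropped. For effect analysis, factors are z-scored
column-wise (missing-aware) and the spasticity axis is flipped so that more
positive always means less impaired; the scaler records one original-units
SD per factor.

## Plausibility testing

Each implied independency is evaluated as the correlation of least-squares
residuals of the two variables on the conditioning set (intercept included;
Pearson correlation when the set is empty), on complete cases per
implication — the per-implication missing-data policy is a convention, as is
coding sex 0/1. No multiple-testing correction is applied: the criterion is
a fixed ±0.3 cutoff on the coefficients themselves. Implications that
cannot be evaluated (insufficient cases, collinear conditioning sets) are
flagged in the report rather than fatal.

## Sum-of-trees regression

BART is implemented from scratch as a backfitting Gibbs sampler. The
response is rescaled to [−0.5, 0.5]; each of *m* trees carries the
structure prior P(split at depth d) = α(1+d)^−β (α = 0.95, β = 2), leaf
values are a priori N(0, σ_μ²) with σ_μ = 0.5/(k√m), and σ² has a scaled
inverse-χ²(ν, λ) prior with λ solved on the χ² quantile function so a
data-based estimate (least-squares residual SD on complete cases, response
SD fallback) sits at the prior's q quantile. Per iteration, each tree is
updated by a Metropolis–Hastings grow/prune/change proposal
(0.28/0.28/0.44; uniform over usable variables and interior split values;
change moves act on singly-internal nodes) against its partial residual,
followed by conjugate draws of leaf values and of σ². Leaves must hold at
least 5 training rows. Missing predictor values are routed by a per-split
missing-direction flag sampled with the split (missingness incorporated in
attributes), so informative missingness is usable signal; prediction with
missing values requires a model trained that way. Chains default to 1000
burn-in + 1000 kept draws; a fixed seed makes the posterior bit-identical
across runs on one machine. This sampler cannot replicate the random-number
stream of other BART implementations, so any comparison to externally
reported fit statistics is tolerance-based, never seed-based. Pseudo-R² and
RMSE are computed from posterior-mean predictions, in-sample by default.
K-fold cross-validated RMSE selection over a config grid is available
(ties break toward fewer trees, then smaller k); the default grid is
k ∈ {2,3,5} × (ν,q) ∈ {(3,0.9),(3,0.99),(10,0.75)} × m ∈ {50,200}.

## Accumulated local effects and effect sizes

First-order ALE with K = 40 quantile bins by default (duplicate edges
merged, bins reduced for discrete factors): per-row prediction differences
between bin edges, averaged per bin, accumulated, and centered so the
curve's sample-weighted mean is zero (piecewise-linear interpolation at the
sample points). Rows missing the target factor are dropped for that
factor's curve; other-column missingness is the model's business.
Uncertainty bands are pointwise posterior quantiles over per-draw ALE
curves (default; an evenly thinned subset of ≤ 200 draws is used, and at
least 20 draws are required). A nonparametric bootstrap mode — resample
rows, refit, recompute — is provided but off by default because the refits
are costly. The effect size of a factor is the range (max − min) of its
interpolated curve over the factor's [2.5th, 97.5th] percentile window, in
watts; it is invariant to constant shifts of the curve and to linear
rescaling of the factor axis.

## Pipeline

`run_analysis` chains the steps: accept or compute summary scores; test
plausibility (warn and proceed on failure by default, hard-fail
configurable); derive adjustment sets (non-identifiable exposures are
reported and skipped); z-score factors; fit one model per distinct
predictor set ({exposure} ∪ adjustment set — two models under the bundled
graph); compute ALE curves, effect sizes and the five-factor ranking.
Walking speed's curve is computed from the GDI model, labeled a direct
effect, and excluded from the ranking. Model hyperparameters default to
m = 50 trees with k = 5, ν = 3, q = 0.99 and missing-data handling on;
`--cv` switches on grid selection. Reports serialize to JSON and Markdown;
curves export as tidy CSV. Everything is deterministic under a fixed seed.

## Synthetic cohort generator

The generator samples age (truncated normal, 2–18 y), sex (56.2% male) and
a standard-normal latent injury severity, then propagates frozen structural
equations in the graph's topological order: height linear in age and sex;
mass a power law in height with lognormal dispersion; impairment scores
linear in severity with small size terms; speed linear in the standardized
impairments and demographics (floored at 0.05 m/s); GDI sigmoidal
(amp·tanh) in a weighted impairment/speed index, so it plateaus at the
extremes; and power as mass- and speed-dependent terms plus sigmoidal
impairment/GDI terms and an inverted-U (Gaussian bump) strength term, with
18 W residual noise and a 5 W floor. Location/scale anchors and the default
coefficients were calibrated once against the published cohort's marginals
(median GDI 71.1, net power 124.2 W, speed 0.79 m/s, GMFCS proportions,
missingness rates) and then frozen; the intended effect magnitudes mirror
the published ordering with clear separation (GDI ≈ 57 W over its middle-95%
window, then SMC ≈ 31, DMC ≈ 26, spasticity ≈ 20, strength ≈ 13). GMFCS
levels are severity terciles at the published proportions. Missingness is
MCAR at the published rates by default; a MAR option ties DMC missingness to
GMFCS level (clinically, more involved children more often skip the EMG
protocol). Ordinal exam items are thresholded noisy copies (loading 0.8) of
each domain's latent severity; a child whose summary score is masked also
loses exam items so the two tables agree.

Ground truth: because the structural equations are known, any
do-intervention is evaluated by paired Monte Carlo — regenerate exogenous
draws, pin the factor in both arms, let speed/GDI/power respond, and
average the power contrast. On fully linear configurations this matches the
hand-computed path rule, which the tests verify.

What the generator does *not* emulate: raw kinematic, EMG or
breath-by-breath signals (summary columns are generated directly);
GMFCS IV/V children; repeat visits; measurement error in demographics; and
any treatment or longitudinal structure. Passing the recovery tests
therefore shows the estimator chain is faithful under the assumed model at
realistic scale and missingness — not that the clinical conclusions of any
particular real cohort are correct.

## Validation settings and numerical choices

The end-to-end recovery check (tests and acceptance script) runs the
pipeline on the default cohort (n = 2000) with a 200-tree forest and the
default k = 5 shrinkage. The four impairments are strongly collinear (one
latent severity drives all four), and with only 50 trees the forest shares
split credit among them, attenuating each factor's individual ALE by
25–50%; 200 trees — a value inside the standard CV grid — removes that
attenuation, while k = 5 keeps the small strength effect from being inflated
by noise. With these settings all five estimated effect sizes land within
25% of the Monte-Carlo ground truth and the true ranking is recovered.
Problem sizes used by the checks: cohorts of 2000 (analysis) and 5000
(marginals/plausibility), 30 000 Monte-Carlo draws for truth contrasts, 500
train/test rows for the nonlinear regression benchmark.

Other numerical conventions: polychoric estimates clipped to ±0.999 and
optimized to 1e-5; PSD repair by eigenvalue clipping; σ² floored at 1e-18
so constant responses degenerate gracefully; ALE centering exact to
interpolation error; report hashing over sorted JSON for determinism
checks.

## Known limitations

* The bundled DAG is a reconstruction; conclusions are conditional on it,
  and the package deliberately makes swapping in alternatives trivial.
* Partial-correlation plausibility tests are linear; a nonlinear dependence
  that leaves partial correlations small would go undetected.
* The MH `change` proposal uses a symmetric-likelihood acceptance that
  ignores the (equal-cardinality) split-rule proposal ratio; with uniform
  rule proposals on a fixed node this is exact, but growable-leaf counting
  approximates reversibility when a proposed rule has no valid split.
* Effect sizes are ranges of curves, so they inherit the upward bias of a
  max − min statistic under estimation noise; intervals from posterior
  draws quantify but do not remove this.
* Single-visit, cross-sectional semantics only: effects are do-intervention
  contrasts under the assumed graph, not predictions of longitudinal
  treatment response.
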