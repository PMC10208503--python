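# gaitcausal

Causal-effect analysis of net metabolic power during walking in ambulatory
children with cerebral palsy (GMFCS levels I–III).

Children with cerebral palsy expend two to three times more metabolic energy
walking than typically developing peers, and clinicians must decide which of
several inter-related treatment targets — gait kinematics (summarized by the
gait deviation index, GDI), dynamic and selective motor control (DMC, SMC),
spasticity, or muscle strength — most influences that cost. Randomized
experiments that change one factor while holding the others fixed are
impossible, so this package estimates *total* causal effects from
observational gait-lab cohorts by combining four ingredients:

1. **A structural causal model.** A directed acyclic graph over the latent
   brain injury, the five clinical factors, walking speed, and the
   demographic confounders (age, sex, height, mass). The graph is queried
   for its testable implications (d-separation) and for minimal backdoor
   adjustment sets: for exposure X and outcome Y, a smallest set **Z** of
   observed non-descendants of X with X ⊥ Y | **Z** in the graph stripped of
   X's outgoing edges. For the bundled study graph this reproduces the
   published adjustment table — one set for GDI (including walking speed)
   and one shared set for the four impairments — so only two regression
   models are needed.
2. **Polychoric-PCA summary scores.** Item-level ordinal exams (Ashworth
   spasticity 1–5, Kendall strength 1–5, selective motor control 0–2; six
   muscle groups, both sides) are reduced to one score per domain via the
   first principal component of the pairwise polychoric correlation matrix,
   since ordinary PCA is biased on ordinal codes. Net metabolic power is
   walking minus resting oxygen uptake converted at 20.1 J/mL O₂.
3. **Plausibility testing.** Every conditional independence the graph
   implies is checked against the data by partial correlation; the model is
   plausible when all |r| fall inside the conventional ±0.3 cutoff.
4. **Sum-of-trees regression + accumulated local effects.** Net power is
   regressed on {exposure} ∪ adjustment set with Bayesian additive
   regression trees (BART: a sum of m regularized trees fitted by
   backfitting MCMC, with native missing-data routing), and each factor's
   effect is read off as an accumulated-local-effects (ALE) curve — local
   prediction differences within quantile bins, accumulated and centered —
   which stays unbiased under the strong collinearity between impairments.
   The scalar **effect size** is the range of the curve over the factor's
   middle 95% sample window, in watts, with posterior uncertainty bands.

A structural-equation cohort generator with known do-intervention ground
truth (`gaitcausal.synthetic`) emulates the study conditions — published
marginals, missingness rates (32.1% DMC, 18.3% spasticity, 17.7% strength,
17.5% SMC, 0.6% GDI), sigmoidal factor→power links with plateaus, an
inverted-U strength term — and is the test bed for the whole pipeline.

## Worked example

```bash
gaitcausal simulate --n 500 --seed 7 --out demo
gaitcausal report --cohort demo/cohort.csv --seed 42 --out demo/results
```

prints (abridged):

```
## Model plausibility
max |partial r| = 0.116 (cutoff 0.3) — plausible

## Fit metrics
- model A: pseudo-R² = 0.92, RMSE = 16.49 W
- model B: pseudo-R² = 0.89, RMSE = 19.61 W

## Effect sizes (range of the ALE curve over the middle 95%)

| rank | factor | effect (W) | 95% interval |
|---|---|---|---|
| 1 | GDI | 49.8 | [36.7, 63.3] |
| 2 | DMC | 26.4 | [17.8, 42.9] |
| 3 | SMC | 19.5 | [11.8, 38.3] |
| 4 | Spasticity | 15.4 | [8.2, 33.2] |
| 5 | Strength | 6.3 | [2.1, 20.8] |
```

Reading: the data are consistent with the causal model (every implied
conditional independence has |partial r| < 0.3). Model A predicts net power
from GDI plus its adjustment set; model B serves the four impairments.
Changing a child's GDI across its clinically observed range moves expected
net power by ~50 W — roughly twice the next factor — while strength moves it
least, matching the qualitative conclusion that gait pattern and motor
control dominate the metabolic cost of walking. (At n = 500 the intervals
are wide; analyses at cohort scale, n ≈ 2000, tighten them substantially.)

The same analysis is available as a library call:

```python
from gaitcausal.pipeline import run_analysis
from gaitcausal.synthetic import SyntheticConfig, generate_cohort

cohort, exams, truth = generate_cohort(SyntheticConfig(n=2000, seed=0))
report = run_analysis(cohort)
print(report.to_markdown())
```

To analyze a real cohort table (CSV or XLSX), supply a column-mapping config
(`{"column_map": {"GDI": "gdi_score", ...}}`) to `gaitcausal report
--cohort cohort.xlsx --config map.json`.

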