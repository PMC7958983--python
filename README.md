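# ipvcooc

Co-occurrence analysis and radial visualization of intimate partner
violence (IPV) survey data.

## What problem this addresses

Violence in a relationship rarely comes in one form.  Survey instruments
such as the National Intimate Partner and Sexual Violence Survey record,
for each survivor, ordinal past-year frequencies (0 = never … 4 = more
than fifty times) on dozens of items spanning physical violence (PV),
psychological aggression (PA) and sexual violence (SV) — plus a single
very high-frequency name-calling item that behaves as its own construct,
micro-aggression (MA).  `ipvcooc` is a tested, reusable pipeline for
asking: *which types of violence co-occur, how intense are they jointly,
and how do trauma symptoms and health problems distribute over that
space?*  It is written for quantitative social scientists and
epidemiologists working with survivor-by-item ordinal matrices.

Because such microdata are restricted-access, the package ships a
synthetic cohort generator (a latent-Gaussian ordinal copula with
calibrated score-scale correlations) so every stage runs and is tested
end to end with known ground truth.

## The methods at its core

Given the filtered survivor-by-item matrix *R* ∈ {0..4}ⁿˣ³⁹ and per-type
scores *s_T(i)* (the mean response over type *T*'s items):

- **Co-occurrence.** Survivor *i* is "high" in type *T* iff
  *s_T(i) > s̄_T* (strict, population mean).  Each type pair gets a 2×2
  table (n_HH, n_HL, n_LH, n_LL), the odds ratio
  OR = n_HH·n_LL / (n_HL·n_LH), the log-scale standard error
  SE = √(1/n_HH + 1/n_LL + 1/n_HL + 1/n_LH), intervals
  [OR·e^{−zSE}, OR·e^{+zSE}] (z = 1 `literal`, z = 1.96 `wald95`), and
  the independence baseline E[N_HH] = n_H(T)·n_H(T′)/n.
- **Item network.** An edge joins two items when the Pearson correlation
  of their response columns exceeds 0.2 (strict); summaries report
  connected components, degree and cross-degree (edges to other types).
- **Radial projection.** Scores are rank-normalized to r_T ∈ (0,1]
  (percentile ranks, average ties).  Treating (r_PV, r_PA, r_SV) as RGB
  channels, the hue/lightness part of the HSL color transform gives
  Intensity = (max + min)/2 and a hue-like type angle; survivors land at
  (x, y) = Intensity·(cos θ, sin θ), so radius is violence intensity and
  angle is violence type.  Ties across all three channels are
  "achromatic": intensity is defined, the angle is not.
- **Subgroups.** Euclidean K-means on the raw 39-item profiles, best of
  100 restarts by total within-cluster distance, K chosen by the
  Calinski-Harabasz index; subgroup heterogeneity (mean pairwise
  distance) is compared against a permutation null band from random
  survivor groups of the same size.
- **Outcomes.** Health-problem and trauma-symptom category scores are
  item means, then averaged per polar bin of the radial plane and
  summarized per subgroup.

## Worked example

```python
from ipvcooc import (CohortSpec, ItemCatalog, all_pairs, compute_type_scores,
                     dichotomize, filter_survivors, generate_cohort,
                     radial_points, type_correlations)

cohort = generate_cohort(CohortSpec(n_survivors=873, seed=7))
matrix = filter_survivors(cohort.responses)
scores = compute_type_scores(matrix, ItemCatalog.default())
flags = dichotomize(scores)
r, p = type_correlations(scores)
for res in all_pairs(flags, ci_style="wald95"):
    a, b = res.type_pair
    print(f"{a}-{b}: OR={res.odds_ratio:.2f} CI=[{res.ci_low:.2f}, {res.ci_high:.2f}] "
          f"r={r.loc[a, b]:+.3f}")
```

prints

```
PV-PA: OR=4.57 CI=[3.25, 6.43] r=+0.463
PV-SV: OR=0.75 CI=[0.45, 1.25] r=-0.024
PV-MA: OR=2.21 CI=[1.59, 3.07] r=+0.175
PA-SV: OR=1.23 CI=[0.80, 1.87] r=+0.015
PA-MA: OR=3.79 CI=[2.79, 5.14] r=+0.411
SV-MA: OR=0.85 CI=[0.55, 1.29] r=-0.025
```

Reading this: physical violence and psychological aggression strongly
co-occur (OR ≈ 4.6, interval well above 1; score correlation ≈ 0.46,
matching the generator's 0.45 design target), micro-aggression co-occurs
with PA more than with PV, and sexual violence is essentially decoupled
from everything else (ORs straddling 1, near-zero correlations) — the
qualitative structure the default cohort is built to emulate.
`radial_points(scores)` then yields each survivor's (intensity, angle,
x, y) for plotting or polar binning.

The same pipeline is available from the shell:

```bash
ipvcooc simulate --n 873 --seed 7 --out cohort.csv --outcomes outcomes.csv
ipvcooc score    --matrix cohort.csv --out scores.csv
ipvcooc cooccur  --scores scores.csv --ci-style wald95 --out cooccur.json
ipvcooc radial   --scores scores.csv --out radial.csv
ipvcooc cluster  --matrix cohort.csv --k auto --out clusters.csv
```

## Layout

- `src/ipvcooc/cohort.py` — matrix loading/validation, item catalog and
  reassignment, filtering, type scores, item frequencies
- `src/ipvcooc/synthetic_data.py` — latent-Gaussian ordinal cohort
  generator with correlation calibration and planted-regime mixtures
- `src/ipvcooc/cooccurrence.py` — dichotomization, 2×2 tables, odds
  ratios, score correlations
- `src/ipvcooc/item_network.py` — item correlation network and summaries
- `src/ipvcooc/radial.py` — rank normalization, HSL-style transform,
  PCA projection, polar binning
- `src/ipvcooc/subgroups.py` — K-means, K selection, heterogeneity and
  its permutation null
- `src/ipvcooc/outcomes.py` — outcome category scores, overlays,
  per-subgroup distributions
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations
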