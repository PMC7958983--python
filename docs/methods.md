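# Methods

This note documents the statistical model behind `ipvcooc`, the defaults
it ships with, the numerical conventions that matter, and what the
synthetic test bed does and does not establish about real survey data.

## Data model

The unit of analysis is a survivor-by-item matrix with ordinal entries in
{0..4}, where 0 means an item was never experienced in the past year and
1–4 encode increasing frequency bands.  These codes are treated directly
as numbers, i.e. as a rough log-frequency scale; no back-transformation
to counts is attempted.  Survivors with no nonzero response on any of the
39 violence items are removed before analysis, and all population
statistics (score means used for dichotomization, cohort outcome means)
are computed over this filtered cohort.

Missing responses default to 0 ("never") with a logged count — the
conservative reading for a screening instrument — and a strict mode
rejects them instead.

### Item catalog and reassignment

The instrument's original subscales are PV (12 items), SV (22) and
PA (5).  Three items are reassigned on occurrence-pattern grounds:
the name-calling item (original PA3) becomes the single micro-aggression
item MA1; the threat item (original PV1) moves to psychological
aggression as PA6; the forced-sexual-activity item (original PV8) moves
to sexual violence as SV22.  The working catalog is therefore PV=10,
PA=5, SV=23, MA=1.  Four SV item IDs are not published with the
instrument text; the catalog carries synthetic placeholders (SV8, SV13,
SV14, SV17, labelled as such) so the subscale keeps its stated size.
`apply_reassignment` is idempotent and rejects catalogs missing a
referenced item.

## Synthetic cohorts

The generator is a latent-Gaussian ordinal copula.  Each survivor draws
latent type intensities z = (z_PV, z_PA, z_SV, z_MA) from a zero-mean
multivariate normal; each item latent is the convex blend
u = w·z_type + (1−w)·ε with independent standard-normal item noise and
blend weight w = 0.7; u is discretized through four increasing cutpoints
placed so that P(response > 0) equals the item's prevalence tier, with
the nonzero mass split 50/25/15/10% over categories 1–4.

**Prevalence tiers.** Defaults encode the instrument's reporting
gradient: MA1 at 0.80 (the most frequent item of all), PA items 0.40–0.55,
PV items 0.04–0.38, SV items 0.02–0.12.  At these tiers roughly 9% of a
default cohort reports nothing at all; those rows are generated and
retained so the filtering step is exercised.

**Correlation semantics and calibration.** `type_correlation` is the
*target correlation of the observable type scores* in the filtered
cohort, defaulting to the qualitative structure the pipeline studies: a
strong PV–PA association (0.45), moderate PA–MA (0.39), weak PV–MA
(0.22) and near-zero SV couplings.  Discretizing zero-inflated ordinal
items attenuates correlations substantially (a latent 0.45 comes out
near 0.33 at these tiers), so the generator calibrates the latent copula
correlation pair by pair: it probes the latent-to-score slope with a
deterministic 30,000-survivor draw (independent of the user's seed,
cached per parameter signature) and sets latent ρ = target / slope,
repairing the matrix to the nearest correlation matrix if the pairwise
solutions leave it indefinite.  This is the standard approach for
simulating ordinal data with prescribed product-moment correlations.
`GroundTruth` records both the target and the calibrated latent matrix.
Unattainable targets (|latent| > 0.99) are clipped with a warning.

**Outcomes.** Trauma and health latents are linear in (z_PA, z_PV, z_SV)
— defaults 0.6/0.4/0.1 for trauma and 0.5/0.3/0.2 for health, unit noise
SD — standardized and discretized through the same blend machinery into
16 health items and 4 trauma items at prevalence 0.5.  Setting all
loadings to zero decouples outcomes from violence exactly.

**Planted regimes.** `generate_regime_cohort` replaces the multivariate
normal with a five-component mixture over latent means.  The default
regimes use block on/off levels (+3 / −2.5 latent SD) chosen so that
every pair of regimes differs across at least one whole item block after
discretization — the separation needed for K-means on raw ordinal
profiles to recover the planting reliably.  The five patterns emulate
qualitatively distinct subgroups: everything-but-SV, MA-only, everything,
SV-dominated-without-MA, and PA+MA-without-PV/SV.

**Determinism.** One integer seed governs a draw; per-stage substreams
(latents, item noise, outcome noise) are spawned from it, so cohorts are
bit-reproducible.

## Co-occurrence analysis

Dichotomization uses a strict `>` against the cohort mean of each type
score (alternatives exposed: any-violence zero threshold, mean + 1 SD,
mean + 2 SD).  A constant score column flags nobody and warns.

The odds ratio uses the cross-product form with
SE = √(Σ 1/cell).  Two interval styles are deliberate:

- `literal` (default): [OR/e^SE, OR·e^SE] — one log-odds standard error
  each side, the form the pipeline is specified with.  Its nominal
  coverage under the null is that of a ±1·SE interval (~68%), which the
  acceptance suite measures (~64% empirically).
- `wald95`: [OR·e^{±1.96·SE}], the standard 95% Wald interval; measured
  null coverage ~0.93 at the default cohort size.

Tables with a zero cell receive the Haldane–Anscombe +0.5 correction in
all four cells and are flagged.  No multiple-testing correction is
applied across the six type pairs.  Score correlations are Pearson with
two-sided t-distribution p-values.

## Item network

Edges require correlation strictly greater than the threshold (default
0.2).  Zero-variance items have undefined correlations; these are
reported as missing and never create edges, rather than being treated as
zero — an isolated degenerate item should read as "no information", not
"independent".  Cross-degree counts edges whose endpoints carry
different assigned types; top-k lists (k = 5) break ties by item ID.

## Radial projection

Rank normalization maps scores to r = rank/n with average ranks on ties,
so the maximum observed score maps to exactly 1 and the marginal is
uniform up to ties.  (The alternative (rank−1)/(n−1) convention would
map minima to 0; rank/n is used so a lone survivor has percentile 1.)

The transform follows the hue/lightness arithmetic of the RGB→HSL color
transform with channels (PV, PA, SV).  Conventions that required a
decision:

- **Hue constant.** The angle is H′ × π/6 by default (`narrow`), so
  angles span [0, π); the conventional HSL constant of 60° is available
  as `standard` (π/3, spanning [0, 2π)).  The narrow scale is the
  package's primary convention; the polar grid default
  (`angle_max = π`) matches it.
- **Ties for the maximal channel** resolve by the fixed precedence
  PV > PA > SV (the order the branches are written in).  At a boundary
  the two admissible branches agree analytically, so the tie-break only
  matters for which formula is evaluated.
- **The PV branch's `mod 6`** uses the non-negative remainder, keeping
  H′ ∈ [0, 6).
- **Achromatic survivors** (all three ranks equal, Δ = 0) keep their
  intensity, are placed on the angle-0 ray for plotting, and are
  excluded from angular binning statistics.
- **MA** is scored and analyzed via contingency and clustering but does
  not enter the three-channel transform.

PCA is mean-centered without variance scaling: all items share the 0–4
scale, and standardizing would erase exactly the dominance of the
high-frequency items that motivates treating MA separately.  Component
signs are fixed so each component's largest-magnitude loading is
positive.

Polar binning uses a 12-angle × 5-radius lattice by default over
[0, 1] × [0, angle_max); boundary values land in the last bin of their
axis, empty bins report count 0 with a missing mean.

## Subgroups

Clustering operates on the raw 39-item profiles (not type scores) with
Euclidean K-means, k-means++ seeding, and best-of-100 restarts by total
within-cluster distance; labels are canonicalized by descending cluster
size so identical partitions compare equal.  K is selected as the
Calinski-Harabasz argmax over K = 2..10, with the full index table
returned so a judgment call can override the argmax.  The heterogeneity
null band uses empirical 2.5/97.5 percentiles over 100 random
without-replacement groups per size — no normal approximation.

## Problem sizes in the verification suite

The test suite and acceptance script run entirely on generated cohorts:
873-survivor cohorts for co-occurrence checks (20 seeds for correlation
recovery, 200–500 for interval coverage), 2,000–5,000 survivors for
marginal and independence checks, 600-survivor five-regime cohorts (10
seeds) for subgroup recovery with 100 clustering restarts (20 per K for
the selection sweep), and 10,000 random triples for the transform's
radius identity.  These sizes give Monte-Carlo error comfortably inside
each asserted tolerance.

## What the synthetic test bed does and does not show

Passing tests establish that the pipeline's arithmetic is correct
(oracle-checked odds ratios, exact geometric identities, conservation),
that it recovers planted structure (correlations, network blocks,
regimes) at realistic sizes, and that its intervals have the coverage
their construction implies.  They do not establish anything about real
survey cohorts: the copula has no demographic covariates, no survey
weights, no longitudinal structure, no informative missingness, and its
outcome model is linear-Gaussian in the latents.  Odds ratios are
emergent under the copula — the generator matches score-scale
*correlations*, so OR levels on synthetic cohorts need not match those
of any particular real cohort even when correlations do.

## Known limitations

- The correlation calibration targets the default filtered-cohort
  conditions; under extreme user-supplied prevalence tiers the pairwise
  slopes are still estimated, but very rare scales (every item < 1%)
  make targets above ~0.6 unattainable and trigger the clipping warning.
- `select_k` maximizes Calinski-Harabasz globally; a pronounced but
  non-maximal elbow is not detected automatically.
- Venn-style figures and force-directed network layouts are out of
  scope; exports (edge lists, GraphML, per-bin CSV) are meant for
  downstream tooling.
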