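"""Synthetic ordinal survey cohorts with known co-occurrence structure.

Real cohorts of this kind are restricted-access survey microdata, so every
downstream stage of the pipeline is exercised on generated cohorts whose
ground truth is known.  The generative model is a latent-Gaussian ordinal
copula:

1. each survivor draws a vector of latent violence-type intensities from a
   zero-mean multivariate normal over (PV, PA, SV, MA);
2. each item's latent value is a convex blend ``w * z_type + (1-w) * eps``
   of its type's intensity and independent item noise (default w = 0.7);
3. the item latent is discretized through four increasing cutpoints chosen
   so the nonzero-response probability matches the item's prevalence tier,
   with the nonzero mass split 50/25/15/10% over responses 1..4;
4. latent trauma/health outcomes are linear in the PA/PV/SV intensities
   plus Gaussian noise and discretized to the same 0..4 scale.

``CohortSpec.type_correlation`` is the *target correlation of the observable
type scores* in the filtered cohort.  Ordinal discretization attenuates
correlations (rare, zero-inflated items especially), so the generator
calibrates the latent copula correlation upward, pair by pair, using a
deterministic Monte-Carlo probe of the latent-to-score correlation slope --
the usual approach when simulating ordinal data with prescribed product-
moment correlations.  The latent matrix actually used is recorded in
``GroundTruth.latent_correlation``.

Default prevalence tiers follow the reporting-frequency gradient of the
instrument: the single micro-aggression item is the most frequent of all,
psychological-aggression items are next, physical-violence items moderate,
and sexual-violence items rare.  All-zero survivor rows occur naturally and
are retained, so the cohort filtering step has real work to do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TYPES, ResponseMatrix

#: Default latent correlations over (PV, PA, SV, MA): a strong PV-PA link,
#: a moderate PA-MA link, a weak PV-MA link and near-zero SV couplings.
DEFAULT_TYPE_CORRELATION = np.array(
    [
        [1.000, 0.450, 0.015, 0.220],
        [0.450, 1.000, 0.080, 0.390],
        [0.015, 0.080, 1.000, 0.010],
        [0.220, 0.010, 0.390, 1.000],
    ]
)
# symmetrize the (SV, MA) pair explicitly
DEFAULT_TYPE_CORRELATION[2, 3] = DEFAULT_TYPE_CORRELATION[3, 2] = 0.010
DEFAULT_TYPE_CORRELATION[1, 3] = DEFAULT_TYPE_CORRELATION[3, 1] = 0.390
DEFAULT_TYPE_CORRELATION.flags.writeable = False

DEFAULT_ITEM_COUNTS: dict[str, int] = {"PV": 10, "PA": 5, "SV": 23, "MA": 1}

#: Marginal probability of a nonzero response per canonical item.
DEFAULT_PREVALENCE: dict[str, float] = {
    "MA1": 0.80,
    "PA1": 0.55, "PA2": 0.50, "PA4": 0.45, "PA5": 0.40, "PA6": 0.45,
    "PV2": 0.30, "PV3": 0.38, "PV4": 0.18, "PV5": 0.15, "PV6": 0.12,
    "PV7": 0.20, "PV9": 0.10, "PV10": 0.12, "PV11": 0.04, "PV12": 0.05,
    "SV1": 0.06, "SV2": 0.04, "SV3": 0.04, "SV4": 0.08, "SV5": 0.12,
    "SV6": 0.10, "SV7": 0.05, "SV8": 0.03, "SV9": 0.02, "SV10": 0.04,
    "SV11": 0.03, "SV12": 0.05, "SV13": 0.03, "SV14": 0.02, "SV15": 0.03,
    "SV16": 0.02, "SV17": 0.02, "SV18a": 0.03, "SV18b": 0.04, "SV19": 0.06,
    "SV20": 0.10, "SV21": 0.02, "SV22": 0.05,
}

#: Prevalence ranges used to fill in tiers for non-default item counts.
_TYPE_PREVALENCE_RANGE: dict[str, tuple[float, float]] = {
    "MA": (0.80, 0.80),
    "PA": (0.62, 0.40),
    "PV": (0.38, 0.04),
    "SV": (0.12, 0.02),
}

#: Split of the nonzero response mass over categories 1..4.
_NONZERO_SPLIT = np.array([0.50, 0.25, 0.15, 0.10])

DEFAULT_OUTCOME_LOADINGS: dict[str, dict[str, float]] = {
    "trauma": {"PA": 0.6, "PV": 0.4, "SV": 0.1},
    "health": {"PA": 0.5, "PV": 0.3, "SV": 0.2},
}

DEFAULT_OUTCOME_ITEM_COUNTS: dict[str, int] = {"health": 16, "trauma": 4}


def _canonical_item_table(item_counts: dict[str, int]) -> list[tuple[str, str]]:
    """(item_id, type) pairs; canonical IDs when counts match the defaults."""
    if item_counts == DEFAULT_ITEM_COUNTS:
        from .items import CANONICAL_ORDER, assigned_type

        return [(i, assigned_type(i)) for i in CANONICAL_ORDER]
    table = []
    for t in ("MA", "PA", "PV", "SV"):
        for k in range(item_counts.get(t, 0)):
            table.append((f"{t}_{k + 1:02d}", t))
    return table


def _fill_prevalence(items: list[tuple[str, str]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for t in ("MA", "PA", "PV", "SV"):
        ids = [i for i, tt in items if tt == t]
        hi, lo = _TYPE_PREVALENCE_RANGE[t]
        vals = np.linspace(hi, lo, max(len(ids), 1))
        out.update(dict(zip(ids, vals)))
    return out


@dataclass
class CohortSpec:
    """Parameters of the synthetic-cohort generative model.

    ``type_correlation`` is over (PV, PA, SV, MA) in that order and must be
    symmetric, unit-diagonal and positive semi-definite.  ``blend_weight``
    is the convex weight of the type intensity in each item latent.
    ``ordinal_cutpoints`` may override the prevalence-derived thresholds
    with explicit 4-vectors per item.
    """

    n_survivors: int = 873
    type_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_TYPE_CORRELATION.copy()
    )
    item_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ITEM_COUNTS))
    prevalence_tiers: dict[str, float] | None = None
    ordinal_cutpoints: dict[str, tuple[float, float, float, float]] | None = None
    outcome_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_LOADINGS.items()}
    )
    noise_sd: float = 1.0
    blend_weight: float = 0.7
    seed: int = 0

    def items(self) -> list[tuple[str, str]]:
        return _canonical_item_table(self.item_counts)

    def prevalence(self) -> dict[str, float]:
        if self.prevalence_tiers is not None:
            return dict(self.prevalence_tiers)
        if self.item_counts == DEFAULT_ITEM_COUNTS:
            return dict(DEFAULT_PREVALENCE)
        return _fill_prevalence(self.items())

    def validate(self) -> None:
        c = np.asarray(self.type_correlation, dtype=float)
        if c.shape != (4, 4):
            raise ValueError(f"type_correlation must be 4x4, got {c.shape}")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("type_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("type_correlation must have a unit diagonal")
        min_eig = float(np.linalg.eigvalsh(c).min())
        if min_eig < -1e-10:
            raise ValueError(
                f"type_correlation is not positive semi-definite "
                f"(smallest eigenvalue {min_eig:.4g})"
            )
        if self.n_survivors <= 0:
            raise ValueError(f"n_survivors must be positive, got {self.n_survivors}")
        if any(v < 0 for v in self.item_counts.values()):
            raise ValueError("negative item counts are not allowed")
        for item, p in self.prevalence().items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {item!r} must be in (0,1), got {p}")
        if not 0.0 < self.blend_weight <= 1.0:
            raise ValueError("blend_weight must be in (0, 1]")
        if self.ordinal_cutpoints is not None:
            for item, cuts in self.ordinal_cutpoints.items():
                if len(cuts) != 4 or not np.all(np.diff(cuts) > 0):
                    raise ValueError(
                        f"ordinal_cutpoints for {item!r} must be 4 strictly "
                        f"increasing thresholds"
                    )


@dataclass
class GroundTruth:
    """What the generator actually drew: latent intensities and parameters.

    ``type_correlation`` is the target score-scale correlation from the
    spec; ``latent_correlation`` is the calibrated latent-copula matrix the
    draw actually used.
    """

    latent: pd.DataFrame                 # survivors x (PV, PA, SV, MA)
    type_correlation: np.ndarray
    latent_correlation: np.ndarray
    outcome_loadings: dict[str, dict[str, float]]
    outcome_latents: pd.DataFrame        # survivors x outcome categories
    regime_labels: np.ndarray | None = None


@dataclass
class SyntheticCohort:
    """A generated cohort: violence responses, outcome responses, truth."""

    responses: ResponseMatrix
    outcomes: ResponseMatrix
    outcome_catalog: pd.DataFrame        # columns item_id, category
    truth: GroundTruth


def _cutpoints_for(p: float, sd: float) -> np.ndarray:
    """Thresholds on the item-latent scale hitting nonzero-probability p."""
    tail = p * np.concatenate(([1.0], 1.0 - np.cumsum(_NONZERO_SPLIT[:-1])))
    return sd * stats.norm.ppf(1.0 - tail)


def _discretize(u: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, u, side="right").astype(np.int64)


def _latent_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = corr, tolerant of semi-definite matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _item_responses(
    z_cols: np.ndarray,
    items: list[tuple[str, str]],
    cutpoints: dict[str, np.ndarray],
    w: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend type latents with item noise and discretize, column by column."""
    n = z_cols.shape[0]
    out = np.empty((n, len(items)), dtype=np.int64)
    type_index = {t: k for k, t in enumerate(TYPES)}
    eps = rng.standard_normal((n, len(items)))
    for j, (item, t) in enumerate(items):
        u = w * z_cols[:, type_index[t]] + (1.0 - w) * eps[:, j]
        out[:, j] = _discretize(u, cutpoints[item])
    return out


def _outcome_block(
    z: np.ndarray,
    loadings: dict[str, dict[str, float]],
    corr: np.ndarray,
    noise_sd: float,
    w: float,
    item_counts: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, str]], pd.DataFrame]:
    """Latent outcomes linear in PV/PA/SV, discretized per outcome item."""
    n = z.shape[0]
    type_index = {t: k for k, t in enumerate(TYPES)}
    categories = list(loadings)
    latents = {}
    for cat in categories:
        load = loadings[cat]
        lvec = np.zeros(4)
        for t, coef in load.items():
            lvec[type_index[t]] = coef
        lam = z @ lvec + noise_sd * rng.standard_normal(n)
        var = float(lvec @ corr @ lvec + noise_sd**2)
        latents[cat] = lam / np.sqrt(var) if var > 0 else lam
    items: list[tuple[str, str]] = []
    for cat in categories:
        prefix = cat[:1].upper()
        items += [(f"{prefix}{k + 1:02d}", cat) for k in range(item_counts.get(cat, 0))]
    sd_u = np.sqrt(w**2 + (1.0 - w) ** 2)
    cuts = _cutpoints_for(0.5, sd_u)
    out = np.empty((n, len(items)), dtype=np.int64)
    eps = rng.standard_normal((n, len(items)))
    for j, (item, cat) in enumerate(items):
        u = w * latents[cat] + (1.0 - w) * eps[:, j]
        out[:, j] = _discretize(u, cuts)
    latent_df = pd.DataFrame(latents)
    catalog = pd.DataFrame(items, columns=["item_id", "category"])
    return out, items, (latent_df, catalog)


# ---------------------------------------------------------------------------
# Latent-correlation calibration.
#
# The latent-to-score correlation slope is estimated per type pair from a
# deterministic probe draw (independent of the user's seed), then the latent
# correlation is set to target / slope.  Slopes are cached per (correlation
# targets, item table, prevalence, blend) signature.
# ---------------------------------------------------------------------------

_CAL_N = 30_000
_CAL_SEED = 202_305
_calibration_cache: dict[tuple, np.ndarray] = {}


def _probe_score_corr(
    pair: tuple[int, int],
    rho_probe: float,
    items: list[tuple[str, str]],
    cutpoints: dict[str, np.ndarray],
    w: float,
) -> float:
    """Observed filtered-cohort score correlation at a probe latent rho."""
    i, j = pair
    corr = np.eye(4)
    corr[i, j] = corr[j, i] = rho_probe
    rng = np.random.default_rng([_CAL_SEED, i, j])
    z = rng.standard_normal((_CAL_N, 4)) @ _latent_factor(corr).T
    values = _item_responses(z, items, cutpoints, w, rng)
    keep = (values > 0).any(axis=1)
    cols_i = [k for k, (_, t) in enumerate(items) if t == TYPES[i]]
    cols_j = [k for k, (_, t) in enumerate(items) if t == TYPES[j]]
    s_i = values[keep][:, cols_i].mean(axis=1)
    s_j = values[keep][:, cols_j].mean(axis=1)
    return float(np.corrcoef(s_i, s_j)[0, 1])


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh(c)
    c = v @ np.diag(np.clip(w, 1e-10, None)) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _calibrate_latent_correlation(spec: CohortSpec) -> np.ndarray:
    """Latent copula correlation matrix hitting the spec's score targets."""
    target = np.asarray(spec.type_correlation, dtype=float)
    off = target[~np.eye(4, dtype=bool)]
    if np.allclose(off, 0.0):
        return target.copy()
    items = spec.items()
    prevalence = spec.prevalence()
    w = spec.blend_weight
    key = (
        target.round(9).tobytes(),
        tuple(items),
        tuple(sorted((k, round(v, 9)) for k, v in prevalence.items())),
        round(w, 9),
    )
    if key in _calibration_cache:
        return _calibration_cache[key].copy()
    sd_u = np.sqrt(w**2 + (1.0 - w) ** 2)
    cutpoints = {
        item: (
            np.asarray(spec.ordinal_cutpoints[item], dtype=float)
            if spec.ordinal_cutpoints and item in spec.ordinal_cutpoints
            else _cutpoints_for(prevalence[item], sd_u)
        )
        for item, _ in items
    }
    latent = np.eye(4)
    for i in range(4):
        for j in range(i + 1, 4):
            t = target[i, j]
            if abs(t) < 1e-12:
                continue
            # probe in a regime where the slope is well estimated
            rho_p = np.sign(t) * min(max(abs(t), 0.3), 0.8)
            slope = _probe_score_corr((i, j), rho_p, items, cutpoints, w) / rho_p
            lat = t / slope if slope > 0 else t
            if abs(lat) > 0.99:
                warnings.warn(
                    f"target correlation {t:.3f} between {TYPES[i]} and {TYPES[j]} "
                    f"is not attainable under this discretization; latent "
                    f"correlation clipped to {np.sign(lat) * 0.99:.2f}",
                    stacklevel=3,
                )
                lat = float(np.clip(lat, -0.99, 0.99))
            latent[i, j] = latent[j, i] = lat
    if np.linalg.eigvalsh(latent).min() < 0:
        latent = _nearest_correlation(latent)
    _calibration_cache[key] = latent.copy()
    return latent


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from the latent-Gaussian ordinal model.

    Deterministic for a fixed ``spec.seed``: all randomness flows from a
    single seed through per-stage child streams (latents, item noise,
    outcome noise).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_latent, rng_items, rng_out = (np.random.default_rng(c) for c in ss.spawn(3))

    corr = np.asarray(spec.type_correlation, dtype=float)
    latent_corr = _calibrate_latent_correlation(spec)
    n = spec.n_survivors
    z = rng_latent.standard_normal((n, 4)) @ _latent_factor(latent_corr).T

    items = spec.items()
    w = spec.blend_weight
    sd_u = np.sqrt(w**2 + (1.0 - w) ** 2)
    prevalence = spec.prevalence()
    cutpoints = {
        item: (
            np.asarray(spec.ordinal_cutpoints[item], dtype=float)
            if spec.ordinal_cutpoints and item in spec.ordinal_cutpoints
            else _cutpoints_for(prevalence[item], sd_u)
        )
        for item, _ in items
    }
    values = _item_responses(z, items, cutpoints, w, rng_items)

    survivor_ids = [f"S{k + 1:04d}" for k in range(n)]
    responses = ResponseMatrix(survivor_ids, [i for i, _ in items], values)

    out_values, out_items, (latent_df, out_catalog) = _outcome_block(
        z, spec.outcome_loadings, corr, spec.noise_sd, w,
        DEFAULT_OUTCOME_ITEM_COUNTS, rng_out,
    )
    outcomes = ResponseMatrix(survivor_ids, [i for i, _ in out_items], out_values)
    latent_df.index = pd.Index(survivor_ids, name="survivor_id")

    truth = GroundTruth(
        latent=pd.DataFrame(z, index=latent_df.index, columns=list(TYPES)),
        type_correlation=corr.copy(),
        latent_correlation=latent_corr,
        outcome_loadings={k: dict(v) for k, v in spec.outcome_loadings.items()},
        outcome_latents=latent_df,
    )
    return SyntheticCohort(responses, outcomes, out_catalog, truth)


#: Latent mean profiles over (PV, PA, SV, MA) for five planted regimes that
#: mimic qualitatively distinct violence subgroups: (1) elevated violence
#: except SV, (2) intense MA only, (3) intense everything, (4) SV-dominated
#: with very low MA, (5) intense PA+MA with low PV/SV.  Levels are block
#: on/off (+3 / -2.5 latent SD) so each pair of regimes differs on at least
#: one whole item block after discretization.
DEFAULT_REGIME_MEANS: dict[str, tuple[float, float, float, float]] = {
    "low_sv_elevated_rest": (3.0, 3.0, -2.5, 3.0),
    "high_ma_low_rest": (-2.5, -2.5, -2.5, 3.0),
    "high_everything": (3.0, 3.0, 3.0, 3.0),
    "sv_dominated_low_ma": (-2.5, -2.5, 3.0, -2.5),
    "high_pa_ma_low_pv_sv": (-2.5, 3.0, -2.5, 3.0),
}


def generate_regime_cohort(
    n_per_regime: int = 120,
    regime_means: dict[str, tuple[float, float, float, float]] | None = None,
    within_sd: float = 0.45,
    spec: CohortSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Cohort drawn from a mixture of latent regimes (planted subgroups).

    Each regime contributes ``n_per_regime`` survivors whose latent type
    intensities are normal around the regime's mean vector with spread
    ``within_sd``, then pass through the same item blend/discretization as
    :func:`generate_cohort`.  Ground-truth regime labels are recorded in
    ``truth.regime_labels``.
    """
    means = regime_means or DEFAULT_REGIME_MEANS
    base = spec or CohortSpec()
    base.validate()
    n_regimes = len(means)
    n = n_per_regime * n_regimes
    ss = np.random.SeedSequence(seed)
    rng_latent, rng_items, rng_out = (np.random.default_rng(c) for c in ss.spawn(3))

    mu = np.array(list(means.values()), dtype=float)
    labels = np.repeat(np.arange(n_regimes), n_per_regime)
    z = mu[labels] + within_sd * rng_latent.standard_normal((n, 4))

    items = base.items()
    w = base.blend_weight
    sd_u = np.sqrt(w**2 + (1.0 - w) ** 2)
    prevalence = base.prevalence()
    cutpoints = {item: _cutpoints_for(prevalence[item], sd_u) for item, _ in items}
    values = _item_responses(z, items, cutpoints, w, rng_items)
    survivor_ids = [f"S{k + 1:04d}" for k in range(n)]
    responses = ResponseMatrix(survivor_ids, [i for i, _ in items], values)

    corr = np.asarray(base.type_correlation, dtype=float)
    out_values, out_items, (latent_df, out_catalog) = _outcome_block(
        z, base.outcome_loadings, corr, base.noise_sd, w,
        DEFAULT_OUTCOME_ITEM_COUNTS, rng_out,
    )
    outcomes = ResponseMatrix(survivor_ids, [i for i, _ in out_items], out_values)
    latent_df.index = pd.Index(survivor_ids, name="survivor_id")

    truth = GroundTruth(
        latent=pd.DataFrame(z, index=latent_df.index, columns=list(TYPES)),
        type_correlation=corr.copy(),
        latent_correlation=np.eye(4),
        outcome_loadings={k: dict(v) for k, v in base.outcome_loadings.items()},
        outcome_latents=latent_df,
        regime_labels=labels,
    )
    return SyntheticCohort(responses, outcomes, out_catalog, truth)


def spec_with_pv_pa_correlation(rho: float, **kwargs) -> CohortSpec:
    """Identity-latent spec except for a single PV-PA correlation ``rho``."""
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = rho
    return CohortSpec(type_correlation=corr, **kwargs)
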