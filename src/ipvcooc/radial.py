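"""Radial projection of survivors into a violence type vs. intensity plane.

Per-type scores are first rank-normalized to (0, 1].  The three scores
r_PV, r_PA, r_SV are then treated as the red/green/blue channels of a color
and passed through the hue/lightness part of the RGB -> HSL color
transform:

    I_max = max(r_PV, r_PA, r_SV),  I_min = min(...),  Delta = I_max - I_min
    Intensity = (I_max + I_min) / 2                       (lightness analogue)

    H' = ((r_PA - r_SV) / Delta) mod 6      if the max channel is PV
       = (r_SV - r_PV) / Delta + 2          if the max channel is PA
       = (r_PV - r_PA) / Delta + 4          if the max channel is SV
    angle = H' * hue_scale                                (hue analogue)

A survivor with Delta = 0 is *achromatic*: all three channels tie, the type
angle is undefined, and only the intensity carries information.  Radial
plane coordinates are x = Intensity cos(angle), y = Intensity sin(angle),
so distance from the origin is violence intensity and the arc angle is
violence type.

``hue_scale`` defaults to pi/6 ('narrow', angles span [0, pi)); the
conventional HSL hue constant of 60 degrees is available as 'standard'
(pi/3, angles span [0, 2 pi)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .cohort import ResponseMatrix

#: The three channel types entering the transform, in channel order
#: (red, green, blue).  MA is scored but does not map to a channel.
CHANNEL_TYPES: tuple[str, str, str] = ("PV", "PA", "SV")

HUE_SCALES = {"narrow": np.pi / 6, "standard": np.pi / 3}


def resolve_hue_scale(hue_scale) -> float:
    if isinstance(hue_scale, str):
        try:
            return HUE_SCALES[hue_scale]
        except KeyError:
            raise ValueError(
                f"unknown hue scale {hue_scale!r}; choose from {list(HUE_SCALES)}"
            ) from None
    return float(hue_scale)


def rank_normalize(scores: pd.DataFrame) -> pd.DataFrame:
    """Percentile-rank each score column to (0, 1].

    r(i) = rank(i) / n with ascending ranks 1..n; ties receive the average
    of their ranks.  Computed independently per type, so each column has a
    uniform marginal up to ties and the maximum maps to exactly 1.
    """
    if len(scores) < 1:
        raise ValueError("rank normalization requires at least 1 survivor")
    n = len(scores)
    ranked = {
        col: stats.rankdata(scores[col].to_numpy(), method="average") / n
        for col in scores.columns
    }
    return pd.DataFrame(ranked, index=scores.index)


def hsl_transform(
    r_pv: np.ndarray, r_pa: np.ndarray, r_sv: np.ndarray, hue_scale="narrow"
) -> pd.DataFrame:
    """Map rank triples to (intensity, h_prime, angle, achromatic).

    When two channels tie for the maximum the branch is chosen by the fixed
    precedence PV > PA > SV.  The ``mod 6`` of the PV branch uses the
    non-negative remainder.  Achromatic rows (Delta = 0) get NaN angles.
    """
    scale = resolve_hue_scale(hue_scale)
    r = np.column_stack([np.asarray(r_pv, float), np.asarray(r_pa, float),
                         np.asarray(r_sv, float)])
    if np.any((r < 0) | (r > 1)):
        bad = np.argwhere((r < 0) | (r > 1))[0]
        raise ValueError(
            f"rank scores must lie in [0, 1]; got {r[bad[0], bad[1]]} "
            f"in channel {CHANNEL_TYPES[bad[1]]}"
        )
    i_max = r.max(axis=1)
    i_min = r.min(axis=1)
    delta = i_max - i_min
    intensity = (i_max + i_min) / 2.0
    achromatic = delta == 0
    # argmax returns the first maximal channel: precedence PV > PA > SV
    m = np.argmax(r, axis=1)
    h = np.full(len(r), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        pv_branch = np.mod((r[:, 1] - r[:, 2]) / delta, 6.0)
        pa_branch = (r[:, 2] - r[:, 0]) / delta + 2.0
        sv_branch = (r[:, 0] - r[:, 1]) / delta + 4.0
    sel = ~achromatic
    h[sel & (m == 0)] = pv_branch[sel & (m == 0)]
    h[sel & (m == 1)] = pa_branch[sel & (m == 1)]
    h[sel & (m == 2)] = sv_branch[sel & (m == 2)]
    return pd.DataFrame(
        {
            "intensity": intensity,
            "h_prime": h,
            "angle": h * scale,
            "achromatic": achromatic,
        }
    )


def radial_coords(intensity: np.ndarray, angle: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plane coordinates x = I cos(angle), y = I sin(angle).

    Achromatic rows (NaN angle) are placed on the angle-0 ray by
    convention: (intensity, 0).
    """
    intensity = np.asarray(intensity, float)
    angle = np.asarray(angle, float)
    nan = np.isnan(angle)
    x = np.where(nan, intensity, intensity * np.cos(angle))
    y = np.where(nan, 0.0, intensity * np.sin(angle))
    return x, y


def radial_points(scores: pd.DataFrame, hue_scale="narrow") -> pd.DataFrame:
    """Full radial projection of a cohort's type scores.

    Rank-normalizes the scores, applies the hue/lightness transform to the
    PV/PA/SV channels, and attaches plane coordinates.  Returns a DataFrame
    indexed like ``scores`` with columns intensity, h_prime, angle, x, y,
    achromatic; the hue scale used is recorded in ``attrs['hue_scale']``.
    """
    ranks = rank_normalize(scores)
    pts = hsl_transform(
        ranks["PV"].to_numpy(), ranks["PA"].to_numpy(), ranks["SV"].to_numpy(),
        hue_scale=hue_scale,
    )
    pts.index = scores.index
    x, y = radial_coords(pts["intensity"].to_numpy(), pts["angle"].to_numpy())
    pts["x"], pts["y"] = x, y
    pts.attrs["hue_scale"] = resolve_hue_scale(hue_scale)
    return pts


def pca_project(matrix: ResponseMatrix) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Two-component PCA of the response matrix.

    Columns are mean-centered but not variance-scaled: all items share the
    0..4 response scale, and standardizing would mask the dominance of the
    high-frequency items.  Returns (survivor scores n x 2, item loadings
    m x 2, explained variance ratio).  The sign of each component is fixed
    so its largest-magnitude loading is positive.
    """
    if matrix.n_survivors < 3:
        raise ValueError("PCA requires at least 3 survivors")
    if matrix.n_items < 2:
        raise ValueError("PCA requires at least 2 items")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(matrix.values.astype(float))
    loadings = pca.components_.T  # items x 2
    for k in range(2):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return (
        pd.DataFrame(scores, index=matrix.survivor_ids, columns=["PC1", "PC2"]),
        pd.DataFrame(loadings, index=matrix.item_ids, columns=["PC1", "PC2"]),
        pca.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class PolarGridSpec:
    """A polar binning lattice over the annulus [0, 1] x [0, angle_max)."""

    n_angle: int = 12
    n_radius: int = 5
    angle_max: float = 6 * np.pi / 6  # full hue range under the narrow scale

    def __post_init__(self):
        if self.n_angle < 1 or self.n_radius < 1:
            raise ValueError("grid must have at least one bin per axis")
        if self.angle_max <= 0:
            raise ValueError("angle_max must be positive")


@dataclass
class PolarBinGrid:
    """Per-bin survivor counts and mean overlaid outcome values.

    ``table`` is a long-format DataFrame over the full lattice with columns
    angle_bin, radius_bin, count, mean_outcome (NaN for empty bins).
    Achromatic survivors are excluded; counts sum to the number of
    non-achromatic survivors.
    """

    spec: PolarGridSpec
    table: pd.DataFrame
    n_achromatic: int


def bin_radial(
    points: pd.DataFrame,
    outcome_values: np.ndarray | pd.Series | None = None,
    grid: PolarGridSpec | None = None,
) -> PolarBinGrid:
    """Assign non-achromatic survivors to polar bins and aggregate outcomes.

    Each survivor falls in exactly one (angle, radius) bin; the boundary
    values intensity = 1 and angle = angle_max land in the last bin of
    their axis.  Empty bins are reported with count 0 and a missing mean.
    """
    grid = grid or PolarGridSpec()
    if outcome_values is not None and len(outcome_values) != len(points):
        raise ValueError(
            f"outcome length {len(outcome_values)} does not match "
            f"{len(points)} radial points"
        )
    keep = ~points["achromatic"].to_numpy()
    angle = points.loc[keep, "angle"].to_numpy()
    inten = points.loc[keep, "intensity"].to_numpy()
    if np.any((angle < 0) | (angle > grid.angle_max + 1e-12)):
        raise ValueError("angles outside [0, angle_max]; check the hue scale")
    a_idx = np.clip((angle / grid.angle_max * grid.n_angle).astype(int), 0, grid.n_angle - 1)
    r_idx = np.clip((inten * grid.n_radius).astype(int), 0, grid.n_radius - 1)
    out = None
    if outcome_values is not None:
        out = np.asarray(outcome_values, float)[keep]
    rows = []
    flat = a_idx * grid.n_radius + r_idx
    for ab in range(grid.n_angle):
        for rb in range(grid.n_radius):
            sel = flat == ab * grid.n_radius + rb
            cnt = int(sel.sum())
            mean = float(out[sel].mean()) if (out is not None and cnt) else np.nan
            rows.append((ab, rb, cnt, mean))
    table = pd.DataFrame(rows, columns=["angle_bin", "radius_bin", "count", "mean_outcome"])
    return PolarBinGrid(spec=grid, table=table, n_achromatic=int((~keep).sum()))
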