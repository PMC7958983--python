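"""Health-problem and trauma-symptom scores and their violence overlays.

Outcome categories (e.g. 16 health-problem items, a handful of trauma
items) are scored like the violence subscales: the per-survivor arithmetic
mean over the category's items.  Scores are then related to violence
either by averaging within polar bins of the radial type-vs-intensity
plane or by summarizing their distribution within each clustered subgroup.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ResponseMatrix
from .radial import PolarBinGrid, PolarGridSpec, bin_radial
from .subgroups import ClusteringResult


def compute_outcome_scores(
    outcome_matrix: ResponseMatrix, outcome_catalog: pd.DataFrame
) -> pd.DataFrame:
    """Mean response per survivor for each outcome category.

    ``outcome_catalog`` maps item_id -> category.  Every item in the matrix
    must be cataloged; unknown items raise.
    """
    if not {"item_id", "category"} <= set(outcome_catalog.columns):
        raise ValueError("outcome catalog needs columns item_id and category")
    cat = dict(zip(outcome_catalog["item_id"], outcome_catalog["category"]))
    unknown = [i for i in outcome_matrix.item_ids if i not in cat]
    if unknown:
        raise ValueError(f"outcome items not in catalog: {unknown[:5]}")
    df = outcome_matrix.to_frame()
    scores = {}
    for category in dict.fromkeys(cat.values()):
        cols = [i for i in outcome_matrix.item_ids if cat[i] == category]
        if cols:
            scores[category] = df[cols].mean(axis=1)
    return pd.DataFrame(scores)


def overlay_outcomes(
    points: pd.DataFrame,
    outcome_scores: pd.DataFrame,
    grid: PolarGridSpec | None = None,
) -> dict[str, PolarBinGrid]:
    """One polar-bin grid per outcome category, means taken within bins."""
    if len(points) != len(outcome_scores):
        raise ValueError("radial points and outcome scores cover different survivors")
    return {
        category: bin_radial(points, outcome_scores[category].to_numpy(), grid)
        for category in outcome_scores.columns
    }


def outcomes_by_subgroup(
    outcome_scores: pd.DataFrame, clustering: ClusteringResult
) -> pd.DataFrame:
    """Distribution of each outcome category within each subgroup.

    One row per (cluster, category) with n, mean, median, quartiles, tails,
    and ``mean_sign``: +1/-1 when the cluster mean is above/below the
    cohort mean of that category, 0 when they coincide.
    """
    if len(outcome_scores) != len(clustering.labels):
        raise ValueError("outcome scores and clustering cover different survivors")
    cohort_mean = outcome_scores.mean(axis=0)
    rows = []
    for c in range(clustering.k):
        sel = clustering.labels == c
        sub = outcome_scores.loc[sel]
        for category in outcome_scores.columns:
            v = sub[category]
            diff = v.mean() - cohort_mean[category]
            rows.append(
                (c, category, int(sel.sum()), v.mean(), v.median(),
                 v.quantile(0.25), v.quantile(0.75), v.min(), v.max(),
                 int(np.sign(diff)))
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "category", "n", "mean", "median", "q1", "q3",
                 "min", "max", "mean_sign"],
    )
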