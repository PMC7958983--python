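"""Type-level co-occurrence: dichotomization, 2x2 tables, odds ratios.

A survivor is "high" in a violence type when their type score strictly
exceeds the cohort mean of that score.  For every unordered type pair the
2x2 high/low table yields an odds ratio with a log-scale standard error

    SE = sqrt(1/n_HH + 1/n_HL + 1/n_LH + 1/n_LL)

and an interval [OR / e^(z SE), OR * e^(z SE)].  Two interval styles are
provided: ``'literal'`` uses z = 1, i.e. the interval spans one log-odds
standard error on each side; ``'wald95'`` uses z = 1.96, the standard 95%
Wald interval on the log odds scale.  The expected overlap under
independence is n_H(T) n_H(T') / n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TYPES

#: z multipliers for the two supported interval styles.
CI_STYLES = {"literal": 1.0, "wald95": 1.959963984540054}

#: Supported dichotomization thresholds.
THRESHOLDS = ("mean", "zero", "mean+1sd", "mean+2sd")


@dataclass
class HighFlags:
    """Boolean high/low indicators per survivor and type."""

    flags: pd.DataFrame          # survivors x types, bool
    thresholds: pd.Series        # the per-type cutoff actually used
    n_high: pd.Series            # count of high survivors per type

    @property
    def n(self) -> int:
        return len(self.flags)


@dataclass
class ContingencyResult:
    """2x2 high/low contingency analysis for one type pair."""

    type_pair: tuple[str, str]
    n_hh: int
    n_hl: int
    n_lh: int
    n_ll: int
    expected_overlap: float
    odds_ratio: float
    se_log_or: float
    ci_low: float
    ci_high: float
    ci_style: str
    correction_applied: bool

    @property
    def n(self) -> int:
        return self.n_hh + self.n_hl + self.n_lh + self.n_ll


def dichotomize(scores: pd.DataFrame, threshold: str = "mean") -> HighFlags:
    """Flag survivors as high/low per type against a population threshold.

    The default threshold is the cohort mean of each type score, compared
    with a strict ``>``; alternatives are ``'zero'`` (any violence at all)
    and one or two standard deviations above the mean.  A constant score
    column produces no high flags and a warning.
    """
    if len(scores) < 2:
        raise ValueError("dichotomization requires at least 2 survivors")
    if threshold not in THRESHOLDS:
        raise ValueError(f"unknown threshold {threshold!r}; choose from {THRESHOLDS}")
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=0)
    cut = {
        "mean": mu,
        "zero": pd.Series(0.0, index=scores.columns),
        "mean+1sd": mu + sd,
        "mean+2sd": mu + 2 * sd,
    }[threshold]
    for col in scores.columns:
        if scores[col].nunique() == 1:
            warnings.warn(f"type {col} has a constant score; no survivor is high",
                          stacklevel=2)
    flags = scores.gt(cut, axis=1)
    return HighFlags(flags=flags, thresholds=cut, n_high=flags.sum(axis=0))


def odds_ratio_ci(
    n_hh: float, n_hl: float, n_lh: float, n_ll: float, ci_style: str = "literal"
) -> tuple[float, float, float, float, bool]:
    """OR, log-scale SE and interval for one 2x2 table.

    Tables with a zero cell receive the Haldane-Anscombe +0.5 continuity
    correction in all four cells (flagged in the last return value).
    """
    if ci_style not in CI_STYLES:
        raise ValueError(f"unknown ci_style {ci_style!r}; choose from {list(CI_STYLES)}")
    cells = np.array([n_hh, n_hl, n_lh, n_ll], dtype=float)
    if cells.sum() == 0:
        raise ValueError("empty contingency table")
    correction = bool((cells == 0).any())
    if correction:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = CI_STYLES[ci_style]
    return or_, se, or_ / math.exp(z * se), or_ * math.exp(z * se), correction


def contingency(
    flags: HighFlags, type_a: str, type_b: str, ci_style: str = "literal"
) -> ContingencyResult:
    """Contingency analysis of one type pair from high/low flags."""
    n = flags.n
    if n == 0:
        raise ValueError("no survivors in the cohort")
    a = flags.flags[type_a].to_numpy()
    b = flags.flags[type_b].to_numpy()
    n_hh = int((a & b).sum())
    n_hl = int((a & ~b).sum())
    n_lh = int((~a & b).sum())
    n_ll = int((~a & ~b).sum())
    expected = flags.n_high[type_a] * flags.n_high[type_b] / n
    or_, se, lo, hi, corr = odds_ratio_ci(n_hh, n_hl, n_lh, n_ll, ci_style)
    return ContingencyResult(
        type_pair=(type_a, type_b),
        n_hh=n_hh, n_hl=n_hl, n_lh=n_lh, n_ll=n_ll,
        expected_overlap=float(expected),
        odds_ratio=or_, se_log_or=se, ci_low=lo, ci_high=hi,
        ci_style=ci_style, correction_applied=corr,
    )


def all_pairs(flags: HighFlags, ci_style: str = "literal") -> list[ContingencyResult]:
    """Contingency results for all unordered type pairs."""
    cols = list(flags.flags.columns)
    return [contingency(flags, a, b, ci_style) for a, b in itertools.combinations(cols, 2)]


def type_correlations(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of type scores with two-sided p-values.

    Constant score columns produce NaN correlations and a warning.
    """
    if len(scores) < 3:
        raise ValueError("correlations require at least 3 survivors")
    cols = list(scores.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        xa, xb = scores[a].to_numpy(), scores[b].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(f"correlation of constant scores ({a}, {b}) is undefined",
                          stacklevel=2)
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def cooccurrence_report(
    scores: pd.DataFrame, threshold: str = "mean", ci_style: str = "literal"
) -> dict:
    """Full type-level co-occurrence report as a JSON-serializable dict."""
    flags = dichotomize(scores, threshold=threshold)
    results = all_pairs(flags, ci_style=ci_style)
    r, p = type_correlations(scores)
    return {
        "n_survivors": flags.n,
        "threshold": threshold,
        "ci_style": ci_style,
        "n_high": {t: int(flags.n_high[t]) for t in flags.flags.columns},
        "pairs": [
            {
                "types": list(res.type_pair),
                "n_hh": res.n_hh, "n_hl": res.n_hl,
                "n_lh": res.n_lh, "n_ll": res.n_ll,
                "expected_overlap": res.expected_overlap,
                "odds_ratio": res.odds_ratio,
                "se_log_or": res.se_log_or,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "correction_applied": res.correction_applied,
                "correlation": None if np.isnan(r.loc[res.type_pair]) else float(r.loc[res.type_pair]),
                "correlation_p": None if np.isnan(p.loc[res.type_pair]) else float(p.loc[res.type_pair]),
            }
            for res in results
        ],
    }
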