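"""Differential entropy of alpha oscillations and two-group rank statistics.

Differential entropy DE(X) = -∫ p(x) log p(x) dx measures the information
content of a continuous-valued time series.  Under a Gaussian model it has
the closed form 0.5 * log(2*pi*e*sigma^2), which is the default estimator
here (alpha-band EEG amplitude is well approximated as Gaussian over
minutes-long windows); a histogram plug-in estimator is kept for checking
departures from Gaussianity.  Values are in nats by default.

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney U) test: exact
permutation enumeration when the pooled sample is small enough, otherwise
the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_montage import RegionSpec

__all__ = [
    "StatResult",
    "differential_entropy",
    "regional_de",
    "rank_sum_test",
    "group_summary",
]

EXACT_LIMIT = 16  # exact enumeration feasible for n1 + n2 up to this


def differential_entropy(x, estimator: str = "gaussian",
                         base: float = math.e) -> float:
    """Differential entropy of a sample, in units of ``log(base)``.

    gaussian
        0.5 * ln(2*pi*e*var) with the unbiased sample variance; a
        zero-variance sample is an error.
    histogram
        Plug-in estimate -sum_b p_b * ln(p_b / w) over occupied bins of
        Freedman–Diaconis width w; needs at least two distinct values.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least two samples")
    if estimator == "gaussian":
        var = float(np.var(x, ddof=1))
        if var <= 0.0:
            raise ValueError("zero variance: Gaussian entropy undefined")
        de = 0.5 * math.log(2.0 * math.pi * math.e * var)
    elif estimator == "histogram":
        if np.unique(x).size < 2:
            raise ValueError("histogram estimator needs >= 2 distinct values")
        counts, edges = np.histogram(x, bins="fd")
        w = float(edges[1] - edges[0])
        p = counts[counts > 0] / len(x)
        de = float(-np.sum(p * np.log(p / w)))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return de / math.log(base)


def regional_de(records: pd.DataFrame, region: RegionSpec) -> pd.DataFrame:
    """Average per-node DE over a region, per subject and segment.

    ``records`` needs columns subject, group, segment, node, de.  Every
    region channel must be present for every (subject, segment); a missing
    node is an error naming it.
    """
    required = {"subject", "group", "segment", "node", "de"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns {sorted(missing_cols)}")
    wanted = set(region.channels)
    sub = records[records["node"].isin(wanted)]
    rows = []
    for (subject, grp, seg), cell in sub.groupby(["subject", "group", "segment"]):
        present = set(cell["node"])
        absent = wanted - present
        if absent:
            raise ValueError(
                f"subject {subject} segment {seg}: region node "
                f"{sorted(absent)[0]!r} missing"
            )
        rows.append({"subject": subject, "group": grp, "segment": seg,
                     "region": region.name, "de": float(cell["de"].mean())})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StatResult:
    """Outcome of a two-group rank-sum comparison."""

    u_stat: float
    z_stat: float
    p_value: float
    n1: int
    n2: int
    method: str
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_level


def _u_statistic(pooled_ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    return float(np.sum(pooled_ranks[list(idx)]) - n1 * (n1 + 1) / 2.0)


def _normal_z(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0.0:
        return 0.0
    cc = 0.5 if u > mu else (-0.5 if u < mu else 0.0)
    return (u - mu - cc) / math.sqrt(var)


def rank_sum_test(a: Iterable[float], b: Iterable[float],
                  mode: str = "auto", alpha_level: float = 0.05) -> StatResult:
    """Two-sided Wilcoxon rank-sum / Mann–Whitney U test.

    Modes: ``exact`` enumerates the permutation null over all C(n1+n2, n1)
    group assignments of the pooled midranks (feasible for n1+n2 <= 16 and
    valid under ties); ``normal`` uses the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    feasible.  The reported U and Z are for sample ``a``; the two-sided
    exact p is min(1, 2*min(P(U <= u), P(U >= u))).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    if mode not in {"auto", "exact", "normal"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = _u_statistic(ranks, range(n1), n1)
    z = _normal_z(u_obs, n1, n2, pooled)
    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_LIMIT)
    if use_exact:
        n = n1 + n2
        us = np.fromiter(
            (_u_statistic(ranks, comb, n1) for comb in combinations(range(n), n1)),
            dtype=float,
        )
        lo = float(np.mean(us <= u_obs + 1e-9))
        hi = float(np.mean(us >= u_obs - 1e-9))
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"
    return StatResult(u_obs, z, min(p, 1.0), n1, n2, method, alpha_level)


def group_summary(df: pd.DataFrame, value: str = "de",
                  by: Sequence[str] = ("group", "segment", "region")) -> pd.DataFrame:
    """Mean ± SD table per cell (sample SD, n-1 denominator).

    A singleton cell reports SD 0 with a warning rather than NaN.
    """
    by = [c for c in by if c in df.columns]
    out = (df.groupby(by, as_index=False)[value]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count"))
    singles = out["n"] == 1
    if singles.any():
        warnings.warn(f"{int(singles.sum())} singleton cell(s): SD reported as 0")
        out.loc[singles, "sd"] = 0.0
    return out
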