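"""Hypothesis tests used in the descriptive comparisons.

Two tests only: the Pearson chi-square on 2x2 count tables (no continuity
correction -- the compared counts are in the thousands) and the two-sided
Mann-Whitney rank-sum test used to compare per-center reduction ratios
between high and low epidemic-incidence zones. The rank-sum test uses exact
enumeration for small samples (combined size <= 12) and otherwise a normal
approximation with midranks and tie-corrected variance, without continuity
correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, ValidationError

EXACT_THRESHOLD = 12  # combined sample size at or below which we enumerate


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float  # min(U1, U2), the classic Mann-Whitney U
    p_value: float
    method: str  # "exact" or "normal"
    all_tied: bool = False  # every pooled value identical; p = 1 by convention


def chi_square_2x2(a: float, b: float, c: float, d: float) -> ChiSquareResult:
    """Pearson chi-square for the 2x2 table ``[[a, b], [c, d]]``, 1 df.

    Computed via the closed form ``N (ad - bc)^2 / (r1 r2 c1 c2)`` without
    Yates correction; the p-value is the upper chi-square tail.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError(f"negative cell count {x}")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("2x2 table has an empty margin")
    n = r1 + r2
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return ChiSquareResult(statistic=float(statistic), p_value=float(sps.chi2.sf(statistic, df=1)))


def _u_from_ranksum(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u1_obs: float) -> float:
    """Two-sided exact p by full enumeration of group-label assignments.

    Works on midranks, so ties are handled by the same statistic as the
    asymptotic branch. p = 2 * min(P(U1 <= u), P(U1 >= u)), capped at 1.
    """
    total = 0
    le = ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(len(ranks)), n1):
        u1 = _u_from_ranksum(float(ranks[list(combo)].sum()), n1)
        total += 1
        if u1 <= u1_obs + eps:
            le += 1
        if u1 >= u1_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test comparing two independent groups.

    Exact enumeration when the combined sample size is at most
    ``EXACT_THRESHOLD``; otherwise the normal approximation with midranks
    and tie-corrected variance. When every pooled value is identical the
    test is uninformative and returns ``p = 1`` with ``all_tied=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            u_statistic=n1 * n2 / 2.0, p_value=1.0, method="degenerate", all_tied=True
        )
    ranks = sps.rankdata(pooled)  # midranks
    u1 = _u_from_ranksum(float(ranks[:n1].sum()), n1)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    n = n1 + n2
    if n <= EXACT_THRESHOLD:
        p = _exact_two_sided_p(ranks, n1, u1)
        return RankSumResult(u_statistic=u, p_value=p, method="exact")
    # normal approximation, tie-corrected variance, no continuity correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return RankSumResult(u_statistic=u, p_value=1.0, method="normal", all_tied=True)
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return RankSumResult(u_statistic=u, p_value=min(1.0, p), method="normal")
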