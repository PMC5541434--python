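"""Rank statistics shared by the similarity and association modules.

The one-sided Mann-Whitney U test is computed exactly for small samples and
by a tie-corrected normal approximation for large ones:

* combined n <= 16 — full enumeration of all C(n, n1) group assignments of
  the pooled midranks, valid with or without ties;
* combined n <= 50 and no ties — the exact null distribution via the
  count-generating recursion (scipy's exact method);
* otherwise — normal approximation with tie correction and continuity
  correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["MannWhitneyResult", "mann_whitney_one_sided"]

_ENUMERATION_LIMIT = 16
_EXACT_LIMIT = 50


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "enumeration", "exact" or "asymptotic"


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def _enumerate_p(x: np.ndarray, y: np.ndarray, alternative: str) -> MannWhitneyResult:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks, so ties are handled exactly
    n1 = len(x)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    count = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n1):
        u = _u_from_ranks(ranks[list(idx)].sum(), n1)
        if alternative == "greater":
            count += u >= u_obs - eps
        else:
            count += u <= u_obs + eps
        total += 1
    return MannWhitneyResult(u=u_obs, p=count / total, method="enumeration")


def mann_whitney_one_sided(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U test of sample ``x`` against sample ``y``.

    ``alternative="greater"`` tests the alternative that values in ``x``
    tend to exceed those in ``y``. Returns the U statistic of ``x`` and the
    one-sided p-value.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n = len(x) + len(y)
    if n <= _ENUMERATION_LIMIT:
        return _enumerate_p(x, y, alternative)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    if n <= _EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")
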