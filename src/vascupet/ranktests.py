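"""Exact small-sample Wilcoxon tests by complete enumeration.

At the sample sizes of a small-animal study (n = 5 or 6 per group) normal
approximations to the rank-test null distributions are unreliable, and ties
make published critical-value tables ambiguous.  Both tests here therefore
enumerate the complete null distribution — all 2^n sign patterns for the
signed-rank test, all C(n+m, n) group allocations for the rank-sum test —
with midranks for ties, and report the conventional min-tail statistic
(min(W+, W-) and min(U_A, U_B)) together with an exact two-tailed p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError, ValidationError

_MAX_N = 20  # complete enumeration stays trivially fast up to here


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    n: int
    p_two_tailed: float
    method: str
    m: int | None = None
    n_zeros_dropped: int = 0


def signed_rank_exact(
    x: "np.ndarray | list", y: "np.ndarray | list | None" = None
) -> RankTestResult:
    """Exact two-tailed Wilcoxon signed-rank test.

    ``x`` is either the paired differences, or the first sample with ``y``
    the second (differences ``x - y``).  Zero differences are dropped and
    their count reported.  The statistic is W = min(W+, W-) over midranked
    absolute differences; the p-value enumerates all 2^n sign patterns.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValidationError("need a 1D, nonempty array of paired differences")
    zeros = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n > _MAX_N:
        raise ValidationError(f"exact enumeration supports n <= {_MAX_N}, got {n}")

    ranks = rankdata(np.abs(d))  # midranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)

    # Null distribution of 2*W+ (integer-valued) by dynamic programming
    # over the 2^n equally likely sign patterns.
    r2 = np.rint(2 * ranks).astype(int)
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= 2.0**n

    w2 = int(np.rint(2 * w))
    tot2 = int(np.rint(2 * total))
    p = float(dist[: w2 + 1].sum() + dist[tot2 - w2 :].sum())
    return RankTestResult(
        statistic=w,
        n=n,
        p_two_tailed=min(p, 1.0),
        method="signed_rank",
        n_zeros_dropped=zeros,
    )


def rank_sum_exact(group_a, group_b) -> RankTestResult:
    """Exact two-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    Reports U = min(U_A, U_B) with an exact p-value from complete
    enumeration of all C(n+m, n) allocations of the pooled midranks.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n, m = a.size, b.size
    if n + m > _MAX_N:
        raise ValidationError(f"exact enumeration supports n + m <= {_MAX_N}")

    ranks = rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n].sum())
    u_a = r_a - n * (n + 1) / 2.0
    u_b = n * m - u_a
    u = min(u_a, u_b)

    n_total = math.comb(n + m, n)
    count = 0
    for idx in itertools.combinations(range(n + m), n):
        ua = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if ua <= u + 1e-9 or ua >= n * m - u - 1e-9:
            count += 1
    return RankTestResult(
        statistic=u,
        n=n,
        m=m,
        p_two_tailed=min(count / n_total, 1.0),
        method="rank_sum",
    )


def mean_se(values) -> tuple[float, float]:
    """Sample mean and standard error (n-1 denominator, / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("mean +/- SE needs at least two values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))
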