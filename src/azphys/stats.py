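"""Small-sample statistics: exact Mann-Whitney U, two-sample t tests from
raw values or summary statistics, and a permutation test for grouped
curves.

With n = 4 vs 4 per group (the typical per-animal imaging design) the
exact two-sided Mann-Whitney p-values lie on the lattice k / C(8,4) =
k/70, e.g. 2/70 = 0.0286 for complete separation.  The exact test
enumerates all C(n1+n2, n1) group labelings of the observed values, which
handles ties correctly through mid-ranks and the exact conditional
distribution.

The unit-of-analysis tag exists to prevent pseudo-replication: imaging
comparisons are made per animal, electrophysiology per terminal/cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError

__all__ = [
    "GroupSample",
    "exact_mann_whitney",
    "t_test",
    "t_test_from_summary",
    "permutation_curve_test",
]


@dataclass(frozen=True)
class GroupSample:
    """Values of one group with its unit of analysis (animal|cell|terminal)."""

    values: tuple
    label: str = ""
    unit: str = "animal"

    def __post_init__(self):
        if self.unit not in ("animal", "cell", "terminal"):
            raise InvalidParameterError("unit must be animal|cell|terminal")
        if len(self.values) < 1:
            raise InvalidParameterError("empty group")


def _as_values(g) -> np.ndarray:
    if isinstance(g, GroupSample):
        return np.asarray(g.values, float)
    v = np.asarray(list(g), float)
    if v.size == 0:
        raise InvalidParameterError("empty group")
    return v


def exact_mann_whitney(a, b, max_total: int = 20):
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Returns (U, p) where U is the statistic of the first sample (rank sum
    minus its minimum) using mid-ranks for ties, and p is the exact
    conditional two-sided p-value 2*min(P(U <= u), P(U >= u)) capped at 1.
    Enumeration is limited to combined n <= ``max_total``.
    """
    x, y = _as_values(a), _as_values(b)
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n > max_total:
        raise InvalidParameterError(
            f"combined n = {n} exceeds exact-enumeration limit {max_total}")
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    idx = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp,
        count=comb(n, n1) * n1).reshape(-1, n1)
    u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    p_lo = np.mean(u_all <= u_obs + eps)
    p_hi = np.mean(u_all >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return float(u_obs), float(p)


def t_test(a, b, variant: str = "student"):
    """Two-sample t test on raw values.  Returns (t, df, two-sided p).

    ``variant`` is 'student' (pooled variance) or 'welch'.  Zero variance
    in both groups with equal means is degenerate and raises."""
    x, y = _as_values(a), _as_values(b)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, float(x.size + y.size - 2), 1.0
    equal_var = variant == "student"
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def t_test_from_summary(mean1, sem1, n1, mean2, sem2, n2,
                        variant: str = "student"):
    """Two-sample t test reconstructed from mean +- SEM and n per group
    (SD = SEM * sqrt(n)).  Returns (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise InvalidParameterError("SEM must be > 0")
    sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    equal_var = variant == "student"
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def permutation_curve_test(curves_a, curves_b, n_perm: int = 999,
                           seed: int | None = None):
    """Permutation test for a group difference between families of curves
    sharing an x-grid (stand-in for ANOVA-style curve comparisons).

    Statistic: sum over x of squared group-mean differences.  p-value by
    random relabeling of whole curves, (1 + #{T* >= T}) / (1 + n_perm).
    Returns (statistic, p).
    """
    a = np.atleast_2d(np.asarray(curves_a, float))
    b = np.atleast_2d(np.asarray(curves_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidParameterError("need >= 2 curves per group")
    if a.shape[1] != b.shape[1]:
        raise InvalidParameterError("curves must share the x-grid")
    if n_perm < 999:
        raise InvalidParameterError("n_perm must be >= 999")

    def stat(ga, gb):
        return float(np.sum((ga.mean(axis=0) - gb.mean(axis=0)) ** 2))

    t_obs = stat(a, b)
    pool = np.vstack([a, b])
    n1 = a.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        if stat(pool[perm[:n1]], pool[perm[n1:]]) >= t_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return t_obs, float(p)
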