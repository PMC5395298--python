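"""Paired and two-sample tests used by the tuning-range analyses.

The conventions here are matched to how the source statistics are reported:
the Wilcoxon statistic W is the sum of the ranks of the positive differences
(zeros discarded, mid-ranks for ties), the sign statistic S is the count of
positive differences, and the Mann-Whitney U is computed with mid-ranks.
Small-sample branches are exact by enumeration; larger samples use normal
approximations with tie corrections.  All p-values are two-sided.

The Moore test is a rank-weighted Rayleigh test for paired angles: each pair
contributes a difference vector (cos a - cos b, sin a - sin b); the vectors
are ranked by magnitude and the resultant of rank-weighted unit vectors,
scaled by n^(3/2), gives R'.  Because the published critical-value tables
are coarse, the p-value is estimated from a seeded rotation-permutation null
and the tabulated bound is reported alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .tuning import SingularDesignError

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "sign_test",
    "mann_whitney_u",
    "moore_paired_angle_test",
    "weighted_linregress",
    "DegenerateInputError",
]

# Approximate 5%/1% critical values for Moore's R' (large-sample row of the
# published table); used only for the reported bound, not the p-value.
_MOORE_CRIT = {0.10: 0.919, 0.05: 1.048, 0.01: 1.329}


class DegenerateInputError(ValueError):
    """The input carries no information for the requested test."""


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    n: int
    p: float
    method_notes: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _wilcoxon_W(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = _midranks(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), ranks


def wilcoxon_signed_rank(diffs, exact_max_n: int = 15) -> TestResult:
    """Wilcoxon signed-rank test of median zero for paired differences.

    W is the positive-rank sum after discarding zeros.  For n <= 15 the
    two-sided p is exact, from the full 2^n sign-assignment distribution
    (valid with ties); otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateInputError("all differences are zero")
    W, ranks = _wilcoxon_W(diffs)
    mean = n * (n + 1) / 4.0
    if n <= exact_max_n:
        # enumerate all sign assignments of the observed |rank| multiset
        tail = sum(
            1
            for signs in itertools.product((0.0, 1.0), repeat=n)
            if abs(np.dot(signs, ranks) - mean) >= abs(W - mean) - 1e-12
        )
        p = tail / 2.0**n
        notes = "exact enumeration over sign assignments"
    else:
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, counts = np.unique(np.abs(diffs), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
        z = (abs(W - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(z))
        notes = "normal approximation with tie and continuity correction"
    return TestResult("W", W, n, p, notes)


def sign_test(diffs) -> TestResult:
    """Exact two-sided sign test; S counts positive nonzero differences."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateInputError("all differences are zero")
    S = int(np.sum(diffs > 0))
    p = min(1.0, 2.0 * min(sps.binom.cdf(S, n, 0.5), sps.binom.sf(S - 1, n, 0.5)))
    return TestResult("S", float(S), n, p, "exact binomial")


def mann_whitney_u(x, y, exact_max_comb: int = 200_000) -> TestResult:
    """Mann-Whitney U test (U reported for the first sample, mid-ranks).

    Exact p by enumeration of group assignments when C(nx+ny, nx) is small
    enough (valid with ties); otherwise tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    U = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mean = nx * ny / 2.0
    if math.comb(nx + ny, nx) <= exact_max_comb:
        ranks_sorted = ranks  # enumeration over index subsets of the pooled ranks
        tail = 0
        total = 0
        base = nx * (nx + 1) / 2.0
        for idx in itertools.combinations(range(nx + ny), nx):
            u = ranks_sorted[list(idx)].sum() - base
            total += 1
            if abs(u - mean) >= abs(U - mean) - 1e-12:
                tail += 1
        p = tail / total
        notes = "exact enumeration over group assignments"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        n = nx + ny
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        z = (abs(U - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(z))
        notes = "normal approximation with tie and continuity correction"
    return TestResult("U", U, nx + ny, p, notes)


def moore_R(angles_a_deg, angles_b_deg) -> tuple[float, np.ndarray, np.ndarray]:
    """R' statistic and the per-pair difference vectors (ranks, angles)."""
    a = np.radians(np.asarray(angles_a_deg, dtype=float))
    b = np.radians(np.asarray(angles_b_deg, dtype=float))
    dx = np.cos(a) - np.cos(b)
    dy = np.sin(a) - np.sin(b)
    mag = np.hypot(dx, dy)
    ranks = _midranks(mag)
    theta = np.arctan2(dy, dx)  # angle of a zero vector is 0; weight via rank
    n = len(a)
    X = np.sum(ranks * np.cos(theta))
    Y = np.sum(ranks * np.sin(theta))
    return float(math.hypot(X, Y) / n**1.5), ranks, theta


def moore_paired_angle_test(
    angles_a_deg,
    angles_b_deg,
    n_resamples: int = 10_000,
    seed: int | None = 0,
) -> TestResult:
    """Moore's paired-angle test with a rotation-permutation p-value.

    Under the null of no systematic angular change, the directions of the
    per-pair difference vectors are uniform; the null distribution of R' is
    built by independently rotating each difference vector by a uniform
    random angle (magnitudes, hence ranks, are preserved).
    """
    a = np.asarray(angles_a_deg, dtype=float)
    b = np.asarray(angles_b_deg, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    dx = np.cos(np.radians(a)) - np.cos(np.radians(b))
    dy = np.sin(np.radians(a)) - np.sin(np.radians(b))
    if np.all(np.hypot(dx, dy) == 0.0):
        raise DegenerateInputError("all difference vectors are zero")
    R, ranks, _ = moore_R(a, b)
    rng = np.random.default_rng(seed)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=(n_resamples, n))
    X = (ranks * np.cos(phis)).sum(axis=1)
    Y = (ranks * np.sin(phis)).sum(axis=1)
    null = np.hypot(X, Y) / n**1.5
    p = float((np.sum(null >= R - 1e-12) + 1) / (n_resamples + 1))
    bound = "P>0.10"
    for alpha, crit in sorted(_MOORE_CRIT.items(), reverse=True):
        if R >= crit:
            bound = f"P<{alpha:.2f}"
    return TestResult(
        "R'",
        R,
        n,
        p,
        "rotation-permutation null; tabulated bound in extra['table_bound']",
        extra={"table_bound": bound},
    )


def weighted_linregress(x, y, w=None) -> TestResult:
    """Weighted least-squares line fit with an F-test of the slope.

    Minimizes sum w (y - a - b x)^2; the F statistic compares the line
    against the weighted constant model with (1, n-2) degrees of freedom.
    Returns slope as the statistic; intercept, F and their values in extra.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    pos = w > 0
    if len(np.unique(x[pos])) < 2:
        raise SingularDesignError("all positive-weight x values identical")
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = np.sum(w * (y - intercept - slope * x) ** 2)
    tss = np.sum(w * (y - ybar) ** 2)
    n = int(np.sum(pos))
    dof = n - 2
    if rss <= 0 or dof <= 0:
        F = np.inf if tss > rss else 0.0
        p = 0.0 if F == np.inf else 1.0
    else:
        F = (tss - rss) / (rss / dof)
        p = float(sps.f.sf(F, 1, dof))
    return TestResult(
        "slope",
        float(slope),
        n,
        p,
        "weighted least squares; F-test vs constant model",
        extra={"intercept": float(intercept), "F": float(F), "dof": dof},
    )
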