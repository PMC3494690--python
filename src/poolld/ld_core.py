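"""Direct and approximate maximum-likelihood r^2 estimators.

Two estimators of the squared allelic correlation r^2 between a pair of
SNPs, both driven by the 2x2 intersecting-template haplotype table:

* **direct**: r^2 computed naively from the table itself — pA = (x11+x12)/n,
  pB = (x11+x21)/n, D = x11/n − pA·pB, r^2 = D²/(pA(1−pA)pB(1−pB)).

* **approximate ML**: the table is treated as multinomial with expected cell
  proportions f_ij(pA', pB', D), where pA', pB' are allele frequencies from
  ALL reads covering each locus (more precise than the intersecting-read
  marginals) and are held fixed rather than re-estimated — maximizing over
  the single parameter D. Because the intersecting templates are a subset of
  all reads, the all-read frequencies may be incongruent with the table; the
  likelihood maximum then sits on the boundary of the feasible D range and
  the estimate is flagged.

A pooled sample is a double draw — chromosomes into the pool, then reads
from chromosomes — so n templates carry less information than n haplotypes.
The effective number of observations n_eff = d·c/(d+c) (read depth d,
chromosomes c) rescales the cell counts in the log-likelihood, inflating the
variance accordingly; the profile confidence interval is the set of D whose
log-likelihood is within 1.96 units of the maximum, mapped to r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .pair_counting import HaplotypeTable

# orientation of D in each cell of the (major,major / major,minor / ...) table
_SIGNS = np.array([1.0, -1.0, -1.0, 1.0])

#: CI half-width in log-likelihood units (as printed: 1.96, not chi2_1/2)
LL_UNITS = 1.96


@dataclass
class DirectResult:
    r2: float  # NaN when undefined (monomorphic among intersecting reads)
    p_a: float
    p_b: float
    d: float
    defined: bool


@dataclass
class MleResult:
    r2: float
    ci_low: float
    ci_high: float
    boundary: bool
    d_hat: float
    n_eff: float


@dataclass
class LdEstimate:
    """Everything reported for one SNP pair."""

    chrom: str
    pos_a: int
    pos_b: int
    n: int
    n_eff: float
    p_a: float
    p_b: float
    p_a_all: float
    p_b_all: float
    depth_a: int
    depth_b: int
    maf_a_all: float
    maf_b_all: float
    r2_direct: float
    r2_mle: float
    ci_low: float
    ci_high: float
    boundary: bool
    d_hat: float

    @property
    def distance(self) -> int:
        return self.pos_b - self.pos_a


def direct_r2(table: HaplotypeTable) -> DirectResult:
    """Naive r^2 from the haplotype table's own counts.

    Undefined when either locus is monomorphic among the intersecting
    templates (pA or pB in {0,1}); then ``r2`` is NaN and ``defined`` False —
    never a division by zero.
    """
    x11, x12, x21, x22 = table.counts
    n = table.n
    if n <= 0:
        raise ValueError("empty haplotype table")
    p_a = (x11 + x12) / n
    p_b = (x11 + x21) / n
    d = x11 / n - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return DirectResult(float("nan"), p_a, p_b, d, defined=False)
    r2 = d * d / denom
    return DirectResult(min(max(r2, 0.0), 1.0), p_a, p_b, d, defined=True)


def feasible_D_range(p_a: float, p_b: float) -> tuple[float, float]:
    """Range of the disequilibrium coefficient D keeping all f_ij >= 0."""
    d_min = max(-p_a * p_b, -(1 - p_a) * (1 - p_b))
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    return d_min, d_max


def expected_haplotype_freqs(
    p_a: float, p_b: float, d: float
) -> tuple[float, float, float, float]:
    """Expected haplotype proportions f_ij given marginals and D.

    f11 = pA·pB + D, f12 = pA(1−pB) − D, f21 = (1−pA)pB − D,
    f22 = (1−pA)(1−pB) + D; non-negative and summing to one for feasible D.
    """
    d_min, d_max = feasible_D_range(p_a, p_b)
    if d < d_min - 1e-12 or d > d_max + 1e-12:
        raise ValueError(f"infeasible D={d} for pA={p_a}, pB={p_b}")
    f11 = p_a * p_b + d
    f12 = p_a * (1 - p_b) - d
    f21 = (1 - p_a) * p_b - d
    f22 = (1 - p_a) * (1 - p_b) + d
    return (max(f11, 0.0), max(f12, 0.0), max(f21, 0.0), max(f22, 0.0))


def effective_n(depth: float, n_chrom: int) -> float:
    """Effective number of observations under double binomial sampling.

    Reads are drawn from pooled chromosomes, which were drawn from the
    population; composing the two binomial stages gives
    n_eff = depth·n_chrom/(depth + n_chrom), strictly below both.
    """
    if depth <= 0 or n_chrom <= 0:
        raise ValueError("depth and n_chrom must be positive")
    return depth * n_chrom / (depth + n_chrom)


def _loglik_grid(
    xe: np.ndarray, f0: np.ndarray, d_grid: np.ndarray
) -> np.ndarray:
    """Vectorized log-likelihood over a grid of D values."""
    f = f0[None, :] + np.outer(d_grid, _SIGNS)
    np.clip(f, 0.0, None, out=f)
    active = xe > 0
    with np.errstate(divide="ignore"):
        logf = np.where(f[:, active] > 0, np.log(f[:, active]), -np.inf)
    return logf @ xe[active]


def approx_mle_r2(
    table: HaplotypeTable,
    p_a_all: float,
    p_b_all: float,
    n_chrom: int,
    grid_points: int = 1001,
) -> MleResult:
    """Approximate-ML r^2 conditional on the all-read allele frequencies.

    The cell counts are rescaled by n_eff/n before entering the multinomial
    log-likelihood l(D) = sum x_ij^eff · log f_ij(pA', pB', D), which is then
    maximized over signed D across the full feasible range by a dense grid
    plus local refinement (l is concave on the open interval). ``boundary``
    is True when the maximizer is pinned at an edge of the range — the
    incongruent case. The CI is the image in r^2 of
    {D : l(D) >= l(D_hat) − 1.96}.
    """
    if not (0.0 < p_a_all < 1.0 and 0.0 < p_b_all < 1.0):
        raise ValueError("all-read frequencies must lie strictly in (0,1)")
    x = np.asarray(table.counts, dtype=float)
    n = x.sum()
    if n < 1:
        raise ValueError("empty haplotype table")
    n_eff = effective_n(n, n_chrom)
    xe = x * (n_eff / n)

    d_min, d_max = feasible_D_range(p_a_all, p_b_all)
    span = d_max - d_min
    f0 = np.array(
        [
            p_a_all * p_b_all,
            p_a_all * (1 - p_b_all),
            (1 - p_a_all) * p_b_all,
            (1 - p_a_all) * (1 - p_b_all),
        ]
    )

    def negll(d: float) -> float:
        f = f0 + _SIGNS * d
        total = 0.0
        for xi, fi in zip(xe, f):
            if xi > 0:
                if fi <= 0:
                    return math.inf
                total += xi * math.log(fi)
        return -total

    d_grid = np.linspace(d_min, d_max, grid_points)
    ll = _loglik_grid(xe, f0, d_grid)
    k = int(np.argmax(ll))
    lo = d_grid[max(k - 1, 0)]
    hi = d_grid[min(k + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded", options={"xatol": span * 1e-9}
    )
    d_hat = float(res.x)
    ll_max = -float(res.fun)
    # the supremum may sit exactly on the boundary where negll is +inf
    eps = span * 1e-6
    boundary = False
    if d_hat - d_min <= eps or k == 0:
        if -negll(d_min) >= ll_max or d_hat - d_min <= eps:
            d_hat, boundary = d_min, True
    if d_max - d_hat <= eps or k == grid_points - 1:
        if -negll(d_max) >= ll_max or d_max - d_hat <= eps:
            d_hat, boundary = d_max, True
    if boundary:
        ll_max = max(ll_max, -negll(d_hat)) if math.isfinite(negll(d_hat)) else ll_max

    denom = p_a_all * (1 - p_a_all) * p_b_all * (1 - p_b_all)
    r2 = min(max(d_hat * d_hat / denom, 0.0), 1.0)

    ci_low, ci_high = _profile_ci(negll, ll_max, d_hat, d_min, d_max, denom, d_grid, ll)
    ci_low = min(ci_low, r2)
    ci_high = max(ci_high, r2)
    return MleResult(r2, ci_low, ci_high, boundary, d_hat, n_eff)


def _profile_ci(
    negll,
    ll_max: float,
    d_hat: float,
    d_min: float,
    d_max: float,
    denom: float,
    d_grid: np.ndarray,
    ll: np.ndarray,
) -> tuple[float, float]:
    """Map {D : l(D) >= l_max − LL_UNITS} to an interval in r^2.

    By concavity the D-set is an interval [d_lo, d_hi]; r^2 = D²/denom is
    monotone away from zero, so the r^2 interval's endpoints come from the
    D endpoints, with minimum 0 when the interval straddles D = 0.
    """
    cut = ll_max - LL_UNITS

    def g(d: float) -> float:
        v = -negll(d)
        return (v if math.isfinite(v) else -1e30) - cut

    # left endpoint
    if g(d_min) >= 0:
        d_lo = d_min
    else:
        a = d_min
        below = d_grid[(d_grid < d_hat) & (ll < cut)]
        if below.size:
            a = float(below[-1])
        d_lo = optimize.brentq(g, a, d_hat, xtol=1e-12) if d_hat > a else d_hat
    if g(d_max) >= 0:
        d_hi = d_max
    else:
        b = d_max
        above = d_grid[(d_grid > d_hat) & (ll < cut)]
        if above.size:
            b = float(above[0])
        d_hi = optimize.brentq(g, d_hat, b, xtol=1e-12) if b > d_hat else d_hat

    r2_lo_end = d_lo * d_lo / denom
    r2_hi_end = d_hi * d_hi / denom
    ci_high = min(max(r2_lo_end, r2_hi_end), 1.0)
    ci_low = 0.0 if d_lo <= 0.0 <= d_hi else min(r2_lo_end, r2_hi_end)
    return min(ci_low, 1.0), ci_high
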