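"""Coverage validation and rank-uniformity validation for scalar functionals.

Coverage validation: for each of n replicates whose true parameter was
drawn from the prior, the shortest (highest-posterior-density) interval at
credibility ``alpha`` is built from the replicate's L posterior draws; if
the implementation is correct the covered count is Binomial(n, alpha), so
it must fall inside the central binomial interquantile bounds (e.g. 90..99
of 100 at alpha = 0.95).

Rank-uniformity validation (the simulation-based-calibration rank check):
the rank of the true value among its L posterior draws is uniform on
[1, L+1] under correctness.  Departures are diagnosed with a binned rank
histogram (per-bin binomial bands), an ECDF with a Monte-Carlo simultaneous
band, a chi-square goodness-of-fit test, and a coarse pattern tag (central
hump = overdispersed estimates, horns = underdispersed or autocorrelated,
left/right shift = systematic over-/under-estimation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReplicateResult",
    "CredibleInterval",
    "RankRecord",
    "CoverageReport",
    "RankHistogram",
    "EcdfBand",
    "RuvVerdict",
    "hpd_interval",
    "binomial_central_interval",
    "coverage_count",
    "sbc_rank",
    "rank_histogram",
    "ecdf_band",
    "ruv_verdict",
]


@dataclass(frozen=True)
class ReplicateResult:
    """True value and its L retained posterior draws for one replicate."""

    index: int
    true_value: float
    draws: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "draws", np.asarray(self.draws, dtype=float))


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    level: float


@dataclass(frozen=True)
class RankRecord:
    """SBC rank of a true value among L posterior draws, on [1, L+1]."""

    rank: int
    L: int
    tie_broken: bool = False


@dataclass
class CoverageReport:
    parameter: str
    covered: int
    n: int
    alpha: float
    bound_lo: int
    bound_hi: int
    passed: bool
    records: list = field(default_factory=list)  # (index, true, lower, upper, covered)

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.covered / self.n

    def summary(self) -> str:
        return (
            f"{self.parameter}: {self.covered}/{self.n} covered at alpha={self.alpha} "
            f"vs bounds ({self.bound_lo}, {self.bound_hi}) -> "
            f"{'pass' if self.passed else 'FAIL'}"
        )


# ----------------------------------------------------------------------
# intervals and coverage
# ----------------------------------------------------------------------

def hpd_interval(samples, alpha: float) -> CredibleInterval:
    """Shortest interval containing ceil(alpha * L) of the sorted samples.

    Ties in width are resolved toward the lowest start index.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    L = x.size
    if L < 20:
        raise ValueError(f"need >= 20 samples for an HPD estimate, got {L}")
    m = math.ceil(alpha * L)
    widths = x[m - 1 :] - x[: L - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return CredibleInterval(float(x[i]), float(x[i + m - 1]), alpha)


def binomial_central_interval(n: int, alpha: float, level: float = 0.95) -> tuple[int, int]:
    """Central interquantile bounds of Binomial(n, alpha) at the given level."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lo = int(stats.binom.ppf((1.0 - level) / 2.0, n, alpha))
    hi = int(stats.binom.ppf(1.0 - (1.0 - level) / 2.0, n, alpha))
    return lo, hi


def coverage_count(
    replicates: Sequence[ReplicateResult],
    alpha: float,
    parameter: str = "",
    level: float = 0.95,
) -> CoverageReport:
    """Count replicates whose closed HPD interval [a, b] contains the truth."""
    if len(replicates) < 2:
        raise ValueError("coverage needs at least 2 replicates")
    records = []
    covered = 0
    for rep in replicates:
        ci = hpd_interval(rep.draws, alpha)
        hit = ci.lower <= rep.true_value <= ci.upper
        covered += hit
        records.append((rep.index, rep.true_value, ci.lower, ci.upper, bool(hit)))
    n = len(replicates)
    lo, hi = binomial_central_interval(n, alpha, level)
    return CoverageReport(
        parameter=parameter,
        covered=covered,
        n=n,
        alpha=alpha,
        bound_lo=lo,
        bound_hi=hi,
        passed=lo <= covered <= hi,
        records=records,
    )


# ----------------------------------------------------------------------
# ranks
# ----------------------------------------------------------------------

def sbc_rank(true_value: float, draws, rng: np.random.Generator) -> RankRecord:
    """Rank of the truth among its draws: 1 + #{draws < truth}, ties randomized.

    With t draws exactly equal to the truth the rank is uniform over the
    t + 1 positions the truth could occupy — the standard randomized
    tie-break, essential for discrete functionals (e.g. tree distances).
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one draw")
    less = int(np.count_nonzero(x < true_value))
    ties = int(np.count_nonzero(x == true_value))
    if ties:
        return RankRecord(1 + less + int(rng.integers(0, ties + 1)), x.size, True)
    return RankRecord(1 + less, x.size, False)


def _normalized(ranks: Sequence[RankRecord]) -> np.ndarray:
    Ls = {r.L for r in ranks}
    if len(Ls) != 1:
        raise ValueError(f"ranks mix different L values: {sorted(Ls)}")
    L = Ls.pop()
    return np.array([r.rank for r in ranks], dtype=float) / (L + 1)


@dataclass
class RankHistogram:
    counts: np.ndarray
    bins: int
    n: int
    expected: float
    band_lo: int
    band_hi: int
    edges: np.ndarray

    @property
    def outside_band(self) -> np.ndarray:
        return (self.counts < self.band_lo) | (self.counts > self.band_hi)


def rank_histogram(ranks: Sequence[RankRecord], bins: int = 20) -> RankHistogram:
    """Bin normalized ranks into equal-width bins on (0, 1] with binomial bands."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    n = len(ranks)
    if n < bins:
        raise ValueError(f"n={n} ranks cannot fill {bins} bins; use fewer bins")
    u = _normalized(ranks)
    idx = np.clip(np.ceil(u * bins).astype(int) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    if np.any(counts == 0):
        warnings.warn(
            "empty rank-histogram bin(s): bins may be too narrow or L too low"
        )
    lo, hi = binomial_central_interval(n, 1.0 / bins)
    return RankHistogram(
        counts=counts,
        bins=bins,
        n=n,
        expected=n / bins,
        band_lo=lo,
        band_hi=hi,
        edges=np.linspace(0.0, 1.0, bins + 1),
    )


@dataclass
class EcdfBand:
    grid: np.ndarray
    ecdf: np.ndarray      # counts / n at each grid point
    lower: np.ndarray     # simultaneous band, as fractions
    upper: np.ndarray
    level: float
    passed: bool
    pointwise_gamma: float


def ecdf_band(
    ranks: Sequence[RankRecord],
    L: int,
    rng: np.random.Generator,
    band_level: float = 0.95,
    n_mc: int = 5000,
    max_grid: int = 100,
) -> EcdfBand:
    """ECDF of normalized ranks with a Monte-Carlo simultaneous band.

    The band is the per-point central binomial envelope whose *simultaneous*
    coverage — estimated over ``n_mc`` simulated uniform rank sets of the
    same size — equals ``band_level``; the pointwise level is found by
    bisection.  Verdict: pass iff the observed ECDF stays inside the band
    at every grid point.
    """
    n = len(ranks)
    if n < 20:
        raise ValueError("ECDF band needs >= 20 ranks")
    if n_mc < 100:
        raise ValueError("need >= 100 Monte-Carlo replicates for a reliable band")
    u = _normalized(ranks)
    K = min(L + 1, max_grid)
    grid = np.arange(1, K + 1) / K
    obs = np.array([(u <= g + 1e-12).sum() for g in grid], dtype=int)

    sims = rng.integers(1, L + 2, size=(n_mc, n)) / (L + 1)
    # counts[mc, k] = #(sims[mc] <= grid[k]); ranks are discrete so use a
    # half-step offset to make the comparison exact
    cnt = (sims[:, :, None] <= grid[None, None, :] + 1e-12).sum(axis=1)

    def simultaneous_coverage(gamma: float) -> float:
        lo = stats.binom.ppf(gamma / 2.0, n, grid)
        hi = stats.binom.ppf(1.0 - gamma / 2.0, n, grid)
        inside = np.all((cnt >= lo) & (cnt <= hi), axis=1)
        return float(inside.mean())

    lo_g, hi_g = 1e-10, 1.0 - 1e-10
    for _ in range(60):
        mid = 0.5 * (lo_g + hi_g)
        if simultaneous_coverage(mid) >= band_level:
            lo_g = mid  # band can be narrowed
        else:
            hi_g = mid
    gamma = lo_g
    lo = stats.binom.ppf(gamma / 2.0, n, grid)
    hi = stats.binom.ppf(1.0 - gamma / 2.0, n, grid)
    passed = bool(np.all((obs >= lo) & (obs <= hi)))
    return EcdfBand(
        grid=grid,
        ecdf=obs / n,
        lower=lo / n,
        upper=hi / n,
        level=band_level,
        passed=passed,
        pointwise_gamma=gamma,
    )


@dataclass
class RuvVerdict:
    passed: bool
    pattern: str
    chi2_p: float
    histogram: RankHistogram
    ecdf: EcdfBand


def _pattern_tag(hist: RankHistogram, u: np.ndarray) -> str:
    thirds = np.array_split(np.arange(hist.bins), 3)
    above = [bool(np.any(hist.counts[t] > hist.band_hi)) for t in thirds]
    below = [bool(np.any(hist.counts[t] < hist.band_lo)) for t in thirds]
    if above[0] and above[2]:
        return "horns"
    if above[1] and not (above[0] or above[2]):
        return "central-hump"
    if (above[0] and not above[2]) or (below[2] and not below[0]):
        return "left-shift"
    if (above[2] and not above[0]) or (below[0] and not below[2]):
        return "right-shift"
    if below[1]:
        return "horns"
    # no bin breaches its band: fall back to moments of the normalized ranks
    mean = float(u.mean())
    if mean < 0.45:
        return "left-shift"
    if mean > 0.55:
        return "right-shift"
    var = float(u.var())
    return "central-hump" if var < 1.0 / 12.0 else "horns"


def ruv_verdict(
    ranks: Sequence[RankRecord],
    rng: np.random.Generator,
    bins: int = 20,
    gof_alpha: float = 0.01,
    band_level: float = 0.95,
    n_mc: int = 5000,
) -> RuvVerdict:
    """Combined rank-uniformity verdict.

    Pass requires both (i) chi-square goodness-of-fit against uniform bin
    counts at the ``gof_alpha`` level and (ii) the ECDF staying inside its
    simultaneous band.  The pattern tag describes which thirds of the
    histogram breach their bands (``uniform`` when the verdict passes).
    """
    hist = rank_histogram(ranks, bins=bins)
    L = ranks[0].L
    band = ecdf_band(ranks, L, rng, band_level=band_level, n_mc=n_mc)
    chi2_p = float(stats.chisquare(hist.counts).pvalue)
    passed = (chi2_p > gof_alpha) and band.passed
    pattern = "uniform" if passed else _pattern_tag(hist, _normalized(ranks))
    return RuvVerdict(passed=passed, pattern=pattern, chi2_p=chi2_p, histogram=hist, ecdf=band)
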