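"""Cross-trait LD score regression with a permutation-based empirical p value.

The model: for SNP j with LD score l_j, sample size n and M SNPs genome-wide,

    E[z_j^2]      = 1 + a     + n * h2 * l_j / M
    E[z1_j z2_j]  = intercept + sqrt(n1*n2) * rho_g * l_j / M

where the cross intercept absorbs phenotypic correlation among overlapping
samples. Heritabilities and the genetic covariance are the slopes of weighted
least-squares regressions of z^2 (resp. z1*z2) on the scaled LD score, with
two-pass heteroskedasticity weights and a delete-one block jackknife for
standard errors. The genetic correlation is r_g = rho_g / sqrt(h2_1 * h2_2).

The permutation test shuffles one trait's Z scores across SNPs while holding
the other trait and the LD scores fixed, recomputing the genetic-covariance
slope each time; the add-one empirical p value never returns 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sumstats import GenomeWideStats

logger = logging.getLogger("comogen")

DEFAULT_N_BLOCKS = 200

__all__ = [
    "LdscFit",
    "PermutationResult",
    "LdscModel",
    "fit_h2",
    "fit_rg",
    "permutation_empirical_p",
]


# ---------------------------------------------------------------------------
# Weighted least squares with per-block sufficient statistics


class _BlockWLS:
    """WLS of y on x with intercept, accumulated per contiguous block.

    Storing the five weighted sums per block makes any delete-one-block
    refit an O(1) operation, which keeps the whole-pipeline jackknife cheap.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
        bounds = np.linspace(0, len(x), n_blocks + 1).astype(int)
        stats = np.empty((n_blocks, 5))
        for b in range(n_blocks):
            s = slice(bounds[b], bounds[b + 1])
            wb, xb, yb = w[s], x[s], y[s]
            stats[b] = [wb.sum(), (wb * xb).sum(), (wb * yb).sum(),
                        (wb * xb * xb).sum(), (wb * xb * yb).sum()]
        self.block_stats = stats
        self.totals = stats.sum(axis=0)

    @staticmethod
    def _solve(t: np.ndarray) -> tuple[float, float]:
        sw, swx, swy, swxx, swxy = t
        denom = swxx * sw - swx * swx
        slope = (swxy * sw - swx * swy) / denom
        intercept = (swy - slope * swx) / sw
        return float(slope), float(intercept)

    def fit(self) -> tuple[float, float]:
        return self._solve(self.totals)

    def fit_without(self, b: int) -> tuple[float, float]:
        return self._solve(self.totals - self.block_stats[b])


def _check(stats: GenomeWideStats, n_blocks: int) -> None:
    if len(stats) < 2 * n_blocks:
        raise ValueError(
            f"need at least {2 * n_blocks} SNPs for {n_blocks} jackknife blocks, got {len(stats)}"
        )


def _h2_design(stats: GenomeWideStats):
    x = stats.n * stats.ld_score / stats.m
    y = stats.z**2
    return x, y


def _h2_weights(stats: GenomeWideStats, h2: float) -> np.ndarray:
    h2c = float(np.clip(h2, 0.0, 1.0))
    return 1.0 / (stats.ld_score * (1.0 + stats.n * h2c * stats.ld_score / stats.m) ** 2)


def fit_h2(
    stats: GenomeWideStats, n_blocks: int = DEFAULT_N_BLOCKS
) -> tuple[float, float, float]:
    """Estimate SNP heritability: returns ``(h2, intercept, jackknife_se)``.

    Two-pass weights: an initial 1/l_j fit gives a provisional h2, the final
    fit uses 1 / (l_j * (1 + n*h2*l_j/M)^2).
    """
    _check(stats, n_blocks)
    x, y = _h2_design(stats)
    slope0, _ = _BlockWLS(x, y, 1.0 / stats.ld_score, n_blocks).fit()
    wls = _BlockWLS(x, y, _h2_weights(stats, slope0), n_blocks)
    h2, intercept = wls.fit()
    deleted = np.array([wls.fit_without(b)[0] for b in range(n_blocks)])
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((deleted - deleted.mean()) ** 2).sum()))
    return h2, intercept, se


@dataclass
class LdscFit:
    """Cross-trait LDSC estimates with block-jackknife uncertainty."""

    h2_1: float
    h2_2: float
    rho_g: float
    r_g: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    se_rg: float
    n_blocks: int
    se_h2_1: float = np.nan
    se_h2_2: float = np.nan
    se_rho_g: float = np.nan

    def summary(self) -> str:
        lines = [
            "Cross-trait LD score regression",
            "===============================",
            f"h2 (trait 1)      {self.h2_1: .4f}  (se {self.se_h2_1:.4f}, intercept {self.intercept_1: .4f})",
            f"h2 (trait 2)      {self.h2_2: .4f}  (se {self.se_h2_2:.4f}, intercept {self.intercept_2: .4f})",
            f"rho_g             {self.rho_g: .4f}  (se {self.se_rho_g:.4f}, intercept {self.intercept_cross: .4f})",
            f"r_g               {self.r_g: .4f}  (jackknife se {self.se_rg:.4f}, {self.n_blocks} blocks)",
        ]
        return "\n".join(lines)


def _cross_design(s1: GenomeWideStats, s2: GenomeWideStats):
    x = np.sqrt(s1.n * s2.n) * s1.ld_score / s1.m
    y = s1.z * s2.z
    return x, y


def _cross_weights(s1: GenomeWideStats, s2: GenomeWideStats, h2_1: float, h2_2: float) -> np.ndarray:
    # Product of the two traits' variance inflations; reduces exactly to the
    # univariate weights when the two inputs are the same dataset, which makes
    # identical-trait r_g equal 1 to machine precision.
    a = 1.0 + s1.n * np.clip(h2_1, 0, 1) * s1.ld_score / s1.m
    b = 1.0 + s2.n * np.clip(h2_2, 0, 1) * s2.ld_score / s2.m
    return 1.0 / (s1.ld_score * a * b)


def fit_rg(
    stats1: GenomeWideStats,
    stats2: GenomeWideStats,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscFit:
    """Estimate genetic covariance and correlation between two traits.

    Inputs must already be restricted to shared SNPs in the same order. The
    jackknife re-runs the whole pipeline (both h2 regressions and the cross
    regression, with weights fixed at their full-data values) for every block
    deletion and propagates through to r_g.
    """
    if len(stats1) != len(stats2):
        raise ValueError("inputs must be harmonized to the same SNPs in the same order")
    _check(stats1, n_blocks)

    x1, y1 = _h2_design(stats1)
    x2, y2 = _h2_design(stats2)
    xc, yc = _cross_design(stats1, stats2)

    h1_0, _ = _BlockWLS(x1, y1, 1.0 / stats1.ld_score, n_blocks).fit()
    h2_0, _ = _BlockWLS(x2, y2, 1.0 / stats2.ld_score, n_blocks).fit()

    # second-pass weights for all three regressions use the first-pass h2
    # estimates, so the cross weights reduce exactly to the univariate ones
    # when both inputs are the same dataset
    wls1 = _BlockWLS(x1, y1, _h2_weights(stats1, h1_0), n_blocks)
    wls2 = _BlockWLS(x2, y2, _h2_weights(stats2, h2_0), n_blocks)
    h2_1, int_1 = wls1.fit()
    h2_2, int_2 = wls2.fit()
    wlsc = _BlockWLS(xc, yc, _cross_weights(stats1, stats2, h1_0, h2_0), n_blocks)
    rho_g, int_c = wlsc.fit()

    def _rg(a: float, b: float, rho: float) -> float:
        if a <= 0 or b <= 0:
            return np.nan
        return rho / np.sqrt(a * b)

    r_g = _rg(h2_1, h2_2, rho_g)
    if np.isnan(r_g):
        warnings.warn("non-positive heritability estimate: r_g undefined", stacklevel=2)

    del_h1 = np.array([wls1.fit_without(b)[0] for b in range(n_blocks)])
    del_h2 = np.array([wls2.fit_without(b)[0] for b in range(n_blocks)])
    del_rho = np.array([wlsc.fit_without(b)[0] for b in range(n_blocks)])
    with np.errstate(invalid="ignore"):
        del_rg = np.where(
            (del_h1 > 0) & (del_h2 > 0), del_rho / np.sqrt(del_h1 * del_h2), np.nan
        )

    def _jk_se(vals: np.ndarray) -> float:
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            return np.nan
        k = len(vals)
        return float(np.sqrt((k - 1) / k * ((vals - vals.mean()) ** 2).sum()))

    return LdscFit(
        h2_1=h2_1, h2_2=h2_2, rho_g=rho_g, r_g=r_g,
        intercept_1=int_1, intercept_2=int_2, intercept_cross=int_c,
        se_rg=_jk_se(del_rg), n_blocks=n_blocks,
        se_h2_1=_jk_se(del_h1), se_h2_2=_jk_se(del_h2), se_rho_g=_jk_se(del_rho),
    )


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    """Observed statistic against its permutation null distribution."""

    observed_stat: float
    permuted_stats: np.ndarray
    n_perm: int
    empirical_p: float
    statistic: str = "rho_g"

    def summary(self) -> str:
        return (
            f"permutation test ({self.statistic}): observed {self.observed_stat:.4f}, "
            f"B = {self.n_perm}, empirical p = {self.empirical_p:.4g}"
        )


def permutation_empirical_p(
    stats1: GenomeWideStats,
    stats2: GenomeWideStats,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "rho_g",
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> PermutationResult:
    """Empirical p value for the cross-trait relationship by Z-score permutation.

    Trait 2's Z scores are shuffled across SNPs ``n_perm`` times while trait 1
    and the LD scores stay fixed, and the chosen statistic is recomputed each
    time. The default statistic is the genetic-covariance slope rho_g
    (numerically stable under permutation, identical ranking to r_g);
    ``statistic="r_g"`` recomputes the full genetic correlation instead.
    The two-sided add-one estimate (1 + #{|perm| >= |obs|}) / (B + 1) is
    returned and can never be 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("rho_g", "r_g"):
        raise ValueError("statistic must be 'rho_g' or 'r_g'")
    rng = np.random.default_rng(seed)

    full = fit_rg(stats1, stats2, n_blocks=n_blocks)
    xc, _ = _cross_design(stats1, stats2)
    w = _cross_weights(stats1, stats2, full.h2_1, full.h2_2)
    sw, swx = w.sum(), (w * xc).sum()
    swxx = (w * xc * xc).sum()
    denom = swxx * sw - swx * swx

    def cross_slope(z2: np.ndarray) -> float:
        y = stats1.z * z2
        swy = (w * y).sum()
        swxy = (w * xc * y).sum()
        return float((swxy * sw - swx * swy) / denom)

    if statistic == "rho_g":
        observed = cross_slope(stats2.z)
        permuted = np.empty(n_perm)
        for b in range(n_perm):
            permuted[b] = cross_slope(rng.permutation(stats2.z))
    else:
        observed = full.r_g
        permuted = np.empty(n_perm)
        perm2 = GenomeWideStats(
            variants=stats2.variants, z=stats2.z, n=stats2.n, ld_score=stats2.ld_score, m=stats2.m
        )
        for b in range(n_perm):
            perm2.z = rng.permutation(stats2.z)
            permuted[b] = fit_rg(stats1, perm2, n_blocks=n_blocks).r_g

    exceed = int(np.sum(np.abs(permuted) >= abs(observed)))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed_stat=observed, permuted_stats=permuted, n_perm=n_perm,
        empirical_p=p, statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Model facade


class LdscModel:
    """Cross-trait LD score regression model over two genome-wide Z-score sets.

    Parameters
    ----------
    stats1, stats2
        Harmonized :class:`~comogen.sumstats.GenomeWideStats` on shared SNPs.
    n_blocks
        Contiguous jackknife blocks (default 200).
    """

    def __init__(self, stats1: GenomeWideStats, stats2: GenomeWideStats, n_blocks: int = DEFAULT_N_BLOCKS):
        self.stats1 = stats1
        self.stats2 = stats2
        self.n_blocks = n_blocks

    def fit(self) -> LdscFit:
        return fit_rg(self.stats1, self.stats2, n_blocks=self.n_blocks)

    def permutation_test(self, n_perm: int = 10_000, seed: int = 0, statistic: str = "rho_g") -> PermutationResult:
        return permutation_empirical_p(
            self.stats1, self.stats2, n_perm=n_perm, seed=seed,
            statistic=statistic, n_blocks=self.n_blocks,
        )
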