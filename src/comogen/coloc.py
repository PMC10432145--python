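"""Bayesian colocalization of summary statistics under a single causal variant.

Per-SNP evidence is the Wakefield log approximate Bayes factor computed from
the effect estimate and its standard error,

    lABF = 0.5 * ln(1 - r) + 0.5 * z^2 * r,    r = W / (W + se^2),

with W the prior variance of the true effect. The pairwise engine combines
per-SNP lABFs for two traits into posteriors over the five regional
hypotheses (H0 no association, H1/H2 one trait only, H3 two distinct causal
variants, H4 one shared causal variant) and reports the 95% credible set for
the shared causal variant conditional on H4.

The multi-trait engine generalizes the hypothesis space to partitions of the
trait set into a null subset plus blocks of traits sharing one causal SNP,
with a per-SNP block prior prior1 * (1 - prior2)^(k-1) for a block of k
traits; no divisive clustering is performed. The distinct-SNP constraint is
handled exactly for two blocks and ignored for three or more (the collision
terms are negligible at the default priors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from ._utils import logdiffexp, set_partitions, nonempty_subsets
from .sumstats import RegionStats, TraitType, Variant

logger = logging.getLogger("comogen")

#: Decision threshold for declaring colocalization, PP4 > this value.
PP4_THRESHOLD = 0.8
#: Credible-set mass.
CREDIBLE_MASS = 0.95

__all__ = [
    "ColocPriors",
    "MultiColocPriors",
    "ColocResult",
    "MultiColocResult",
    "wakefield_labf",
    "default_prior_sd",
    "coloc_abf",
    "credible_set",
    "multicoloc",
    "multicoloc_with_fallback",
    "ColocModel",
    "MultiColocModel",
    "PP4_THRESHOLD",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association (pairwise engine defaults)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")


@dataclass(frozen=True)
class MultiColocPriors:
    """Multi-trait priors: prior1 = P(SNP associated with one trait only);
    1 - prior2 = P(association extends to each additional trait)."""

    prior1: float = 1e-10
    prior2: float = 0.7

    def __post_init__(self):
        if not (0 < self.prior1 < 1 and 0 < self.prior2 < 1):
            raise ValueError("prior1 and prior2 must lie in (0, 1)")

    def block_log_prior(self, k: int) -> float:
        return float(np.log(self.prior1) + (k - 1) * np.log1p(-self.prior2))


def default_prior_sd(stats: RegionStats) -> float:
    """Prior effect-size SD: 0.2 on the log-odds scale for case-control
    traits, 0.15 (in trait-SD units) for quantitative traits."""
    return 0.2 if stats.trait_type is TraitType.case_control else 0.15


def wakefield_labf(stats: RegionStats, prior_sd: float | None = None) -> np.ndarray:
    """Per-SNP Wakefield log approximate Bayes factors for association."""
    if prior_sd is None:
        prior_sd = default_prior_sd(stats)
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    V = stats.se**2
    z = stats.z
    if not np.all(np.isfinite(z)):
        bad = np.flatnonzero(~np.isfinite(z))
        raise ValueError(f"non-finite z at SNP index {bad[0]}")
    W = prior_sd**2
    r = W / (W + V)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def credible_set(
    snp_posterior: np.ndarray,
    variants: Sequence[Variant],
    mass: float = CREDIBLE_MASS,
) -> list[Variant]:
    """Smallest set of variants whose summed posteriors reach ``mass``.

    Variants are ranked by descending posterior with ties broken by position
    then id; the shortest prefix with cumulative mass >= the target wins.
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    snp_posterior = np.asarray(snp_posterior, dtype=float)
    if abs(snp_posterior.sum() - 1.0) > 1e-6:
        raise ValueError("snp posteriors must sum to 1")
    order = sorted(
        range(len(variants)),
        key=lambda i: (-snp_posterior[i], variants[i].pos, variants[i].id),
    )
    cum = 0.0
    out = []
    for i in order:
        out.append(variants[i])
        cum += snp_posterior[i]
        if cum >= mass - 1e-12:
            break
    return out


@dataclass
class ColocResult:
    """Posteriors over H0..H4 plus the conditional credible set."""

    pp: np.ndarray  # PP0..PP4
    labf_1: np.ndarray
    labf_2: np.ndarray
    snp_h4_posterior: np.ndarray
    credible_set: list[Variant]
    lead_variant: Variant
    variants: list[Variant] = field(default_factory=list)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def colocalizes(self, threshold: float = PP4_THRESHOLD) -> bool:
        return self.pp4 > threshold

    def summary(self) -> str:
        rows = "  ".join(f"PP{i}={p:.4f}" for i, p in enumerate(self.pp))
        return (
            f"pairwise colocalization over {len(self.labf_1)} SNPs\n{rows}\n"
            f"lead variant {self.lead_variant.id}; "
            f"95% credible set: {len(self.credible_set)} variant(s)"
        )


def _check_aligned(stats: Sequence[RegionStats]) -> None:
    ref = stats[0].ids
    for s in stats[1:]:
        if s.ids != ref:
            raise ValueError(
                "variant sets differ or are out of order; run harmonize() first"
            )


def coloc_abf(
    stats1: RegionStats,
    stats2: RegionStats,
    priors: ColocPriors = ColocPriors(),
    prior_sd_1: float | None = None,
    prior_sd_2: float | None = None,
) -> ColocResult:
    """Pairwise colocalization posteriors under a single causal variant per trait.

    All evidence arithmetic is in log space. With L1, L2 and L12 the
    logsumexps of the per-trait and summed lABFs, the unnormalized
    log-evidences are H0 = 0, H1 = ln p1 + L1, H2 = ln p2 + L2,
    H3 = ln(p1*p2) + ln(exp(L1+L2) - exp(L12)) (exactly zero with one SNP)
    and H4 = ln p12 + L12.
    """
    _check_aligned([stats1, stats2])
    if len(stats1) < 1:
        raise ValueError("need at least one SNP")
    l1 = wakefield_labf(stats1, prior_sd_1)
    l2 = wakefield_labf(stats2, prior_sd_2)

    L1 = logsumexp(l1)
    L2 = logsumexp(l2)
    L12 = logsumexp(l1 + l2)
    h = np.array(
        [
            0.0,
            np.log(priors.p1) + L1,
            np.log(priors.p2) + L2,
            np.log(priors.p1) + np.log(priors.p2) + logdiffexp(L1 + L2, L12),
            np.log(priors.p12) + L12,
        ]
    )
    pp = np.exp(h - logsumexp(h))
    snp_post = np.exp(l1 + l2 - L12)
    cs = credible_set(snp_post, stats1.variants)
    lead = cs[0]
    return ColocResult(
        pp=pp, labf_1=l1, labf_2=l2, snp_h4_posterior=snp_post,
        credible_set=cs, lead_variant=lead, variants=list(stats1.variants),
    )


# ---------------------------------------------------------------------------
# Multi-trait engine


@dataclass
class MultiColocResult:
    """Posteriors over trait-partition hypotheses; full colocalization first."""

    pp_full_coloc: float
    hypothesis_posteriors: dict
    snp_posterior: np.ndarray
    credible_set: list[Variant]
    lead_variant: Variant
    trait_names: list[str]
    used_fallback_window: bool = False

    def colocalizes(self, threshold: float = PP4_THRESHOLD) -> bool:
        return self.pp_full_coloc > threshold

    def summary(self) -> str:
        top = sorted(self.hypothesis_posteriors.items(), key=lambda kv: -kv[1])[:5]
        lines = [f"multi-trait colocalization of {', '.join(self.trait_names)}"]
        lines += [f"  P[{k}] = {v:.4f}" for k, v in top]
        lines.append(f"P(all traits share one causal variant) = {self.pp_full_coloc:.4f}")
        return "\n".join(lines)


def _partition_label(blocks: Sequence[Sequence[str]]) -> str:
    if not blocks:
        return "null"
    return " | ".join("{" + ",".join(b) + "}" for b in blocks)


def multicoloc(
    stats: Sequence[RegionStats],
    priors: MultiColocPriors = MultiColocPriors(),
    prior_sds: Sequence[float] | None = None,
) -> MultiColocResult:
    """Posterior over all ways the input traits can share causal variants.

    Hypotheses are partitions of the trait set into a null subset plus
    blocks, each block sharing one causal SNP. Block evidence factorizes as a
    logsumexp over SNPs of the summed lABFs of the block's traits plus the
    block prior; the distinct-SNP constraint between blocks is applied
    exactly for two blocks and ignored for three or more.
    """
    m = len(stats)
    if not 2 <= m <= 6:
        raise ValueError("multicoloc supports between 2 and 6 traits")
    _check_aligned(stats)
    if prior_sds is None:
        prior_sds = [None] * m
    labf = [wakefield_labf(s, sd) for s, sd in zip(stats, prior_sds)]
    names = [s.trait_name for s in stats]
    trait_idx = list(range(m))

    log_h: dict[str, float] = {"null": 0.0}
    full_label = None
    for subset in nonempty_subsets(trait_idx):
        for blocks in set_partitions(subset):
            # per-block per-SNP log terms
            terms = [
                priors.block_log_prior(len(b)) + np.sum([labf[t] for t in b], axis=0)
                for b in blocks
            ]
            if len(blocks) == 1:
                logev = float(logsumexp(terms[0]))
            elif len(blocks) == 2:
                prod = logsumexp(terms[0]) + logsumexp(terms[1])
                shared = float(logsumexp(terms[0] + terms[1]))
                logev = logdiffexp(prod, shared)
            else:
                logev = float(sum(logsumexp(t) for t in terms))
            label = _partition_label([[names[t] for t in b] for b in blocks])
            log_h[label] = logev
            if len(blocks) == 1 and len(subset) == m:
                full_label = label

    labels = list(log_h)
    logs = np.array([log_h[k] for k in labels])
    post = np.exp(logs - logsumexp(logs))
    hypothesis_posteriors = dict(zip(labels, post))

    total_labf = np.sum(labf, axis=0)
    snp_post = np.exp(total_labf - logsumexp(total_labf))
    cs = credible_set(snp_post, stats[0].variants)
    return MultiColocResult(
        pp_full_coloc=float(hypothesis_posteriors[full_label]),
        hypothesis_posteriors=hypothesis_posteriors,
        snp_posterior=snp_post,
        credible_set=cs,
        lead_variant=cs[0],
        trait_names=names,
    )


def multicoloc_with_fallback(
    credible_set_stats: Sequence[RegionStats],
    full_region_stats: Sequence[RegionStats],
    priors: MultiColocPriors = MultiColocPriors(),
    prior_sds: Sequence[float] | None = None,
) -> MultiColocResult:
    """Run the multi-trait engine on credible-set variants, widening to the
    full 1-Mb window when the credible set is a single variant."""
    if len(credible_set_stats) == 0 or len(credible_set_stats[0]) == 0:
        raise ValueError("credible-set input must contain at least one variant")
    if len(credible_set_stats[0]) == 1:
        logger.info("multicoloc: singleton credible set, falling back to the 1-Mb window")
        res = multicoloc(full_region_stats, priors=priors, prior_sds=prior_sds)
        res.used_fallback_window = True
        return res
    return multicoloc(credible_set_stats, priors=priors, prior_sds=prior_sds)


# ---------------------------------------------------------------------------
# Model facades


class ColocModel:
    """Pairwise colocalization model over two harmonized regional datasets."""

    def __init__(
        self,
        stats1: RegionStats,
        stats2: RegionStats,
        priors: ColocPriors = ColocPriors(),
        prior_sd_1: float | None = None,
        prior_sd_2: float | None = None,
    ):
        self.stats1 = stats1
        self.stats2 = stats2
        self.priors = priors
        self.prior_sd_1 = prior_sd_1
        self.prior_sd_2 = prior_sd_2

    def fit(self) -> ColocResult:
        return coloc_abf(
            self.stats1, self.stats2, priors=self.priors,
            prior_sd_1=self.prior_sd_1, prior_sd_2=self.prior_sd_2,
        )


class MultiColocModel:
    """Multi-trait colocalization model over harmonized regional datasets."""

    def __init__(
        self,
        stats: Sequence[RegionStats],
        priors: MultiColocPriors = MultiColocPriors(),
        prior_sds: Sequence[float] | None = None,
    ):
        self.stats = list(stats)
        self.priors = priors
        self.prior_sds = prior_sds

    def fit(self) -> MultiColocResult:
        return multicoloc(self.stats, priors=self.priors, prior_sds=self.prior_sds)
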