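"""Synthetic-data generators for every input the pipeline consumes.

The generators work directly at the summary-statistic level: marginal Z
scores in a region are drawn from the multivariate normal implied by the LD
matrix and the causal configuration, ``z ~ MVN(causal_z * R[:, c], R)``,
which is exact for the methods in this package (they never touch genotypes).
Genome-wide Z scores follow the LD-score-regression model, including the
sample-overlap term in the cross-trait covariance. Per-gene evidence tables
carry a ground-truth classification computed by an independent restatement
of the scoring rules, so the scoring engine can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, GenomeWideStats, RegionStats, TraitType, Variant

__all__ = [
    "Hypothesis",
    "RegionScenario",
    "GenomeScenario",
    "EvidenceScenario",
    "make_ld",
    "make_variants",
    "simulate_region",
    "simulate_genomewide",
    "simulate_evidence",
    "simulate_instruments",
]


class Hypothesis(str, Enum):
    """Single-causal-variant colocalization configurations for two traits."""

    H0 = "H0"  # no trait associated in the region
    H1 = "H1"  # trait 1 only
    H2 = "H2"  # trait 2 only
    H3 = "H3"  # both traits, distinct causal variants
    H4 = "H4"  # both traits, one shared causal variant


@dataclass
class RegionScenario:
    """Configuration for one simulated 2 Mb colocalization region.

    Defaults mirror the calibration conditions used throughout the test
    suite: 200 SNPs on an AR(1) LD backbone with decay 0.9, causal
    noncentrality 8 and biobank-scale samples.
    """

    n_snps: int = 200
    ld_decay: float = 0.9
    hypothesis: Hypothesis = Hypothesis.H4
    causal_index_1: int | None = None
    causal_index_2: int | None = None
    causal_z: float = 8.0
    n_samples: tuple[int, int] = (100_000, 100_000)
    trait_types: tuple[TraitType, TraitType] = (TraitType.case_control, TraitType.case_control)
    case_fractions: tuple[float, float] = (0.2, 0.2)
    swap_allele_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.hypothesis = Hypothesis(self.hypothesis)
        h = self.hypothesis
        c1, c2 = self.causal_index_1, self.causal_index_2
        if h is Hypothesis.H0 and (c1 is not None or c2 is not None):
            raise ValueError("H0 admits no causal index")
        if h is Hypothesis.H3:
            if c1 is None or c2 is None or c1 == c2:
                raise ValueError("H3 requires two distinct causal indices")
        if h is Hypothesis.H4:
            if c1 is None and c2 is None:
                self.causal_index_1 = self.causal_index_2 = self.n_snps // 2
            elif c1 != c2:
                raise ValueError("H4 requires causal_index_1 == causal_index_2")
        if h is Hypothesis.H1 and c1 is None:
            self.causal_index_1 = self.n_snps // 2
        if h is Hypothesis.H2 and c2 is None:
            self.causal_index_2 = self.n_snps // 2


@dataclass
class GenomeScenario:
    """Configuration for a pair of genome-wide Z-score sets under the LDSC model.

    Defaults emulate a desk-scale version of two well-powered complex-trait
    GWAS: M = 20,000 SNPs, heritability 0.5 for both traits and a genetic
    covariance of 0.12 (implied genetic correlation 0.24, the knee-OA-scale
    estimate used as the generator's truth).
    """

    m_snps: int = 20_000
    h2_1: float = 0.5
    h2_2: float = 0.5
    rho_g: float = 0.12
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    pheno_corr: float = 0.0
    ld_shape: float = 2.0
    ld_scale: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.h2_1 <= 1 and 0 <= self.h2_2 <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        bound = np.sqrt(self.h2_1 * self.h2_2)
        if abs(self.rho_g) > bound + 1e-12:
            raise ValueError("|rho_g| must not exceed sqrt(h2_1 * h2_2)")


@dataclass
class EvidenceScenario:
    """Configuration for a synthetic per-gene evidence table."""

    n_genes: int = 1000
    p_oa: dict = field(
        default_factory=lambda: {"molqtl": 0.15, "deg": 0.2, "ko_mouse": 0.25, "omim": 0.05, "hc": 0.1}
    )
    p_t2d: dict = field(
        default_factory=lambda: {"molqtl": 0.15, "deg": 0.2, "ko_mouse": 0.25, "omim": 0.05, "hc": 0.1}
    )
    p_missense: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for p in [*self.p_oa.values(), *self.p_t2d.values(), self.p_missense]:
            if not 0 <= p <= 1:
                raise ValueError("evidence probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def make_variants(n_snps: int, chrom: str = "1", start: int = 1_000_000, span: int = 2_000_000) -> list[Variant]:
    """Evenly spaced variants across a window with non-palindromic alleles."""
    step = max(1, span // max(1, n_snps - 1)) if n_snps > 1 else span
    return [
        Variant(
            id=f"{chrom}:{start + i * step}",
            chrom=chrom,
            pos=start + i * step,
            effect_allele=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0],
            other_allele=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1],
        )
        for i in range(n_snps)
    ]


def make_ld(n_snps: int, ld_decay: float, variants: list[Variant] | None = None) -> LDMatrix:
    """AR(1) LD matrix: ``r[i, j] = ld_decay ** |i - j|`` (PSD by construction)."""
    if not 0 <= ld_decay < 1:
        raise ValueError("ld_decay must lie in [0, 1)")
    idx = np.arange(n_snps)
    r = ld_decay ** np.abs(idx[:, None] - idx[None, :])
    if variants is None:
        variants = make_variants(n_snps)
    return LDMatrix(variants=variants, r=r)


def _se_for(trait_type: TraitType, n: int, case_fraction: float) -> float:
    if trait_type is TraitType.case_control:
        return 1.0 / np.sqrt(n * case_fraction * (1.0 - case_fraction))
    return 1.0 / np.sqrt(n)


def simulate_region(scenario: RegionScenario, ld: LDMatrix | None = None) -> tuple[RegionStats, RegionStats]:
    """Draw a pair of regional summary statistics under one hypothesis.

    For each trait the marginal z-vector is ``MVN(causal_z * R[:, c], R)``
    (zero mean when the trait carries no causal variant), and
    ``beta = z * se`` with the standard large-sample SE approximation.
    The two traits are drawn independently given the configuration.
    """
    rng = np.random.default_rng(scenario.seed)
    if ld is None:
        ld = make_ld(scenario.n_snps, scenario.ld_decay)
    n_snps = len(ld)
    if scenario.n_snps != n_snps:
        raise ValueError("scenario.n_snps does not match the LD matrix")
    for c in (scenario.causal_index_1, scenario.causal_index_2):
        if c is not None and not 0 <= c < n_snps:
            raise ValueError(f"causal index {c} out of range for {n_snps} SNPs")

    chol = np.linalg.cholesky(ld.r + 1e-12 * np.eye(n_snps))
    causal = {
        Hypothesis.H0: (None, None),
        Hypothesis.H1: (scenario.causal_index_1, None),
        Hypothesis.H2: (None, scenario.causal_index_2),
        Hypothesis.H3: (scenario.causal_index_1, scenario.causal_index_2),
        Hypothesis.H4: (scenario.causal_index_1, scenario.causal_index_2),
    }[scenario.hypothesis]

    out = []
    for t, c in enumerate(causal):
        mu = scenario.causal_z * ld.r[:, c] if c is not None else np.zeros(n_snps)
        z = mu + chol @ rng.standard_normal(n_snps)
        se = _se_for(scenario.trait_types[t], scenario.n_samples[t], scenario.case_fractions[t])
        variants = list(ld.variants)
        beta = z * se
        if scenario.swap_allele_fraction > 0 and t == 1:
            swap = rng.random(n_snps) < scenario.swap_allele_fraction
            beta = np.where(swap, -beta, beta)
            variants = [
                Variant(v.id, v.chrom, v.pos, v.other_allele, v.effect_allele) if s else v
                for v, s in zip(variants, swap)
            ]
        tt = scenario.trait_types[t]
        out.append(
            RegionStats(
                trait_name=f"trait{t + 1}",
                trait_type=tt,
                variants=variants,
                beta=beta,
                se=np.full(n_snps, se),
                n=np.full(n_snps, scenario.n_samples[t]),
                case_fraction=scenario.case_fractions[t] if tt is TraitType.case_control else None,
            )
        )
    return out[0], out[1]


def simulate_genomewide(scenario: GenomeScenario) -> tuple[GenomeWideStats, GenomeWideStats]:
    """Draw paired genome-wide Z scores under the cross-trait LDSC model.

    Per SNP j with LD score l_j the pair (z1j, z2j) is bivariate normal with

        Var(z_ij) = 1 + n_i * h2_i * l_j / M
        Cov       = sqrt(n1*n2) * rho_g * l_j / M
                    + pheno_corr * n_overlap / sqrt(n1*n2)

    LD scores are drawn from a shifted gamma distribution (minimum 1).
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    M = s.m_snps
    l = 1.0 + rng.gamma(s.ld_shape, s.ld_scale, size=M)
    v1 = 1.0 + s.n1 * s.h2_1 * l / M
    v2 = 1.0 + s.n2 * s.h2_2 * l / M
    cov = np.sqrt(s.n1 * s.n2) * s.rho_g * l / M + s.pheno_corr * s.n_overlap / np.sqrt(s.n1 * s.n2)
    resid = v2 - cov**2 / v1
    bad = np.flatnonzero(resid < 0)
    if bad.size:
        raise ValueError(f"per-SNP covariance matrix not PSD at SNP {bad[0]}")
    e1 = rng.standard_normal(M)
    e2 = rng.standard_normal(M)
    z1 = np.sqrt(v1) * e1
    z2 = (cov / np.sqrt(v1)) * e1 + np.sqrt(resid) * e2

    variants = [
        Variant(f"rs{j + 1}", "1", 10_000 + 1_000 * j, "A", "G") for j in range(M)
    ]
    g1 = GenomeWideStats(variants=variants, z=z1, n=np.full(M, s.n1), ld_score=l, m=M)
    g2 = GenomeWideStats(variants=list(variants), z=z2, n=np.full(M, s.n2), ld_score=l.copy(), m=M)
    return g1, g2


# ---------------------------------------------------------------------------
# Evidence tables

_LINES = ("molqtl_coloc", "deg", "ko_mouse", "omim")
_PROB_KEYS = {"molqtl_coloc": "molqtl", "deg": "deg", "ko_mouse": "ko_mouse", "omim": "omim"}


def _oracle_classify(row: dict) -> str:
    # Independent restatement of the scoring rules, kept deliberately separate
    # from comogen.scoring so the two can be cross-checked.
    oa = sum(bool(row[f"{line}_oa"]) for line in _LINES)
    t2d = sum(bool(row[f"{line}_t2d"]) for line in _LINES)
    if oa == 0 and row["established_hc_oa"]:
        oa = 1
    if t2d == 0 and row["established_hc_t2d"]:
        t2d = 1
    mis = 1 if row["missense_in_credible_set"] else 0
    total = 0 if (oa == 0 and t2d == 0) else oa + t2d + mis
    if oa >= 1 and t2d >= 1 and total >= 3:
        return "high_confidence"
    if oa >= 1 and t2d >= 1:
        return "likely"
    if oa >= 1 or t2d >= 1:
        return "potential"
    return "none"


def simulate_evidence(scenario: EvidenceScenario) -> pd.DataFrame:
    """Generate a per-gene evidence-flag table with ground-truth classes.

    Flags are independent Bernoulli draws per evidence line and disease; the
    ``truth_class`` column holds the classification implied by the flags,
    computed by an independent restatement of the scoring rules.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for g in range(scenario.n_genes):
        row: dict = {"gene": f"GENE{g:05d}", "locus_id": f"locus{g % max(1, scenario.n_genes // 10)}"}
        for line in _LINES:
            row[f"{line}_oa"] = bool(rng.random() < scenario.p_oa[_PROB_KEYS[line]])
            row[f"{line}_t2d"] = bool(rng.random() < scenario.p_t2d[_PROB_KEYS[line]])
        row["established_hc_oa"] = bool(rng.random() < scenario.p_oa["hc"])
        row["established_hc_t2d"] = bool(rng.random() < scenario.p_t2d["hc"])
        row["missense_in_credible_set"] = bool(rng.random() < scenario.p_missense)
        row["truth_class"] = _oracle_classify(row)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MR instrument sets


def simulate_instruments(
    n_snps: int = 50,
    true_effect: float = 0.2,
    pleiotropy: float = 0.0,
    invalid_fraction: float = 0.0,
    invalid_effect: float = 0.8,
    se_exp: float = 0.02,
    se_out: float = 0.05,
    n_exp: int = 100_000,
    n_out: int = 100_000,
    seed: int = 0,
) -> "pd.DataFrame":
    """Simulate a harmonized two-sample MR instrument table.

    Valid instruments follow ``b_out = true_effect * b_exp + pleiotropy`` plus
    sampling noise; a fraction of invalid instruments act through a different
    (pleiotropic) ratio ``invalid_effect``. Returns a frame with the
    InstrumentSet columns (b_exp, se_exp, b_out, se_out, n_exp, n_out, valid).
    """
    rng = np.random.default_rng(seed)
    b_exp_true = rng.normal(0.15, 0.05, size=n_snps) * rng.choice([-1, 1], size=n_snps)
    invalid = rng.random(n_snps) < invalid_fraction
    slope = np.where(invalid, invalid_effect, true_effect)
    # directional pleiotropy acts on the exposure-increasing allele, so it
    # survives the joint reorientation performed by MR-Egger
    b_out_true = slope * b_exp_true + pleiotropy * np.sign(b_exp_true)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "b_exp": b_exp_true + rng.normal(0, se_exp, n_snps),
            "se_exp": np.full(n_snps, se_exp),
            "b_out": b_out_true + rng.normal(0, se_out, n_snps),
            "se_out": np.full(n_snps, se_out),
            "n_exp": np.full(n_snps, n_exp),
            "n_out": np.full(n_snps, n_out),
            "valid": ~invalid,
        }
    )
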