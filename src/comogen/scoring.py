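"""Evidence integration and effector-gene classification.

Each gene in a colocalizing locus is scored against six orthogonal lines of
evidence: molecular-QTL colocalization, differential expression, knockout-
mouse phenotypes and monogenic (OMIM) phenotypes — each counted once per
disease — plus previously established high-confidence (HC) gene lists and a
missense-variant lookup in the 95% credible set. Per disease the score is
the count of positive lines among {molQTL, DEG, KO mouse, OMIM}; an
established-HC gene with a zero disease score is bumped to one. The total
score is OA + T2D + missense, except that a gene whose only evidence is the
missense lookup totals zero. Classification: *potential* needs evidence for
at least one disease, *likely* for both, *high-confidence* is a likely gene
with total >= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .sumstats import Locus

logger = logging.getLogger("comogen")

#: Knockout-mouse phenotype term lists (substring match, case-insensitive).
KO_TERMS_T2D = (
    "insulin", "glucose", "diabetes", "hyperglycemia", "pancreas", "pancreatic",
    "obesity", "bmi", "body weight", "body mass", "body fat", "beta cell", "glucosuria",
)
KO_TERMS_OA = (
    "skeletal", "muscle", "bone", "osteo", "arthritis", "muscular", "joint",
    "body size", "growth", "stature", "height",
)
#: OMIM rare/syndromic disease term lists.
OMIM_TERMS_OA = (
    "bone", "muscle", "skeleton", "osteo", "arthritis", "muscular", "joint",
    "body size", "growth", "skeletal", "stature", "height", "hand-foot-uterus",
    "synostosis", "martsolf", "warburg", "leukodystrophy", "squalene", "finca",
)
OMIM_TERMS_T2D = (
    "insulin", "glycemia", "glucose", "diabetes", "pancreas", "pancreatic",
    "obesity", "bmi", "body weight", "body mass", "body fat", "beta cell",
    "glucosuria", "martsolf", "aciduria", "aicardi-goutières", "finca",
)

#: Differential-expression thresholds: >1.5-fold either direction, adj p < 0.05.
DEG_FOLD_THRESHOLD = 1.5
DEG_ALPHA = 0.05

#: OA phenotype vocabulary for joint stratification.
GENERIC_OA_PHENOTYPES = frozenset({"all", "kneehip", "TJR"})
KNEE_PHENOTYPES = frozenset({"knee", "TKR"})
HIP_PHENOTYPES = frozenset({"hip", "THR"})
OA_PHENOTYPES = GENERIC_OA_PHENOTYPES | KNEE_PHENOTYPES | HIP_PHENOTYPES

CLASS_ORDER = ("none", "potential", "likely", "high_confidence")

EVIDENCE_FLAGS = (
    "molqtl_coloc_oa", "molqtl_coloc_t2d", "deg_oa", "deg_t2d",
    "ko_mouse_oa", "ko_mouse_t2d", "omim_oa", "omim_t2d",
    "established_hc_oa", "established_hc_t2d", "missense_in_credible_set",
)

__all__ = [
    "GeneEvidence",
    "GeneScore",
    "match_phenotype_terms",
    "deg_flag",
    "score_gene",
    "score_table",
    "stratify_joint",
    "obesity_level",
    "gene_universe",
    "EVIDENCE_FLAGS",
    "KO_TERMS_OA", "KO_TERMS_T2D", "OMIM_TERMS_OA", "OMIM_TERMS_T2D",
]


@dataclass
class GeneEvidence:
    """Per-gene boolean evidence flags for the two diseases."""

    gene: str
    locus_id: str = ""
    molqtl_coloc_oa: bool = False
    molqtl_coloc_t2d: bool = False
    deg_oa: bool = False
    deg_t2d: bool = False
    ko_mouse_oa: bool = False
    ko_mouse_t2d: bool = False
    omim_oa: bool = False
    omim_t2d: bool = False
    established_hc_oa: bool = False
    established_hc_t2d: bool = False
    missense_in_credible_set: bool = False


@dataclass
class GeneScore:
    """Derived per-gene scores and classification."""

    gene: str
    oa_score: int
    t2d_score: int
    missense_score: int
    total: int
    classification: str
    joint_stratum: set = field(default_factory=set)
    obesity_level: int | None = None


def match_phenotype_terms(phenotype_strings: Iterable[str], term_list: Iterable[str]) -> bool:
    """True iff any phenotype string contains any term (case-insensitive
    substring match, so ``osteo`` matches ``osteoporosis``)."""
    terms = [t.lower() for t in term_list]
    for s in phenotype_strings:
        sl = str(s).lower()
        for t in terms:
            if t in sl:
                logger.info("phenotype match: %r contains %r", s, t)
                return True
    return False


def deg_flag(fold_change: float, adjusted_p: float, scale: str = "linear") -> bool:
    """Differential-expression call: >1.5-fold change in either direction
    with adjusted p < 0.05. ``scale`` fixes the fold-change convention:
    ``"linear"`` (0.6 means 1.67-fold down) or ``"log2"``."""
    import numpy as np

    if scale == "log2":
        big = abs(fold_change) > np.log2(DEG_FOLD_THRESHOLD)
    elif scale == "linear":
        big = fold_change > DEG_FOLD_THRESHOLD or (
            fold_change > 0 and fold_change < 1.0 / DEG_FOLD_THRESHOLD
        )
    else:
        raise ValueError("scale must be 'linear' or 'log2'")
    return bool(big and adjusted_p < DEG_ALPHA)


def score_gene(ev: GeneEvidence, hc_additive: bool = False) -> GeneScore:
    """Apply the scoring and classification rules to one gene.

    ``hc_additive=True`` switches to the alternative reading where an
    established-HC gene always gains one point rather than only when its
    disease score is zero.
    """
    oa = sum([ev.molqtl_coloc_oa, ev.deg_oa, ev.ko_mouse_oa, ev.omim_oa])
    t2d = sum([ev.molqtl_coloc_t2d, ev.deg_t2d, ev.ko_mouse_t2d, ev.omim_t2d])
    if hc_additive:
        oa += int(ev.established_hc_oa)
        t2d += int(ev.established_hc_t2d)
    else:
        if ev.established_hc_oa and oa == 0:
            oa = 1
        if ev.established_hc_t2d and t2d == 0:
            t2d = 1
    missense = int(ev.missense_in_credible_set)
    total = 0 if (oa == 0 and t2d == 0) else oa + t2d + missense
    if oa >= 1 and t2d >= 1 and total >= 3:
        cls = "high_confidence"
    elif oa >= 1 and t2d >= 1:
        cls = "likely"
    elif oa >= 1 or t2d >= 1:
        cls = "potential"
    else:
        cls = "none"
    return GeneScore(
        gene=ev.gene, oa_score=oa, t2d_score=t2d,
        missense_score=missense, total=total, classification=cls,
    )


def score_table(evidence: pd.DataFrame, hc_additive: bool = False) -> pd.DataFrame:
    """Score a per-gene evidence-flag table (one row per gene).

    Expects the :data:`EVIDENCE_FLAGS` columns plus ``gene``; returns the
    input augmented with oa/t2d/missense/total scores and classification.
    """
    out = evidence.copy()
    scores = [
        score_gene(
            GeneEvidence(gene=str(row["gene"]),
                         **{f: bool(row[f]) for f in EVIDENCE_FLAGS if f in row}),
            hc_additive=hc_additive,
        )
        for row in evidence.to_dict("records")
    ]
    out["oa_score"] = [s.oa_score for s in scores]
    out["t2d_score"] = [s.t2d_score for s in scores]
    out["missense_score"] = [s.missense_score for s in scores]
    out["total"] = [s.total for s in scores]
    out["classification"] = [s.classification for s in scores]
    return out


def stratify_joint(locus_phenotypes: Iterable[str]) -> set[str]:
    """Assign a gene's locus to knee and/or hip osteoarthritis.

    A locus colocalizing only with the joint-agnostic phenotypes (any-site,
    knee-and/or-hip, TJR) counts for both joints; colocalization with knee or
    TKR adds knee, with hip or THR adds hip. Membership can overlap.
    """
    s = set(locus_phenotypes)
    unknown = s - OA_PHENOTYPES
    if unknown:
        raise ValueError(f"unknown OA phenotype name(s): {sorted(unknown)}")
    out = set()
    if (s & KNEE_PHENOTYPES) or s <= GENERIC_OA_PHENOTYPES:
        out.add("knee")
    if (s & HIP_PHENOTYPES) or s <= GENERIC_OA_PHENOTYPES:
        out.add("hip")
    return out


def obesity_level(omim_obesity: bool, variant_adiposity_assoc: bool) -> int:
    """Obesity-association level: 1 = OMIM obesity disease, 2 = variants
    associated with adiposity phenotypes, 3 = no association found."""
    if omim_obesity:
        return 1
    if variant_adiposity_assoc:
        return 2
    return 3


def gene_universe(locus: Locus, gene_table: pd.DataFrame, window_bp: int = 1_000_000) -> list[str]:
    """All genes whose span intersects the 1-Mb window on either side of the
    locus lead variant (boundary inclusive)."""
    lead = locus.lead_variant
    lo, hi = lead.pos - window_bp, lead.pos + window_bp
    sel = (
        (gene_table["chrom"].astype(str) == lead.chrom)
        & (gene_table["end"] >= lo)
        & (gene_table["start"] <= hi)
    )
    return list(gene_table.loc[sel, "gene"])
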