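"""Core summary-statistics containers and operations.

Holds the domain types shared by every analysis stage — variants, regional and
genome-wide summary statistics, LD matrices, regions and merged loci — plus
allele harmonization, region definition around index signals, locus merging
and credible-set direction lookup.

Conventions
-----------
* Coordinates are 1-based inclusive (GWAS summary-statistic convention).
* Effect sizes are per effect allele; for case-control traits beta is the
  log-odds ratio.
* Harmonization aligns dataset B to dataset A's effect alleles by inverting
  the sign of B's beta whenever the allele labels are swapped; variants with
  incompatible allele pairs are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("comogen")

#: Canonical column names for delimited summary-statistic files.
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "BETA", "SE", "P", "N", "CASE_FRAC")


class TraitType(str, Enum):
    quantitative = "quantitative"
    case_control = "case_control"


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with an explicit effect/other allele orientation."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos} for {self.id}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect and other allele identical for {self.id}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """A/T and C/G pairs whose strand cannot be resolved from labels."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))


@dataclass
class RegionStats:
    """Per-variant effect sizes and standard errors for one trait in a window."""

    trait_name: str
    trait_type: TraitType
    variants: list[Variant]
    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray
    p: np.ndarray | None = None
    case_fraction: float | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n)
        m = len(self.variants)
        if not (len(self.beta) == len(self.se) == len(self.n) == m):
            raise ValueError("per-variant vectors must match the variant list length")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be positive")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
            if len(self.p) != m:
                raise ValueError("p vector length mismatch")
        self.trait_type = TraitType(self.trait_type)
        if self.trait_type is TraitType.case_control:
            if self.case_fraction is not None and not (0 < self.case_fraction < 1):
                raise ValueError("case_fraction must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset(self, idx: Sequence[int]) -> "RegionStats":
        idx = np.asarray(idx, dtype=int)
        return RegionStats(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            variants=[self.variants[i] for i in idx],
            beta=self.beta[idx],
            se=self.se[idx],
            n=self.n[idx],
            p=None if self.p is None else self.p[idx],
            case_fraction=self.case_fraction,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "SNP": self.ids,
                "CHR": [v.chrom for v in self.variants],
                "BP": [v.pos for v in self.variants],
                "EA": [v.effect_allele for v in self.variants],
                "OA": [v.other_allele for v in self.variants],
                "BETA": self.beta,
                "SE": self.se,
                "N": self.n,
            }
        )
        df["P"] = self.p if self.p is not None else _p_from_z(self.z)
        if self.case_fraction is not None:
            df["CASE_FRAC"] = self.case_fraction
        return df


@dataclass
class GenomeWideStats:
    """Genome-wide Z scores with per-SNP LD scores, the LDSC input."""

    variants: list[Variant]
    z: np.ndarray
    n: np.ndarray
    ld_score: np.ndarray
    m: int  # SNP count used for normalization (M)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float), self.z.shape).copy()
        k = len(self.variants)
        if not (len(self.z) == len(self.n) == len(self.ld_score) == k):
            raise ValueError("per-SNP vectors must match the variant list length")
        if np.any(self.ld_score < 1):
            raise ValueError("LD scores must be >= 1 by convention")
        if self.m < k:
            raise ValueError("m must be at least the number of retained SNPs")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class LDMatrix:
    """Pairwise LD correlations aligned to an ordered variant list."""

    variants: list[Variant]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variants)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape must match the variant list")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        w = np.linalg.eigvalsh(self.r)
        if w.min() < -1e-8:
            raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")

    def __len__(self) -> int:
        return len(self.variants)

    def r2(self, i: int, j: int) -> float:
        return float(self.r[i, j] ** 2)

    def index_of(self) -> dict[str, int]:
        return {v.id: i for i, v in enumerate(self.variants)}


@dataclass(frozen=True)
class Region:
    """A genomic window centred on an index association signal."""

    chrom: str
    start: int
    end: int
    index_variant: Variant
    source_trait: str

    def __post_init__(self):
        if not (self.start <= self.index_variant.pos <= self.end):
            raise ValueError("index variant must lie inside the region")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ColocSignal:
    """One colocalized signal: the unit merged into loci.

    ``snp_h4_posterior`` carries the per-SNP causal posterior (conditional on
    a shared causal variant) for the signal's credible-set variants.
    """

    trait_pair: tuple[str, str]
    lead_variant: Variant
    credible_set: list[Variant]
    lead_posterior: float
    pp4: float = 1.0


@dataclass
class Locus:
    """A merged group of mutually overlapping colocalized signals."""

    signals: list[ColocSignal]
    lead_variant: Variant
    phenotype_pairs: set = field(default_factory=set)

    def __post_init__(self):
        if not self.signals:
            raise ValueError("a locus must contain at least one signal")

    @property
    def chrom(self) -> str:
        return self.lead_variant.chrom


# ---------------------------------------------------------------------------
# I/O


def _p_from_z(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return 2.0 * norm.sf(np.abs(z))


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: TraitType | str = TraitType.quantitative,
    case_fraction: float | None = None,
    sep: str | None = None,
) -> RegionStats:
    """Read a delimited summary-statistics file into a :class:`RegionStats`.

    Parameters
    ----------
    dialect
        Mapping from canonical column names (``SNP, CHR, BP, EA, OA, BETA,
        SE, P, N``) to the column names used in the file. Canonical names
        are assumed where the mapping is absent.
    sep
        Field delimiter; autodetected between tab and comma when None.

    Rows with missing or non-positive SE, or missing beta, are dropped and
    counted in the run log.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    required = ("SNP", "CHR", "BP", "EA", "OA", "BETA", "SE")
    for canon in required:
        if colmap[canon] not in df.columns:
            raise KeyError(
                f"required column {colmap[canon]!r} (canonical {canon}) missing from {path}"
            )

    beta = pd.to_numeric(df[colmap["BETA"]], errors="coerce")
    se = pd.to_numeric(df[colmap["SE"]], errors="coerce")
    keep = beta.notna() & se.notna() & (se > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        for line in np.flatnonzero(~keep.to_numpy())[:50]:
            logger.info("read_sumstats: dropped row %d (missing/invalid beta or se)", line + 2)
        logger.info("read_sumstats: dropped %d of %d rows from %s", n_dropped, len(df), path)
    df = df[keep].reset_index(drop=True)

    variants = [
        Variant(
            id=str(r[colmap["SNP"]]),
            chrom=str(r[colmap["CHR"]]),
            pos=int(r[colmap["BP"]]),
            effect_allele=str(r[colmap["EA"]]).upper(),
            other_allele=str(r[colmap["OA"]]).upper(),
        )
        for r in df.to_dict("records")
    ]
    n_col = colmap["N"]
    n = df[n_col].to_numpy() if n_col in df.columns else np.full(len(df), np.nan)
    p = pd.to_numeric(df[colmap["P"]], errors="coerce").to_numpy() if colmap["P"] in df.columns else None
    cf = case_fraction
    if cf is None and colmap["CASE_FRAC"] in df.columns:
        cf = float(df[colmap["CASE_FRAC"]].iloc[0])
    return RegionStats(
        trait_name=trait_name,
        trait_type=TraitType(trait_type),
        variants=variants,
        beta=df[colmap["BETA"]].to_numpy(dtype=float),
        se=df[colmap["SE"]].to_numpy(dtype=float),
        n=n,
        p=p,
        case_fraction=cf,
    )


def write_sumstats(stats: RegionStats, path, sep: str = "\t") -> None:
    """Write canonical-dialect delimited summary statistics."""
    stats.to_frame().to_csv(path, sep=sep, index=False)


def read_ld_matrix(matrix_path, variants: list[Variant] | None = None, variant_path=None) -> LDMatrix:
    """Read a square delimited LD matrix plus a sidecar variant list."""
    r = np.loadtxt(matrix_path, delimiter="\t")
    if variants is None:
        vdf = pd.read_csv(variant_path, sep="\t")
        variants = [
            Variant(str(v.SNP), str(v.CHR), int(v.BP), str(v.EA), str(v.OA))
            for v in vdf.itertuples()
        ]
    if len(variants) != r.shape[0]:
        raise ValueError("LD matrix and variant list are not aligned")
    return LDMatrix(variants=variants, r=r)


def write_ld_matrix(ld: LDMatrix, matrix_path, variant_path) -> None:
    np.savetxt(matrix_path, ld.r, delimiter="\t")
    pd.DataFrame(
        {
            "SNP": [v.id for v in ld.variants],
            "CHR": [v.chrom for v in ld.variants],
            "BP": [v.pos for v in ld.variants],
            "EA": [v.effect_allele for v in ld.variants],
            "OA": [v.other_allele for v in ld.variants],
        }
    ).to_csv(variant_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


def harmonize(
    a: RegionStats,
    b: RegionStats,
    drop_palindromic: bool = False,
) -> tuple[RegionStats, RegionStats]:
    """Restrict two datasets to shared variants with aligned effect alleles.

    Dataset ``b`` is aligned to ``a``: where b's effect/other alleles are
    swapped relative to a, b's beta sign is inverted (and its allele labels
    swapped); variants whose allele pairs are incompatible are dropped.
    Sign-flipping is by allele-label match only; ``drop_palindromic=True``
    additionally removes strand-ambiguous A/T and C/G variants.
    """
    ids_a = a.ids
    ids_b = b.ids
    if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
        raise ValueError("variant ids must be unique within each dataset")
    index_b = {vid: i for i, vid in enumerate(ids_b)}

    keep_a: list[int] = []
    keep_b: list[int] = []
    flip: list[bool] = []
    for i, va in enumerate(a.variants):
        j = index_b.get(va.id)
        if j is None:
            continue
        vb = b.variants[j]
        if drop_palindromic and va.is_palindromic():
            logger.info("harmonize: dropped palindromic variant %s", va.id)
            continue
        if (va.effect_allele, va.other_allele) == (vb.effect_allele, vb.other_allele):
            flip.append(False)
        elif (va.effect_allele, va.other_allele) == (vb.other_allele, vb.effect_allele):
            flip.append(True)
            logger.info("harmonize: flipped effect sign for %s", va.id)
        else:
            logger.info(
                "harmonize: dropped %s (incompatible alleles %s/%s vs %s/%s)",
                va.id, va.effect_allele, va.other_allele, vb.effect_allele, vb.other_allele,
            )
            continue
        keep_a.append(i)
        keep_b.append(j)

    if not keep_a:
        raise ValueError("no shared variants between the two datasets")

    out_a = a.subset(keep_a)
    out_b = b.subset(keep_b)
    flip_arr = np.asarray(flip, dtype=bool)
    out_b.beta = np.where(flip_arr, -out_b.beta, out_b.beta)
    out_b.variants = [
        Variant(v.id, v.chrom, v.pos, va.effect_allele, va.other_allele)
        if f
        else v
        for v, va, f in zip(out_b.variants, out_a.variants, flip_arr)
    ]
    return out_a, out_b


# ---------------------------------------------------------------------------
# Region definition and locus merging

#: Default half-window around an index signal (1 Mb per side -> 2 Mb regions).
DEFAULT_WINDOW_BP = 1_000_000
#: Genome-wide significance for the T2D-style scan.
GW_SIGNIFICANCE = 5e-8
#: Multiple-phenotype adjusted genome-wide significance for the OA-style scan.
ADJUSTED_GW_SIGNIFICANCE = 1.3e-8


def define_regions(
    stats: RegionStats,
    p_threshold: float = GW_SIGNIFICANCE,
    window_bp: int = DEFAULT_WINDOW_BP,
    index_variants: Iterable[str] | None = None,
) -> list[Region]:
    """Define 2 Mb analysis windows (±``window_bp``) around index signals.

    Index signals are chosen greedily by ascending p value, suppressing any
    further index within ``window_bp`` on the same chromosome; ties are broken
    by (p, position, id). An explicit ``index_variants`` id list bypasses the
    greedy selection (for externally established signals).
    """
    p = stats.p if stats.p is not None else _p_from_z(stats.z)
    if index_variants is not None:
        wanted = set(index_variants)
        out = []
        for v in stats.variants:
            if v.id in wanted:
                out.append(Region(v.chrom, max(1, v.pos - window_bp), v.pos + window_bp, v, stats.trait_name))
        return out

    order = sorted(
        np.flatnonzero(p <= p_threshold),
        key=lambda i: (p[i], stats.variants[i].pos, stats.variants[i].id),
    )
    chosen: list[Variant] = []
    for i in order:
        v = stats.variants[i]
        if any(c.chrom == v.chrom and abs(c.pos - v.pos) <= window_bp for c in chosen):
            logger.info("define_regions: %s suppressed by a stronger nearby index", v.id)
            continue
        chosen.append(v)
    return [
        Region(v.chrom, max(1, v.pos - window_bp), v.pos + window_bp, v, stats.trait_name)
        for v in chosen
    ]


def merge_signals_to_loci(
    signals: Sequence[ColocSignal],
    lead_distance_bp: int = 1_000_000,
) -> list[Locus]:
    """Collapse colocalized signals into unique genomic loci.

    Two signals are merged when their 95% credible sets share a variant or
    their lead variants lie within ``lead_distance_bp`` on the same
    chromosome; merging is transitive (union-find closure). The locus lead is
    the member lead variant with the highest per-SNP shared-causal posterior.
    """
    n = len(signals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    cs_ids = [set(v.id for v in s.credible_set) for s in signals]
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = signals[i], signals[j]
            close = (
                si.lead_variant.chrom == sj.lead_variant.chrom
                and abs(si.lead_variant.pos - sj.lead_variant.pos) <= lead_distance_bp
            )
            if close or (cs_ids[i] & cs_ids[j]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for members in groups.values():
        group = [signals[i] for i in members]
        lead = max(group, key=lambda s: (s.lead_posterior, -s.lead_variant.pos)).lead_variant
        loci.append(
            Locus(
                signals=group,
                lead_variant=lead,
                phenotype_pairs={s.trait_pair for s in group},
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.lead_variant.pos))
    return loci


def annotate_direction(
    credible_set: Sequence[Variant],
    external: RegionStats,
    alpha: float = GW_SIGNIFICANCE,
) -> pd.DataFrame:
    """Look up effect direction and significance of credible-set variants.

    ``external`` must already be harmonized to the credible set's allele
    orientation. Returns one row per credible-set variant with the sign of the
    external beta, a significance flag at ``alpha`` and a missingness flag.
    """
    idx = {v.id: i for i, v in enumerate(external.variants)}
    p_ext = external.p if external.p is not None else _p_from_z(external.z)
    rows = []
    for v in credible_set:
        i = idx.get(v.id)
        if i is None:
            rows.append({"SNP": v.id, "sign": "", "significant": False, "missing": True})
        else:
            rows.append(
                {
                    "SNP": v.id,
                    "sign": "+" if external.beta[i] > 0 else ("-" if external.beta[i] < 0 else "0"),
                    "significant": bool(p_ext[i] <= alpha),
                    "missing": False,
                }
            )
    return pd.DataFrame(rows)
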