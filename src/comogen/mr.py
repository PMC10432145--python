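"""Two-sample Mendelian randomization from harmonized summary statistics.

Implements instrument selection (genome-wide significance plus greedy LD
clumping), Steiger directionality filtering, the Wald ratio, inverse-variance
weighted (IVW) estimation with multiplicative random effects, the weighted
median with parametric-bootstrap SE, MR-Egger regression with its pleiotropy
intercept, Cochran heterogeneity, summary-level instrument-strength F
statistics, Benjamini-Hochberg FDR adjustment, two-step mediation
orchestration and a Z test for comparing two independent estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import GW_SIGNIFICANCE, LDMatrix, RegionStats, Variant, harmonize

logger = logging.getLogger("comogen")

#: Clumping defaults: strict r^2 over a 10 Mb window per side.
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000
#: Conventional weak-instrument threshold for the mean F statistic.
WEAK_F_THRESHOLD = 10.0

__all__ = [
    "InstrumentSet",
    "MRResult",
    "MRModel",
    "clump",
    "steiger_filter",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "f_statistic",
    "fdr_adjust",
    "run_mr",
    "two_step_mr",
    "estimate_difference_z",
]


@dataclass
class InstrumentSet:
    """Harmonized per-variant exposure and outcome effects for MR."""

    variants: list[str]
    b_exp: np.ndarray
    se_exp: np.ndarray
    b_out: np.ndarray
    se_out: np.ndarray
    n_exp: np.ndarray | None = None
    n_out: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.b_exp = np.asarray(self.b_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        k = len(self.variants)
        for name in ("b_exp", "se_exp", "b_out", "se_out"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length must match the variant list")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be positive")
        for name in ("n_exp", "n_out"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.broadcast_to(np.asarray(v, dtype=float), (k,)).copy())

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, idx) -> "InstrumentSet":
        idx = np.asarray(idx, dtype=int)
        return InstrumentSet(
            variants=[self.variants[i] for i in idx],
            b_exp=self.b_exp[idx], se_exp=self.se_exp[idx],
            b_out=self.b_out[idx], se_out=self.se_out[idx],
            n_exp=None if self.n_exp is None else self.n_exp[idx],
            n_out=None if self.n_out is None else self.n_out[idx],
            provenance=list(self.provenance),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InstrumentSet":
        return cls(
            variants=list(df["SNP"].astype(str)),
            b_exp=df["b_exp"].to_numpy(), se_exp=df["se_exp"].to_numpy(),
            b_out=df["b_out"].to_numpy(), se_out=df["se_out"].to_numpy(),
            n_exp=df["n_exp"].to_numpy() if "n_exp" in df else None,
            n_out=df["n_out"].to_numpy() if "n_out" in df else None,
        )

    @property
    def wald_ratios(self) -> np.ndarray:
        return self.b_out / self.b_exp

    @property
    def wald_se(self) -> np.ndarray:
        return self.se_out / np.abs(self.b_exp)


@dataclass
class MRResult:
    """One MR estimate with its sensitivity diagnostics."""

    method: str
    estimate: float
    se: float
    p: float
    n_snps: int
    q: float = np.nan
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    f_stat: float = np.nan
    fdr_q: float = np.nan

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def weak_instruments(self) -> bool:
        return bool(np.isfinite(self.f_stat) and self.f_stat < WEAK_F_THRESHOLD)

    def summary(self) -> str:
        lo, hi = self.ci95
        out = (
            f"{self.method}: estimate {self.estimate:.4f} (se {self.se:.4f}, "
            f"95% CI [{lo:.4f}, {hi:.4f}], p {self.p:.3g}, {self.n_snps} SNPs)"
        )
        if np.isfinite(self.q):
            out += f"\n  heterogeneity Q {self.q:.2f} (p {self.q_p:.3g})"
        if np.isfinite(self.egger_intercept):
            out += f"\n  Egger intercept {self.egger_intercept:.4f} (p {self.egger_intercept_p:.3g})"
        if np.isfinite(self.f_stat):
            flag = " [weak instruments]" if self.weak_instruments else ""
            out += f"\n  F statistic {self.f_stat:.1f}{flag}"
        return out


# ---------------------------------------------------------------------------
# Instrument selection


def clump(
    candidates: RegionStats,
    ld: LDMatrix | None,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    p_threshold: float | None = None,
) -> list[Variant]:
    """Greedy LD clumping: repeatedly keep the lowest-p remaining SNP and
    discard every SNP with r^2 >= threshold within the window around it.

    Pairs with no LD entry (and all cross-chromosome pairs) are treated as
    r^2 = 0 with a logged warning. Ties are broken by (p, position, id).
    """
    p = candidates.p
    if p is None:
        p = 2.0 * sps.norm.sf(np.abs(candidates.z))
    idx = np.arange(len(candidates))
    if p_threshold is not None:
        idx = idx[p[idx] <= p_threshold]
    order = sorted(idx, key=lambda i: (p[i], candidates.variants[i].pos, candidates.variants[i].id))
    ld_index = ld.index_of() if ld is not None else {}

    kept: list[Variant] = []
    removed: set[int] = set()
    warned = False
    for i in order:
        if i in removed:
            continue
        vi = candidates.variants[i]
        kept.append(vi)
        ii = ld_index.get(vi.id)
        for j in order:
            if j == i or j in removed:
                continue
            vj = candidates.variants[j]
            if vi.chrom != vj.chrom or abs(vi.pos - vj.pos) > window_bp:
                continue
            jj = ld_index.get(vj.id)
            if ii is None or jj is None:
                if not warned:
                    logger.warning("clump: missing LD for some pairs; treating r^2 as 0")
                    warned = True
                continue
            if ld.r2(ii, jj) >= r2_threshold:
                removed.add(j)
    return kept


def steiger_filter(iv: InstrumentSet) -> InstrumentSet:
    """Keep instruments explaining strictly more variance in the exposure.

    Per SNP the variance explained is approximated as r^2 = z^2 / (z^2 + n)
    on each side; the SNP is retained iff r2_exposure > r2_outcome. SNPs
    missing a sample size are dropped with a warning.
    """
    if iv.n_exp is None or iv.n_out is None:
        raise ValueError("Steiger filtering requires per-variant sample sizes")
    z_exp = iv.b_exp / iv.se_exp
    z_out = iv.b_out / iv.se_out
    ok_n = np.isfinite(iv.n_exp) & np.isfinite(iv.n_out)
    if not ok_n.all():
        logger.warning("steiger_filter: dropped %d SNPs with missing n", int((~ok_n).sum()))
    r2_exp = z_exp**2 / (z_exp**2 + iv.n_exp)
    r2_out = z_out**2 / (z_out**2 + iv.n_out)
    keep = ok_n & (r2_exp > r2_out)
    out = iv.subset(np.flatnonzero(keep))
    for vid, kept in zip(iv.variants, keep):
        out.provenance.append(f"steiger:{vid}:{'keep' if kept else 'drop'}")
    return out


# ---------------------------------------------------------------------------
# Estimators


def wald_ratio(
    b_exp: float, se_exp: float, b_out: float, se_out: float,
    second_order: bool = False,
) -> MRResult:
    """Single-instrument causal estimate b_out / b_exp.

    The default SE is the first-order delta method se_out / |b_exp|;
    ``second_order=True`` adds the exposure-uncertainty term.
    """
    if b_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for b_exp = 0")
    est = b_out / b_exp
    se = se_out / abs(b_exp)
    if second_order:
        se = np.sqrt(se_out**2 / b_exp**2 + b_out**2 * se_exp**2 / b_exp**4)
    p = 2.0 * sps.norm.sf(abs(est) / se)
    return MRResult(method="wald", estimate=float(est), se=float(se), p=float(p), n_snps=1)


def ivw(iv: InstrumentSet) -> MRResult:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Weighted regression of b_out on b_exp through the origin with weights
    1/se_out^2; the SE is scaled by max(1, residual scale). With a single
    instrument this reduces exactly to the Wald ratio.
    """
    if len(iv) < 1:
        raise ValueError("ivw requires at least one instrument")
    w = 1.0 / iv.se_out**2
    sxx = float(np.sum(w * iv.b_exp**2))
    est = float(np.sum(w * iv.b_exp * iv.b_out) / sxx)
    se_fixed = float(np.sqrt(1.0 / sxx))
    resid = iv.b_out - est * iv.b_exp
    q = float(np.sum(w * resid**2))
    n = len(iv)
    if n >= 2:
        scale = np.sqrt(q / (n - 1))
        q_p = float(sps.chi2.sf(q, n - 1))
    else:
        scale, q_p = 1.0, np.nan
    se = se_fixed * max(1.0, scale)
    p = 2.0 * sps.norm.sf(abs(est) / se)
    return MRResult(method="ivw", estimate=est, se=se, p=float(p), n_snps=n, q=q, q_p=q_p)


def weighted_median(iv: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the Wald ratios (50% breakdown estimator).

    Ratios are ordered; with inverse-variance weights normalized to 1 the
    estimate interpolates the ratio at cumulative weight 0.5. The SE comes
    from a seeded parametric bootstrap of the summary statistics.
    """
    if len(iv) < 3:
        raise ValueError("weighted_median requires at least three instruments")

    def wm(b_exp, b_out) -> float:
        ratios = b_out / b_exp
        w = 1.0 / (iv.se_out / np.abs(b_exp)) ** 2
        order = np.argsort(ratios)
        r, wv = ratios[order], w[order]
        cum = np.cumsum(wv) - 0.5 * wv
        cum /= wv.sum()
        if cum[0] >= 0.5:
            return float(r[0])
        below = np.flatnonzero(cum < 0.5)[-1]
        if below == len(r) - 1:
            return float(r[-1])
        f = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
        return float(r[below] + f * (r[below + 1] - r[below]))

    est = wm(iv.b_exp, iv.b_out)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(iv.b_exp, iv.se_exp)
        by = rng.normal(iv.b_out, iv.se_out)
        boot[b] = wm(bx, by)
    se = float(np.std(boot, ddof=1))
    p = 2.0 * sps.norm.sf(abs(est) / se) if se > 0 else (0.0 if est else 1.0)
    return MRResult(method="weighted_median", estimate=est, se=se, p=float(p), n_snps=len(iv))


def egger(iv: InstrumentSet) -> MRResult:
    """MR-Egger regression: slope is the pleiotropy-adjusted causal estimate,
    the intercept measures directional horizontal pleiotropy.

    Exposure effects are oriented positive (flipping outcome effects
    jointly); the weighted regression uses 1/se_out^2 weights and the
    multiplicative random-effects SE scaling. Intercept and slope p values
    use a t distribution with n - 2 degrees of freedom.
    """
    n = len(iv)
    if n < 3:
        raise ValueError("egger requires at least three instruments")
    flip = np.sign(iv.b_exp)
    flip[flip == 0] = 1.0
    bx = iv.b_exp * flip
    by = iv.b_out * flip
    w = 1.0 / iv.se_out**2

    sw, swx = w.sum(), (w * bx).sum()
    swy, swxx, swxy = (w * by).sum(), (w * bx * bx).sum(), (w * bx * by).sum()
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (n - 2)))
    se_slope = np.sqrt(sw / denom) * scale
    se_int = np.sqrt(swxx / denom) * scale
    p_slope = 2.0 * sps.t.sf(abs(slope) / se_slope, n - 2)
    p_int = 2.0 * sps.t.sf(abs(intercept) / se_int, n - 2)
    return MRResult(
        method="egger", estimate=float(slope), se=float(se_slope), p=float(p_slope),
        n_snps=n, q=q, q_p=float(sps.chi2.sf(q, n - 2)),
        egger_intercept=float(intercept), egger_intercept_se=float(se_int),
        egger_intercept_p=float(p_int),
    )


def f_statistic(b_exp: np.ndarray, se_exp: np.ndarray) -> float:
    """Summary-level instrument strength: mean over SNPs of (beta/se)^2."""
    b_exp = np.atleast_1d(np.asarray(b_exp, dtype=float))
    se_exp = np.atleast_1d(np.asarray(se_exp, dtype=float))
    return float(np.mean((b_exp / se_exp) ** 2))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def estimate_difference_z(result_a: MRResult, result_b: MRResult) -> tuple[float, float]:
    """Z test for the difference between two independent MR estimates."""
    z = (result_a.estimate - result_b.estimate) / np.sqrt(result_a.se**2 + result_b.se**2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Dispatch and orchestration


def run_mr(iv: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> list[MRResult]:
    """Method dispatch by instrument count: one SNP uses the Wald ratio, two
    or more IVW with heterogeneity, more than three additionally MR-Egger
    (and the weighted median from three). The F statistic is attached to all.
    """
    if len(iv) == 0:
        return []
    f = f_statistic(iv.b_exp, iv.se_exp)
    if len(iv) == 1:
        res = [wald_ratio(iv.b_exp[0], iv.se_exp[0], iv.b_out[0], iv.se_out[0])]
    else:
        res = [ivw(iv)]
        if len(iv) >= 3:
            res.append(weighted_median(iv, n_boot=n_boot, seed=seed))
        if len(iv) > 3:
            res.append(egger(iv))
    for r in res:
        r.f_stat = f
    return res


def select_instruments(
    exposure: RegionStats,
    outcome: RegionStats,
    ld: LDMatrix | None = None,
    p_threshold: float = GW_SIGNIFICANCE,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    steiger: bool = True,
    exclude_near: Sequence[Variant] = (),
) -> InstrumentSet:
    """Build a harmonized instrument set from exposure and outcome statistics.

    Genome-wide-significant exposure SNPs are LD-clumped, optionally purged
    of SNPs in LD with ``exclude_near`` index variants (instrument-overlap
    exclusion for mediation analyses), harmonized against the outcome and
    optionally Steiger-filtered.
    """
    kept = clump(exposure, ld, r2_threshold=r2_threshold, window_bp=window_bp, p_threshold=p_threshold)
    if exclude_near:
        ld_index = ld.index_of() if ld is not None else {}
        excluded = []
        for v in kept:
            drop = False
            for e in exclude_near:
                if v.chrom != e.chrom or abs(v.pos - e.pos) > window_bp:
                    continue
                vi, ei = ld_index.get(v.id), ld_index.get(e.id)
                r2 = ld.r2(vi, ei) if (vi is not None and ei is not None) else 0.0
                if v.id == e.id or r2 >= r2_threshold:
                    drop = True
                    break
            if not drop:
                excluded.append(v)
        kept = excluded
    kept_ids = {v.id for v in kept}
    idx = [i for i, v in enumerate(exposure.variants) if v.id in kept_ids]
    exp_sub = exposure.subset(idx)
    try:
        exp_h, out_h = harmonize(exp_sub, outcome)
    except ValueError:
        return InstrumentSet(variants=[], b_exp=[], se_exp=[], b_out=[], se_out=[],
                             provenance=["no shared variants"])
    iv = InstrumentSet(
        variants=exp_h.ids,
        b_exp=exp_h.beta, se_exp=exp_h.se, b_out=out_h.beta, se_out=out_h.se,
        n_exp=exp_h.n, n_out=out_h.n,
        provenance=[f"p_threshold={p_threshold}", f"clump_r2={r2_threshold}",
                    f"clump_window_bp={window_bp}"],
    )
    if steiger:
        iv = steiger_filter(iv)
    return iv


def two_step_mr(
    adiposity: RegionStats,
    expression: Mapping[tuple[str, str], RegionStats],
    disease: RegionStats,
    ld: LDMatrix | None = None,
    p_threshold: float = GW_SIGNIFICANCE,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    steiger: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-step mediation MR: adiposity -> gene expression -> disease.

    Step 1 instruments the adiposity measure on each gene's expression.
    Step 2 instruments each gene's expression (cis eQTLs, excluding variants
    in LD with the adiposity index SNPs) on the disease, dispatching the
    estimator by instrument count. FDR adjustment is applied per step across
    the gene batch. Genes with no surviving instruments are reported with a
    note rather than raising.
    """
    adiposity_index = clump(adiposity, ld, r2_threshold=r2_threshold,
                            window_bp=window_bp, p_threshold=p_threshold)
    rows = []
    for (gene, tissue), eqtl in expression.items():
        # step 1: adiposity -> expression
        iv1 = select_instruments(adiposity, eqtl, ld, p_threshold, r2_threshold,
                                 window_bp, steiger=steiger)
        if len(iv1) == 0:
            rows.append({"gene": gene, "tissue": tissue, "step": 1, "method": "none",
                         "note": "no valid instruments"})
        else:
            for r in run_mr(iv1, seed=seed):
                rows.append({"gene": gene, "tissue": tissue, "step": 1, "method": r.method,
                             "estimate": r.estimate, "se": r.se, "p": r.p, "n_snps": r.n_snps,
                             "q": r.q, "q_p": r.q_p, "egger_intercept": r.egger_intercept,
                             "egger_intercept_p": r.egger_intercept_p, "f_stat": r.f_stat,
                             "note": ""})
        # step 2: expression -> disease, excluding adiposity-linked eQTLs
        iv2 = select_instruments(eqtl, disease, ld, p_threshold, r2_threshold,
                                 window_bp, steiger=steiger, exclude_near=adiposity_index)
        if len(iv2) == 0:
            rows.append({"gene": gene, "tissue": tissue, "step": 2, "method": "none",
                         "note": "no valid instruments"})
        else:
            for r in run_mr(iv2, seed=seed):
                rows.append({"gene": gene, "tissue": tissue, "step": 2, "method": r.method,
                             "estimate": r.estimate, "se": r.se, "p": r.p, "n_snps": r.n_snps,
                             "q": r.q, "q_p": r.q_p, "egger_intercept": r.egger_intercept,
                             "egger_intercept_p": r.egger_intercept_p, "f_stat": r.f_stat,
                             "note": ""})
    report = pd.DataFrame(rows)
    if "p" in report.columns:
        for step in (1, 2):
            mask = (report["step"] == step) & report["p"].notna()
            if mask.any():
                report.loc[mask, "fdr_q"] = fdr_adjust(report.loc[mask, "p"].to_numpy())
    return report


# ---------------------------------------------------------------------------
# Model facade


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    ``fit(method=...)`` returns a single :class:`MRResult`; ``fit_all()``
    runs the count-appropriate battery and returns a tidy frame.
    """

    _METHODS = {"wald", "ivw", "weighted_median", "egger"}

    def __init__(self, instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0):
        self.instruments = instruments
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, method: str = "ivw") -> MRResult:
        iv = self.instruments
        if method not in self._METHODS:
            raise ValueError(f"unknown method {method!r}")
        if method == "wald":
            if len(iv) != 1:
                raise ValueError("wald applies to exactly one instrument")
            res = wald_ratio(iv.b_exp[0], iv.se_exp[0], iv.b_out[0], iv.se_out[0])
        elif method == "ivw":
            res = ivw(iv)
        elif method == "weighted_median":
            res = weighted_median(iv, n_boot=self.n_boot, seed=self.seed)
        else:
            res = egger(iv)
        res.f_stat = f_statistic(iv.b_exp, iv.se_exp)
        return res

    def fit_all(self) -> pd.DataFrame:
        res = run_mr(self.instruments, n_boot=self.n_boot, seed=self.seed)
        return pd.DataFrame(
            [
                {
                    "method": r.method, "estimate": r.estimate, "se": r.se,
                    "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p,
                    "n_snps": r.n_snps, "q": r.q, "q_p": r.q_p,
                    "egger_intercept": r.egger_intercept,
                    "egger_intercept_p": r.egger_intercept_p, "f_stat": r.f_stat,
                }
                for r in res
            ]
        )
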