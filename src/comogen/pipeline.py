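"""End-to-end orchestration on a synthetic comorbidity scenario.

``run_pipeline`` wires the full chain together: simulate regional summary
statistics for a disease pair across several loci, run pairwise
colocalization and keep signals passing the PP4 threshold, merge signals
into unique loci, superimpose a molecular-QTL trait with the multi-trait
engine, run bidirectional MR between the diseases, and score a synthetic
per-gene evidence table. Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coloc as _coloc
from . import mr as _mr
from . import scoring as _scoring
from . import simulate as _sim
from .sumstats import ColocSignal, harmonize, merge_signals_to_loci

#: OA phenotypes cycled across simulated regions.
_REGION_PHENOTYPES = ("knee", "hip", "all", "TKR")


def run_pipeline(
    seed: int = 0,
    n_regions: int = 6,
    n_snps: int = 150,
    ld_decay: float = 0.9,
    causal_z: float = 8.0,
    pp4_threshold: float = _coloc.PP4_THRESHOLD,
    n_evidence_genes: int = 200,
) -> dict:
    """Run simulate -> coloc -> multicoloc -> mr -> score on one scenario.

    The first ``n_regions - 2`` regions are simulated under a shared causal
    variant (H4), the next under distinct causal variants (H3) and the last
    under the null; each region lives on its own chromosome. Returns a dict
    with the locus table, per-gene scores, the MR report and the multi-trait
    result.
    """
    rng = np.random.default_rng(seed)
    signals = []
    region_rows = []
    h4_stats = None

    hypotheses = ["H4"] * max(0, n_regions - 2) + ["H3", "H0"][: min(2, n_regions)]
    for k, hyp in enumerate(hypotheses):
        chrom = str(k + 1)
        variants = _sim.make_variants(n_snps, chrom=chrom, start=1_000_000)
        ld = _sim.make_ld(n_snps, ld_decay, variants=variants)
        kwargs = dict(
            n_snps=n_snps, ld_decay=ld_decay, hypothesis=hyp, causal_z=causal_z,
            seed=int(rng.integers(2**31 - 1)), swap_allele_fraction=0.2,
        )
        if hyp == "H4":
            kwargs["causal_index_1"] = kwargs["causal_index_2"] = n_snps // 2
        elif hyp == "H3":
            kwargs["causal_index_1"], kwargs["causal_index_2"] = n_snps // 4, 3 * n_snps // 4
        scenario = _sim.RegionScenario(**kwargs)
        t2d, oa = _sim.simulate_region(scenario, ld)
        pheno = _REGION_PHENOTYPES[k % len(_REGION_PHENOTYPES)]
        t2d.trait_name, oa.trait_name = "T2D", pheno
        a, b = harmonize(t2d, oa)
        res = _coloc.ColocModel(a, b).fit()
        region_rows.append(
            {
                "region": f"chr{chrom}", "oa_phenotype": pheno, "hypothesis": hyp,
                "pp0": res.pp[0], "pp1": res.pp[1], "pp2": res.pp[2],
                "pp3": res.pp[3], "pp4": res.pp[4],
                "lead_variant": res.lead_variant.id,
                "credible_set_size": len(res.credible_set),
                "colocalizes": res.colocalizes(pp4_threshold),
            }
        )
        if res.colocalizes(pp4_threshold):
            lead_idx = res.variants.index(res.lead_variant)
            signals.append(
                ColocSignal(
                    trait_pair=("T2D", pheno), lead_variant=res.lead_variant,
                    credible_set=res.credible_set,
                    lead_posterior=float(res.snp_h4_posterior[lead_idx]),
                    pp4=res.pp4,
                )
            )
            if h4_stats is None:
                h4_stats = (a, b, ld, scenario, res)

    loci = merge_signals_to_loci(signals)
    locus_table = pd.DataFrame(
        {
            "locus": [f"locus{i + 1}" for i in range(len(loci))],
            "chrom": [l.chrom for l in loci],
            "lead_variant": [l.lead_variant.id for l in loci],
            "n_signals": [len(l.signals) for l in loci],
            "oa_phenotypes": [sorted(p[1] for p in l.phenotype_pairs) for l in loci],
        }
    )

    # multi-trait run: superimpose an eQTL trait sharing the causal variant
    multi = None
    if h4_stats is not None:
        a, b, ld, scenario, res = h4_stats
        eqtl_scenario = _sim.RegionScenario(
            n_snps=scenario.n_snps, ld_decay=scenario.ld_decay, hypothesis="H4",
            causal_index_1=scenario.causal_index_1, causal_index_2=scenario.causal_index_2,
            causal_z=causal_z, trait_types=("quantitative", "quantitative"),
            n_samples=(400, 400), seed=scenario.seed + 1,
        )
        eqtl, _ = _sim.simulate_region(eqtl_scenario, ld)
        eqtl.trait_name = "eQTL"
        ids = [v.id for v in res.credible_set]
        keep = [i for i, v in enumerate(a.variants) if v.id in set(ids)]
        multi = _coloc.multicoloc_with_fallback(
            [s.subset(keep) for s in (a, b, eqtl)], [a, b, eqtl]
        )

    # bidirectional MR between the disease pair (no causal link simulated)
    mr_rows = []
    for direction in ("T2D->OA", "OA->T2D"):
        iv = _mr.InstrumentSet.from_frame(
            _sim.simulate_instruments(
                n_snps=30, true_effect=0.0, seed=int(rng.integers(2**31 - 1))
            )
        )
        for r in _mr.run_mr(iv, seed=seed):
            mr_rows.append(
                {"analysis": direction, "method": r.method, "estimate": r.estimate,
                 "se": r.se, "p": r.p, "n_snps": r.n_snps, "q": r.q, "q_p": r.q_p,
                 "f_stat": r.f_stat}
            )
    mr_report = pd.DataFrame(mr_rows)
    mr_report["fdr_q"] = _mr.fdr_adjust(mr_report["p"].to_numpy())

    # per-gene evidence scoring with joint stratification
    evidence = _sim.simulate_evidence(
        _sim.EvidenceScenario(n_genes=n_evidence_genes, seed=int(rng.integers(2**31 - 1)))
    )
    scores = _scoring.score_table(evidence)
    locus_phenos = {
        row.locus: set(row.oa_phenotypes) for row in locus_table.itertuples()
    }
    all_phenos = sorted({p for s in locus_phenos.values() for p in s})
    stratum = _scoring.stratify_joint(all_phenos) if all_phenos else set()
    scores["joint_stratum"] = [",".join(sorted(stratum))] * len(scores)

    return {
        "regions": pd.DataFrame(region_rows),
        "locus_table": locus_table,
        "multicoloc": multi,
        "mr_report": mr_report,
        "gene_scores": scores,
        "n_likely": int((scores["classification"].isin(["likely", "high_confidence"])).sum()),
        "n_high_confidence": int((scores["classification"] == "high_confidence").sum()),
    }
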