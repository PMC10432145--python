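"""Two-sample MR: clumping, Steiger filtering, estimators, FDR, two-step."""

import numpy as np
import pytest
from scipy.stats import kstest

from comogen.mr import (
    InstrumentSet,
    MRModel,
    clump,
    egger,
    estimate_difference_z,
    f_statistic,
    fdr_adjust,
    ivw,
    run_mr,
    select_instruments,
    steiger_filter,
    two_step_mr,
    wald_ratio,
    weighted_median,
)
from comogen.simulate import make_ld, make_variants, simulate_instruments
from comogen.sumstats import LDMatrix, TraitType

from conftest import make_region_stats
from oracles import bh_stepup, greedy_clump


def _iv(b_exp, se_exp, b_out, se_out, n=100_000):
    k = len(b_exp)
    return InstrumentSet(
        variants=[f"rs{i}" for i in range(k)],
        b_exp=np.asarray(b_exp, dtype=float), se_exp=np.broadcast_to(se_exp, (k,)).astype(float),
        b_out=np.asarray(b_out, dtype=float), se_out=np.broadcast_to(se_out, (k,)).astype(float),
        n_exp=np.full(k, n), n_out=np.full(k, n),
    )


class TestClump:
    def _stats_with_ld(self, pvals, positions, r):
        variants = [
            make_variants(1)[0].__class__(f"rs{i}", "1", int(p), "A", "G")
            for i, p in enumerate(positions)
        ]
        st = make_region_stats(np.full(len(pvals), 0.1), 0.05, variants=variants)
        st.p = np.asarray(pvals, dtype=float)
        ld = LDMatrix(variants=variants, r=np.asarray(r, dtype=float))
        return st, ld

    def test_correlated_pair_keeps_lower_p(self):
        r = [[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]
        st, ld = self._stats_with_ld([1e-10, 1e-8], [100_000, 110_000], r)
        kept = clump(st, ld, r2_threshold=0.001, window_bp=10_000_000)
        assert [v.id for v in kept] == ["rs0"]

    def test_sub_threshold_r2_keeps_both(self):
        r = [[1.0, np.sqrt(0.0005)], [np.sqrt(0.0005), 1.0]]
        st, ld = self._stats_with_ld([1e-10, 1e-8], [100_000, 110_000], r)
        kept = clump(st, ld, r2_threshold=0.001, window_bp=10_000_000)
        assert len(kept) == 2

    def test_outside_window_keeps_both(self):
        r = [[1.0, 0.9], [0.9, 1.0]]
        st, ld = self._stats_with_ld([1e-10, 1e-8], [100_000, 30_000_000], r)
        kept = clump(st, ld, r2_threshold=0.001, window_bp=10_000_000)
        assert len(kept) == 2

    def test_matches_independent_greedy_oracle(self, rng):
        n = 50
        ld = make_ld(n, 0.8)
        st = make_region_stats(rng.normal(0, 0.2, n), 0.05, variants=ld.variants)
        st.p = 10.0 ** (-rng.uniform(1, 12, n))
        kept = clump(st, ld, r2_threshold=0.1, window_bp=500_000)
        expected = greedy_clump(
            [v.pos for v in st.variants], [v.chrom for v in st.variants],
            list(st.p), ld.r**2, 0.1, 500_000,
        )
        assert [v.id for v in kept] == [st.variants[i].id for i in expected]

    def test_missing_ld_treated_as_independent(self, rng):
        st = make_region_stats(rng.normal(0, 0.2, 4), 0.05)
        st.p = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        kept = clump(st, None, r2_threshold=0.001, window_bp=10_000_000)
        assert len(kept) == 4


class TestSteiger:
    def test_exposure_dominant_snp_retained(self):
        iv = _iv([0.1], 0.01, [0.02], 0.01, n=1000)  # z_exp=10, z_out=2
        out = steiger_filter(iv)
        assert len(out) == 1

    def test_equal_variance_removed_on_strict_inequality(self):
        iv = _iv([0.05], 0.01, [0.05], 0.01, n=1000)
        assert len(steiger_filter(iv)) == 0

    def test_reverse_causal_instruments_mostly_removed(self):
        removed = 0
        total = 0
        rng = np.random.default_rng(1)
        for _ in range(200):
            # outcome-first architecture: SNPs act on the outcome, exposure
            # effects are attenuated downstream copies
            b_out = rng.normal(0.2, 0.02, 10)
            b_exp = 0.4 * b_out + rng.normal(0, 0.02, 10)
            iv = _iv(b_exp, 0.02, b_out, 0.02)
            total += len(iv)
            removed += len(iv) - len(steiger_filter(iv))
        assert removed / total > 0.5

    def test_requires_sample_sizes(self):
        iv = _iv([0.1], 0.01, [0.02], 0.01)
        iv.n_exp = None
        with pytest.raises(ValueError):
            steiger_filter(iv)


class TestWaldRatio:
    def test_closed_form(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        lo, hi = r.ci95
        assert (lo, hi) == (pytest.approx(0.5 - 0.196), pytest.approx(0.5 + 0.196))

    def test_null_outcome(self):
        r = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert r.estimate == 0.0
        assert r.p == pytest.approx(1.0)

    def test_orientation_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.01)
        assert a.estimate == b.estimate and a.se == b.se

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_second_order_se_larger(self):
        a = wald_ratio(0.1, 0.05, 0.05, 0.01)
        b = wald_ratio(0.1, 0.05, 0.05, 0.01, second_order=True)
        assert b.se > a.se


class TestIvw:
    def test_identical_ratios_give_zero_q(self):
        iv = _iv([0.1, 0.2, 0.4], 0.01, [0.03, 0.06, 0.12], 0.01)
        r = ivw(iv)
        assert r.estimate == pytest.approx(0.3)
        assert r.q == pytest.approx(0.0, abs=1e-20)

    def test_two_snp_weighted_mean_oracle(self):
        iv = _iv([0.1, 0.2], [0.01, 0.01], [0.05, 0.04], [0.01, 0.02])
        r = ivw(iv)
        ratios = iv.b_out / iv.b_exp
        w = (iv.b_exp / iv.se_out) ** 2  # 1/var of each Wald ratio
        assert r.estimate == pytest.approx(np.sum(w * ratios) / np.sum(w), abs=1e-12)

    def test_single_snp_reduces_to_wald(self):
        r_ivw = ivw(_iv([0.1], 0.01, [0.05], 0.01))
        r_wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert r_ivw.estimate == pytest.approx(r_wald.estimate, abs=1e-15)
        assert r_ivw.se == pytest.approx(r_wald.se, abs=1e-15)

    def test_joint_sign_flip_invariance(self, rng):
        df = simulate_instruments(n_snps=20, seed=4)
        iv = InstrumentSet.from_frame(df)
        base = ivw(iv)
        flip = rng.choice([-1.0, 1.0], size=20)
        iv2 = _iv(iv.b_exp * flip, iv.se_exp, iv.b_out * flip, iv.se_out)
        assert ivw(iv2).estimate == pytest.approx(base.estimate, abs=1e-12)

    def test_null_simulation_p_uniform(self):
        pvals = [
            ivw(InstrumentSet.from_frame(
                simulate_instruments(n_snps=30, true_effect=0.0, seed=s))).p
            for s in range(300)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.001


class TestWeightedMedian:
    def test_constant_ratio_recovered(self):
        iv = _iv([0.1, 0.2, 0.3], 0.01, [0.02, 0.04, 0.06], 0.01)
        r = weighted_median(iv, n_boot=200, seed=0)
        assert r.estimate == pytest.approx(0.2, abs=1e-12)
        assert r.se > 0

    def test_equal_weights_reduce_to_plain_median(self):
        # equal wald-ratio variances: |b_exp| equal, se_out equal
        iv = _iv([0.1, 0.1, 0.1, 0.1, 0.1], 0.01, [0.01, 0.02, 0.03, 0.05, 0.08], 0.01)
        r = weighted_median(iv, n_boot=10, seed=0)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)

    def test_breakdown_resists_forty_percent_invalid_weight(self):
        # 15 valid instruments at ratio 0.2 and 10 invalid at 0.8 with equal
        # per-SNP weight: exactly 60% of the weight sits on the valid set, so
        # the weighted median must track 0.2
        close = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            b_exp = np.full(25, 0.15) + rng.normal(0, 0.005, 25)
            slope = np.array([0.2] * 15 + [0.8] * 10)
            b_out = slope * 0.15 + rng.normal(0, 0.01, 25)
            iv = _iv(b_exp, 0.005, b_out, 0.01)
            est = weighted_median(iv, n_boot=2, seed=s).estimate
            close += int(abs(est - 0.2) < abs(est - 0.8))
        assert close / 200 >= 0.95

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(_iv([0.1, 0.2], 0.01, [0.02, 0.04], 0.01))


class TestEgger:
    def test_exact_line_recovery(self):
        b_exp = np.array([0.1, 0.2, 0.3, 0.4])
        b_out = 0.1 + 0.3 * b_exp
        r = egger(_iv(b_exp, 0.01, b_out, 0.01))
        assert r.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)
        assert r.q == pytest.approx(0.0, abs=1e-18)

    def test_directional_pleiotropy_recovery(self):
        rng = np.random.default_rng(2)
        n = 100
        b_exp = rng.uniform(0.05, 0.3, n)
        b_out = 0.05 + 0.2 * b_exp + rng.normal(0, 0.01, n)
        r = egger(_iv(b_exp + rng.normal(0, 0.002, n), 0.002, b_out, 0.01))
        assert abs(r.egger_intercept - 0.05) < 0.02
        assert abs(r.estimate - 0.2) < 3 * r.se

    def test_zero_pleiotropy_intercept_p_uniform(self):
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(s)
            b_exp = rng.uniform(0.05, 0.3, 30)
            b_out = 0.2 * b_exp + rng.normal(0, 0.01, 30)
            pvals.append(egger(_iv(b_exp, 0.002, b_out, 0.01)).egger_intercept_p)
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(_iv([0.1, 0.2], 0.01, [0.02, 0.04], 0.01))


class TestFStatAndFdr:
    def test_f_examples(self):
        assert f_statistic(np.array([0.1]), np.array([0.05])) == pytest.approx(4.0)
        assert f_statistic(np.array([0.3, 0.5]), np.array([0.1, 0.1])) == pytest.approx(17.0)

    def test_f_quadratic_scaling(self, rng):
        b = rng.normal(0, 0.1, 10)
        se = rng.uniform(0.01, 0.05, 10)
        assert f_statistic(2 * b, se) == pytest.approx(4 * f_statistic(b, se))

    def test_weak_instrument_flag(self):
        r = wald_ratio(0.1, 0.05, 0.05, 0.01)
        r.f_stat = f_statistic(np.array([0.1]), np.array([0.05]))
        assert r.weak_instruments

    def test_bh_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_matches_stepup_oracle(self, rng):
        p = rng.uniform(0, 1, 40)
        np.testing.assert_allclose(fdr_adjust(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])


class TestEstimateDifference:
    def test_identical_estimates(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        z, p = estimate_difference_z(a, a)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form(self):
        a = wald_ratio(1.0, 0.01, 0.5, 0.1)   # est 0.5, se 0.1
        b = wald_ratio(1.0, 0.01, 0.2, 0.1)   # est 0.2, se 0.1
        z, p = estimate_difference_z(a, b)
        assert z == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-9)
        assert p == pytest.approx(0.0339, abs=2e-3)

    def test_antisymmetry(self):
        a = wald_ratio(1.0, 0.01, 0.5, 0.1)
        b = wald_ratio(1.0, 0.01, 0.2, 0.1)
        z1, p1 = estimate_difference_z(a, b)
        z2, p2 = estimate_difference_z(b, a)
        assert z1 == -z2 and p1 == p2


def _mediation_datasets(step1_effect=0.3, step2_effect=0.5, n_eqtl=5, seed=0):
    """Adiposity -> expression -> disease chain over 100 shared variants."""
    rng = np.random.default_rng(seed)
    n = 100
    variants = make_variants(n)
    se = 0.01
    b_adip = np.zeros(n)
    b_adip[:30] = rng.uniform(0.08, 0.2, 30) * rng.choice([-1, 1], 30)
    b_expr = step1_effect * b_adip
    b_expr[30:30 + n_eqtl] = rng.uniform(0.1, 0.25, n_eqtl)
    b_dis = step2_effect * b_expr
    mk = lambda b, name: make_region_stats(
        b + rng.normal(0, se, n), se, trait_name=name,
        trait_type=TraitType.quantitative, variants=variants, n=300_000,
    )
    return mk(b_adip, "adiposity"), mk(b_expr, "expression"), mk(b_dis, "disease")


class TestTwoStepMr:
    def test_mediation_chain_recovered(self):
        adip, expr, dis = _mediation_datasets(seed=3)
        report = two_step_mr(adip, {("GENE1", "islet"): expr}, dis, ld=None, steiger=True)
        s1 = report[(report.step == 1) & (report.method == "ivw")].iloc[0]
        s2 = report[(report.step == 2) & (report.method == "ivw")].iloc[0]
        assert abs(s1.estimate - 0.3) < 3 * s1.se
        assert abs(s2.estimate - 0.5) < 3 * s2.se
        assert "fdr_q" in report.columns

    def test_single_eqtl_gene_uses_wald(self):
        adip, expr, dis = _mediation_datasets(n_eqtl=1, seed=4)
        report = two_step_mr(adip, {("GENE1", "islet"): expr}, dis, ld=None)
        s2 = report[report.step == 2]
        assert list(s2.method) == ["wald"]
        assert s2.iloc[0].n_snps == 1

    def test_many_instruments_add_egger_row(self):
        adip, expr, dis = _mediation_datasets(n_eqtl=5, seed=5)
        report = two_step_mr(adip, {("GENE1", "islet"): expr}, dis, ld=None)
        methods = set(report[report.step == 2].method)
        assert {"ivw", "egger"} <= methods

    def test_no_instruments_reported_not_raised(self):
        adip, expr, dis = _mediation_datasets(seed=6)
        null_expr = make_region_stats(
            np.zeros(10) + 1e-6, 0.01, trait_type=TraitType.quantitative,
            variants=make_variants(10, chrom="9"),
        )
        report = two_step_mr(adip, {("GENE2", "islet"): null_expr}, dis, ld=None)
        step2 = report[(report.gene == "GENE2") & (report.step == 2)]
        assert (step2.note == "no valid instruments").all()


class TestMRModel:
    def test_fit_dispatch_and_summary(self):
        iv = InstrumentSet.from_frame(simulate_instruments(n_snps=10, seed=7))
        model = MRModel(iv, n_boot=50)
        res = model.fit("ivw")
        assert "ivw" in res.summary()
        table = model.fit_all()
        assert set(table.method) == {"ivw", "weighted_median", "egger"}

    def test_run_mr_dispatch_by_count(self):
        one = InstrumentSet.from_frame(simulate_instruments(n_snps=1, seed=8))
        assert [r.method for r in run_mr(one)] == ["wald"]
        three = InstrumentSet.from_frame(simulate_instruments(n_snps=3, seed=8))
        assert [r.method for r in run_mr(three, n_boot=10)] == ["ivw", "weighted_median"]
        five = InstrumentSet.from_frame(simulate_instruments(n_snps=5, seed=8))
        assert [r.method for r in run_mr(five, n_boot=10)] == ["ivw", "weighted_median", "egger"]
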