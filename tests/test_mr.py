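"""MR estimators against independent oracles: Wald ratios, IVW, Cochran Q,
MR-Egger, weighted median, leave-one-out, harmonization, filters."""

import numpy as np
import pandas as pd
import pytest

from scoremr.derive import InstrumentVariant
from scoremr.fixtures import consortium_missing_rsids, lead_variant_table, pleiotropy_annotations
from scoremr.mr import (
    HarmonizedInstrument,
    associate_score_binary,
    associate_score_continuous,
    bonferroni,
    cochran_q,
    filter_instruments,
    harmonize,
    ivw,
    leave_one_out,
    mr_egger,
    wald_ratio,
    weighted_median,
)


def H(rsid, bx, by, sy, sx=0.01):
    return HarmonizedInstrument(rsid, bx, sx, by, sy, "A", "kept")


def _random_harmonized(rng, J=5):
    bx = rng.uniform(0.05, 0.3, J)
    by = rng.normal(0, 0.05, J)
    sy = rng.uniform(0.01, 0.05, J)
    return [H(f"rs{j}", bx[j], by[j], sy[j]) for j in range(J)]


class TestWaldRatio:
    def test_arithmetic(self):
        theta, se = wald_ratio(H("a", 0.2, 0.1, 0.05))
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.25)

    def test_null_outcome(self):
        assert wald_ratio(H("a", 0.2, 0.0, 0.05))[0] == 0.0

    def test_zero_bx_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(H("a", 0.0, 0.1, 0.05))

    def test_orientation_invariance(self):
        a = wald_ratio(H("a", 0.2, 0.1, 0.05))
        b = wald_ratio(H("a", -0.2, -0.1, 0.05))
        assert a == pytest.approx(b)


class TestIVW:
    def test_single_instrument_equals_wald(self):
        h = [H("a", 0.2, 0.1, 0.05)]
        res = ivw(h)
        theta, se = wald_ratio(h[0])
        assert res.estimate == pytest.approx(theta)
        assert res.se == pytest.approx(se)

    def test_homogeneous_ratios_exact(self):
        h = [H("a", 0.1, 0.05, 0.02), H("b", 0.2, 0.10, 0.02), H("c", 0.4, 0.20, 0.04)]
        res = ivw(h)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        q, df, p = cochran_q(h, res.estimate)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_equals_no_intercept_wls_slope(self):
        import statsmodels.api as sm

        h = _random_harmonized(np.random.default_rng(61), 8)
        bx, by, sy = (np.array([getattr(x, a) for x in h]) for a in ("bx", "by", "sy"))
        res = ivw(h)
        wls = sm.WLS(by, bx.reshape(-1, 1), weights=1.0 / sy**2).fit()
        assert res.estimate == pytest.approx(wls.params[0], abs=1e-10)

    def test_multiplicative_random_inflates_only(self):
        h = _random_harmonized(np.random.default_rng(63), 8)
        assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw([])

    def test_unit_change_equivariance(self):
        h = _random_harmonized(np.random.default_rng(65), 6)
        c = 2.5
        scaled = [H(x.rsid, c * x.bx, x.by, x.sy, c * x.sx) for x in h]
        assert ivw(scaled).estimate == pytest.approx(ivw(h).estimate / c)
        assert mr_egger(scaled)[0].estimate == pytest.approx(mr_egger(h)[0].estimate / c)
        wm_a = weighted_median(h, n_boot=100, seed=1).estimate
        wm_b = weighted_median(scaled, n_boot=100, seed=1).estimate
        assert wm_b == pytest.approx(wm_a / c)

    def test_null_calibration_coverage(self):
        """95% CI coverage of the zero causal effect with 34 instruments."""
        rng = np.random.default_rng(67)
        bx_true = rng.uniform(0.08, 0.12, 34) * np.where(rng.random(34) < 0.5, -1, 1)
        cover = 0
        reps = 1000
        for _ in range(reps):
            bx = rng.normal(bx_true, 0.007)
            by = rng.normal(0.0, 0.02, 34)
            res = ivw([H(f"rs{j}", bx[j], by[j], 0.02, 0.007) for j in range(34)])
            lo, hi = res.ci95
            cover += int(lo <= 0.0 <= hi)
        assert abs(cover / reps - 0.95) < 0.02


class TestCochranQ:
    def test_brute_force_arithmetic(self):
        h = [H("a", 0.1, 0.08, 0.03), H("b", 0.2, 0.05, 0.02), H("c", 0.15, 0.12, 0.04),
             H("d", 0.3, 0.2, 0.05)]
        res = ivw(h)
        q, df, p = cochran_q(h, res.estimate)
        w = np.array([x.bx**2 / x.sy**2 for x in h])
        theta = np.array([x.by / x.bx for x in h])
        q_ref = float(np.sum(w * (theta - res.estimate) ** 2))
        assert q == pytest.approx(q_ref, abs=1e-10)
        assert df == 3

    def test_null_q_pvalues_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(69)
        bx = rng.uniform(0.08, 0.12, 34)
        ps = []
        for _ in range(1000):
            by = 0.3 * bx + rng.normal(0, 0.02, 34)
            h = [H(f"rs{j}", bx[j], by[j], 0.02) for j in range(34)]
            ps.append(cochran_q(h)[2])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestEgger:
    def test_exact_proportionality(self):
        rng = np.random.default_rng(71)
        bx = rng.uniform(0.05, 0.3, 6)
        h = [H(f"rs{j}", bx[j], 0.4 * bx[j], 0.02) for j in range(6)]
        res, (icpt, _, _) = mr_egger(h)
        assert res.estimate == pytest.approx(0.4, abs=1e-10)
        assert icpt == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self):
        h = [H("a", 0.1, 0.08, 0.03), H("b", 0.2, 0.05, 0.02), H("c", 0.15, 0.12, 0.04),
             H("d", 0.3, 0.2, 0.05), H("e", 0.25, 0.1, 0.03)]
        res, (icpt, _, _) = mr_egger(h)
        bx = np.array([x.bx for x in h])
        by = np.array([x.by for x in h])
        w = np.diag([1 / x.sy**2 for x in h])
        X = np.column_stack([np.ones(5), bx])
        coef = np.linalg.solve(X.T @ w @ X, X.T @ w @ by)
        assert icpt == pytest.approx(coef[0], abs=1e-10)
        assert res.estimate == pytest.approx(coef[1], abs=1e-10)

    def test_singular_design_raises(self):
        h = [H(f"rs{j}", 0.2, 0.1, 0.02) for j in range(4)]
        with pytest.raises(np.linalg.LinAlgError):
            mr_egger(h)

    def test_orientation_flip_applied(self):
        rng = np.random.default_rng(73)
        bx = rng.uniform(0.05, 0.3, 6)
        h_pos = [H(f"rs{j}", bx[j], 0.4 * bx[j] + 0.01, 0.02) for j in range(6)]
        h_mix = [
            H(f"rs{j}", -bx[j] if j % 2 else bx[j], -(0.4 * bx[j] + 0.01) if j % 2 else 0.4 * bx[j] + 0.01, 0.02)
            for j in range(6)
        ]
        assert mr_egger(h_mix)[0].estimate == pytest.approx(mr_egger(h_pos)[0].estimate, abs=1e-10)


class TestWeightedMedian:
    def test_middle_of_three_equal_weights(self):
        h = [H("a", 0.1, 0.01, 0.05), H("b", 0.1, 0.05, 0.05), H("c", 0.1, 0.09, 0.05)]
        res = weighted_median(h, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.5)

    def test_matches_interpolation_formula(self):
        h = [H("a", 0.1, 0.02, 0.02), H("b", 0.15, 0.09, 0.03), H("c", 0.2, 0.05, 0.04),
             H("d", 0.25, 0.2, 0.05), H("e", 0.3, 0.12, 0.02)]
        res = weighted_median(h, n_boot=50, seed=0)
        theta = np.array([x.by / x.bx for x in h])
        w = np.array([x.bx**2 / x.sy**2 for x in h])
        order = np.argsort(theta)
        th, wn = theta[order], w[order] / w.sum()
        pq = np.cumsum(wn) - wn / 2
        k = np.searchsorted(pq, 0.5, side="right") - 1
        expected = th[k] + (th[k + 1] - th[k]) * (0.5 - pq[k]) / (pq[k + 1] - pq[k])
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_seeded(self):
        h = _random_harmonized(np.random.default_rng(75), 6)
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert a.se == b.se


class TestLeaveOneOut:
    def test_two_instruments_give_walds(self):
        h = [H("a", 0.1, 0.03, 0.02), H("b", 0.2, 0.12, 0.03)]
        tab = leave_one_out(h)
        assert tab.loc[tab.excluded_rsid == "a", "estimate"].iloc[0] == pytest.approx(
            wald_ratio(h[1])[0]
        )
        assert tab.loc[tab.excluded_rsid == "b", "estimate"].iloc[0] == pytest.approx(
            wald_ratio(h[0])[0]
        )

    def test_homogeneous_identical(self):
        h = [H(f"rs{j}", 0.1 * (j + 1), 0.05 * (j + 1), 0.02) for j in range(4)]
        tab = leave_one_out(h)
        assert np.allclose(tab["estimate"], 0.5)

    def test_outlier_exclusion_moves_estimate_most(self):
        rng = np.random.default_rng(77)
        bx = rng.uniform(0.1, 0.3, 8)
        h = [H(f"rs{j}", bx[j], 0.2 * bx[j], 0.02) for j in range(7)]
        h.append(H("rs_outlier", bx[7], 0.2 * bx[7] + 0.3, 0.02))
        tab = leave_one_out(h)
        dist = np.abs(tab["estimate"] - 0.2)
        assert tab.loc[dist.idxmin(), "excluded_rsid"] == "rs_outlier"


def _outcome_stats_for(instruments, missing=(), beta=0.01):
    rows = []
    for v in instruments:
        if v.rsid in missing:
            continue
        rows.append(
            {
                "chromosome": v.chrom, "base_pair_location": v.pos, "rsid": v.rsid,
                "effect_allele": v.effect_allele, "other_allele": v.other_allele,
                "effect_allele_frequency": v.eaf, "beta": beta, "standard_error": 0.02,
                "p_value": 0.5, "n": 10_000,
            }
        )
    return pd.DataFrame(rows)


def _fixture_instruments():
    return [
        InstrumentVariant(v.rsid, v.chrom, v.pos, v.effect_allele, v.other_allele,
                          v.eaf, v.beta_exposure, 0.01, 1e-8, 19_195, v.beta_exposure,
                          is_cis=v.is_cis)
        for v in lead_variant_table()
    ]


class TestHarmonize:
    def test_identical_coding_all_kept(self):
        instr = _fixture_instruments()
        kept, dropped = harmonize(instr, _outcome_stats_for(instr))
        assert len(kept) == 34 and not dropped
        assert all(h.action_taken == "kept" for h in kept)

    def test_consortium_coverage_30_and_29(self):
        instr = _fixture_instruments()
        missing4 = consortium_missing_rsids()["ischemic_stroke"]
        kept, dropped = harmonize(instr, _outcome_stats_for(instr, missing4))
        assert len(kept) == 30 and len(dropped) == 4
        missing5 = consortium_missing_rsids()["heart_failure"]
        kept, dropped = harmonize(instr, _outcome_stats_for(instr, missing5))
        assert len(kept) == 29 and len(dropped) == 5
        assert all(a == "dropped_missing" for _, a in dropped)

    def test_swapped_alleles_flip_sign(self):
        instr = _fixture_instruments()[:1]
        stats = _outcome_stats_for(instr, beta=0.05)
        stats.loc[0, ["effect_allele", "other_allele"]] = [
            instr[0].other_allele, instr[0].effect_allele
        ]
        kept, _ = harmonize(instr, stats)
        assert kept[0].action_taken == "sign_flipped"
        assert kept[0].by == pytest.approx(-0.05)

    def test_strand_complement_resolved(self):
        instr = _fixture_instruments()[:1]  # A/G variant
        stats = _outcome_stats_for(instr, beta=0.05)
        stats.loc[0, ["effect_allele", "other_allele"]] = ["T", "C"]  # complement of A/G
        kept, _ = harmonize(instr, stats)
        assert kept[0].action_taken == "kept" and kept[0].by == pytest.approx(0.05)

    def _palindromic_instr(self, eaf=0.2):
        return [InstrumentVariant("rs_p", "1", 100, "A", "T", eaf, 0.1, 0.01, 1e-8, 100, 0.1)]

    def test_palindromic_drop_policy(self):
        instr = self._palindromic_instr()
        kept, dropped = harmonize(instr, _outcome_stats_for(instr), "drop")
        assert not kept and dropped == [("rs_p", "dropped_palindromic")]

    def test_palindromic_frequency_align(self):
        instr = self._palindromic_instr(eaf=0.2)
        stats = _outcome_stats_for(instr, beta=0.05)
        stats.loc[0, "effect_allele_frequency"] = 0.8  # opposite strand orientation
        kept, _ = harmonize(instr, stats, "frequency_align")
        assert kept[0].action_taken == "sign_flipped" and kept[0].by == pytest.approx(-0.05)

    def test_palindromic_ambiguous_band_dropped(self):
        instr = self._palindromic_instr(eaf=0.5)
        kept, dropped = harmonize(instr, _outcome_stats_for(instr), "frequency_align")
        assert not kept and dropped[0][1] == "dropped_palindromic"

    def test_duplicate_rsid_rejected(self):
        instr = _fixture_instruments()[:1] * 2
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(instr, _outcome_stats_for(instr[:1]))

    def test_irreconcilable_alleles_raise(self):
        instr = _fixture_instruments()[:1]  # A/G
        stats = _outcome_stats_for(instr)
        stats.loc[0, ["effect_allele", "other_allele"]] = ["A", "C"]
        with pytest.raises(ValueError, match="irreconcilable"):
            harmonize(instr, stats)


class TestFilters:
    def test_pleiotropy_exclusion_keeps_30(self):
        from scoremr.derive import annotate_pleiotropy

        instr = annotate_pleiotropy(_fixture_instruments(), pleiotropy_annotations())
        assert len(filter_instruments(instr, "pleiotropy_flagged")) == 30

    def test_cis_only_keeps_2(self):
        kept = filter_instruments(_fixture_instruments(), "non_cis")
        assert sorted(v.rsid for v in kept) == ["rs6489536", "rs7955866"]

    def test_no_flags_identity(self):
        instr = _fixture_instruments()
        assert filter_instruments(instr, "pleiotropy_flagged") == instr
        assert filter_instruments(instr, "non_lead") == instr

    def test_empty_result_rejected(self):
        instr = [v for v in _fixture_instruments() if not v.is_cis]
        with pytest.raises(ValueError):
            filter_instruments(instr, "non_cis")


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(1.0, 7, 1.0), (0.002, 7, 0.014), (0.2, 7, 1.0)])
    def test_arithmetic_and_cap(self, p, m, expected):
        assert bonferroni(np.array([p]), m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.2]), 7)


class TestScoreAssociations:
    def test_two_by_two_cross_product_oracle(self):
        x = np.concatenate([np.ones(100), np.zeros(100)])
        y = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
        res = associate_score_binary(y, x)
        assert res.odds_ratio == pytest.approx((20 * 90) / (80 * 10), abs=1e-4)

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            associate_score_binary(np.zeros(50), np.random.default_rng(0).standard_normal(50))

    def test_continuous_null(self):
        rng = np.random.default_rng(79)
        res = associate_score_continuous(rng.standard_normal(500), rng.standard_normal(500))
        assert abs(res.estimate) < 3 * res.se

    def test_continuous_deterministic(self):
        x = np.random.default_rng(81).standard_normal(100)
        res = associate_score_continuous(5.0 * x, x)
        assert res.estimate == pytest.approx(5.0, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-6)
        assert "degenerate" in res.scaling_note


class TestOneSampleTwoSampleConsistency:
    def test_agreement_on_disjoint_halves(self):
        """Score-based one-sample estimate and summary-data IVW agree within
        two combined SEs on non-overlapping halves of one population."""
        from scoremr.cohort import make_summary_stats, simulate_cohort
        from scoremr.fixtures import calibrated_config

        log_or = float(np.log(1.4))
        c1 = simulate_cohort(calibrated_config(seed=830, n=40_000, causal_log_or=log_or))
        c2 = simulate_cohort(calibrated_config(seed=831, n=40_000, causal_log_or=log_or))
        # one-sample in half 1: IV estimate = score coef / first-stage slope
        raw = c1.dosages @ c1.truth["per_allele_effects"]
        s = (raw - raw.mean()) / raw.std()
        one = associate_score_binary(c1.outcomes["disease"], s)
        slope = np.polyfit(s, c1.exposure_true, 1)[0]
        est1, se1 = one.estimate / slope, one.se / slope
        # two-sample: exposure stats from half 1, outcome stats from half 2
        xstats = make_summary_stats(c1, "exposure")
        ystats = make_summary_stats(c2, "disease")
        instr = [
            InstrumentVariant(r.rsid, r.chromosome, r.base_pair_location, r.effect_allele,
                              r.other_allele, r.effect_allele_frequency, r.beta,
                              r.standard_error, r.p_value, int(r.n), r.beta)
            for r in xstats.itertuples()
        ]
        kept, _ = harmonize(instr, ystats)
        two = ivw(kept)
        assert abs(est1 - two.estimate) < 2 * np.hypot(se1, two.se)
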