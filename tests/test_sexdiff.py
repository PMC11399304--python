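import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sexstrat.panel import FEMALE, MALE
from sexstrat.sexdiff import (
    DegenerateInputError,
    correlate_maps,
    fit_vg_vp_models,
    mtc_threshold,
    paired_region_tests,
    phenotypic_sexdiff,
    round_to_sig,
    screen_snp_sexdiff,
    trunc_to_sig,
    zdiff,
)


class TestZdiff:
    def test_equal_estimates(self):
        z, p = zdiff(0.3, 0.3, 0.1, 0.1)
        assert z == 0.0 and p == 1.0

    def test_hand_case(self):
        z, p = zdiff(0.30, 0.20, 0.05, 0.05)
        assert z == pytest.approx(0.1 / np.sqrt(0.005), rel=1e-9)
        assert z == pytest.approx(1.41421, abs=1e-5)
        assert p == pytest.approx(0.15730, abs=1e-5)

    def test_swap_symmetry(self):
        z1, p1 = zdiff(0.4, 0.1, 0.05, 0.08)
        z2, p2 = zdiff(0.1, 0.4, 0.08, 0.05)
        assert z1 == pytest.approx(-z2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            zdiff(0.1, 0.2, 0.0, 0.1)

    @given(
        st.floats(-5, 5), st.floats(-5, 5),
        st.floats(0.01, 2), st.floats(0.01, 2),
    )
    def test_p_in_range(self, a, b, sa, sb):
        z, p = zdiff(a, b, sa, sb)
        assert 0 <= p <= 1

    def test_monotone_in_difference(self):
        # p decreases as |est_m - est_f| grows at fixed SEs
        ps = [zdiff(0.1 * k, 0.0, 0.05, 0.05)[1] for k in range(6)]
        assert all(ps[i + 1] < ps[i] for i in range(5))


class TestMtcThreshold:
    def test_cortical_h2_threshold(self):
        assert round_to_sig(mtc_threshold(0.05, 360), 2) == pytest.approx(1.4e-4)

    def test_strict_cortical_threshold(self):
        assert round_to_sig(mtc_threshold(5e-8, 361), 2) == pytest.approx(1.4e-10)

    def test_strict_subcortical_threshold(self):
        assert round_to_sig(mtc_threshold(5e-8, 23), 3) == pytest.approx(2.17e-9)

    def test_subcortical_h2_threshold(self):
        assert trunc_to_sig(mtc_threshold(0.05, 23), 2) == pytest.approx(0.0021)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mtc_threshold(0.05, 0)


class TestPairedRegionTests:
    def test_hand_case(self):
        # differences (0.1, 0.2, 0.3, 0.2, 0.2): mean 0.2, t = 6.3246, df = 4
        m = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        f = np.zeros(5)
        res = paired_region_tests(m, f)
        assert res.mean_diff == pytest.approx(0.2)
        assert res.t == pytest.approx(6.3246, abs=1e-4)
        assert res.df == 4
        assert res.ci_low < 0.2 < res.ci_high

    def test_directionality(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal(100)
        f = m + 0.02 + rng.standard_normal(100) * 0.001
        res = paired_region_tests(m, f)
        assert res.t < 0

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_region_tests(np.ones(5), np.ones(5))

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal(40)
        f = rng.standard_normal(40)
        res = paired_region_tests(m, f)
        ref = stats.ttest_rel(m, f)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


class TestPhenotypicSexdiff:
    def _data(self, n, gap, seed):
        rng = np.random.default_rng(seed)
        sex = np.array([MALE, FEMALE] * (n // 2))
        age = rng.uniform(45, 80, n)
        y = rng.standard_normal(n) + gap * (sex == MALE)
        return y, sex, age

    def test_coefficient_matches_normal_equations(self):
        y, sex, age = self._data(200, 0.5, 2)
        res = phenotypic_sexdiff(y, sex, age)
        X = np.column_stack([np.ones(200), (sex == MALE).astype(float), age, age**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.coef == pytest.approx(beta[1], abs=1e-10)

    def test_direction_positive_when_male_higher(self):
        for seed in range(20):
            y, sex, age = self._data(4000, 1.0, seed)
            assert phenotypic_sexdiff(y, sex, age).t > 0

    def test_null_calibration(self):
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            y, sex, age = self._data(200, 0.0, seed)
            hits += abs(phenotypic_sexdiff(y, sex, age).t) > 1.96
        frac = hits / n_rep
        assert abs(frac - 0.05) <= 2 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01


class TestVgVpModels:
    def _table(self, vp, vg_m, vg_f):
        return pd.DataFrame(
            {
                "sex": [MALE] * len(vp) + [FEMALE] * len(vp),
                "v_p": np.concatenate([vp, vp]),
                "v_g": np.concatenate([vg_m, vg_f]),
            }
        )

    def test_no_sex_difference(self):
        vp = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = self._table(vp, 0.5 * vp, 0.5 * vp)
        fit = fit_vg_vp_models(table)
        assert fit.d.coef == pytest.approx(0.0, abs=1e-10)
        assert fit.f.coef == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_slope_difference(self):
        # male V_G = 0.6 V_P, female V_G = 0.4 V_P -> model 2, d = +0.2
        vp = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = self._table(vp, 0.6 * vp, 0.4 * vp)
        fit = fit_vg_vp_models(table)
        assert fit.model == "model2"
        assert fit.d.coef == pytest.approx(0.2, abs=1e-9)

    def test_nesting_rss(self):
        rng = np.random.default_rng(3)
        vp = rng.uniform(1, 5, 30)
        table = self._table(vp, 0.5 * vp + rng.normal(0, 0.1, 30),
                            0.4 * vp + rng.normal(0, 0.1, 30))
        fit = fit_vg_vp_models(table)
        assert fit.rss_model1 <= fit.rss_model2 + 1e-12

    def test_quadratic_triggers_model1(self):
        rng = np.random.default_rng(4)
        vp = np.linspace(1, 5, 40)
        vg_m = 0.3 * vp + 0.2 * vp**2 + rng.normal(0, 0.01, 40)
        vg_f = 0.3 * vp + rng.normal(0, 0.01, 40)
        fit = fit_vg_vp_models(self._table(vp, vg_m, vg_f))
        assert fit.model == "model1"
        assert fit.f.p < 0.05


class TestStrictTierNullScreen:
    def test_360_region_null_h2_screen_has_no_hits(self):
        # null 360-region panel: identical true h2 in both sexes, estimates
        # perturbed at their SEs — nothing survives the strict tier
        rng = np.random.default_rng(20)
        true_h2 = rng.uniform(0.1, 0.5, 360)
        se = np.full(360, 0.05)
        est_m = true_h2 + rng.standard_normal(360) * se
        est_f = true_h2 + rng.standard_normal(360) * se
        z, p = zdiff(est_m, est_f, se, se)
        strict = mtc_threshold(5e-8, 361)
        assert (p >= strict).all()
        # the per-region MTC level sees at most chance-level leakage
        assert (p < mtc_threshold(0.05, 360)).sum() <= 1


class TestCorrelateMaps:
    def test_identity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_maps(a, a)[0] == pytest.approx(1.0)
        assert correlate_maps(a, -a)[0] == pytest.approx(-1.0)

    def test_hand_case(self):
        r, _ = correlate_maps([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, rel=1e-12)

    def test_zero_variance(self):
        with pytest.raises(DegenerateInputError):
            correlate_maps([1, 1, 1], [1, 2, 3])


def _records(ids, betas, ses, a1="A", ref="G"):
    return pd.DataFrame(
        {
            "ID": ids,
            "A1": [a1] * len(ids),
            "REF": [ref] * len(ids),
            "BETA": betas,
            "SE": ses,
        }
    )


class TestScreenSnpSexdiff:
    def test_identical_records_all_null(self):
        ids = [f"v{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        betas = rng.standard_normal(10)
        rm = _records(ids, betas, np.full(10, 0.1))
        rep = screen_snp_sexdiff(rm, rm.copy(), strict_n_tests=361)
        assert np.allclose(rep.records["Z"], 0.0)
        assert (rep.records["TIER"] == "none").all()

    def test_allele_flip_harmonized(self):
        ids = ["v0"]
        rm = _records(ids, [0.3], [0.1], a1="A", ref="G")
        rf_same = _records(ids, [0.3], [0.1], a1="A", ref="G")
        rf_flip = _records(ids, [-0.3], [0.1], a1="G", ref="A")
        z_same = screen_snp_sexdiff(rm, rf_same, 361).records["Z"].iloc[0]
        z_flip = screen_snp_sexdiff(rm, rf_flip, 361).records["Z"].iloc[0]
        assert z_same == pytest.approx(z_flip, rel=1e-12)

    def test_mismatch_excluded_and_counted(self):
        rm = _records(["v0", "v1"], [0.3, 0.2], [0.1, 0.1], a1="A", ref="G")
        rf = pd.DataFrame(
            {
                "ID": ["v0", "v1"],
                "A1": ["A", "T"],  # v1 alleles irreconcilable
                "REF": ["G", "C"],
                "BETA": [0.3, 0.2],
                "SE": [0.1, 0.1],
            }
        )
        rep = screen_snp_sexdiff(rm, rf, 361)
        assert rep.n_allele_mismatch == 1
        assert list(rep.records["ID"]) == ["v0"]

    def test_one_sex_only_counted(self):
        rm = _records(["v0", "v1"], [0.1, 0.2], [0.1, 0.1])
        rf = _records(["v0"], [0.1], [0.1])
        rep = screen_snp_sexdiff(rm, rf, 361)
        assert rep.n_only_one_sex == 1

    def test_tiers(self):
        # z ~ 5.9 passes relaxed only; z ~ 12 passes strict for n_tests = 361
        rm = _records(["a", "b", "c"], [0.58, 1.2, 0.01], [0.07, 0.07, 0.07])
        rf = _records(["a", "b", "c"], [0.0, 0.0, 0.0], [0.07, 0.07, 0.07])
        rep = screen_snp_sexdiff(rm, rf, strict_n_tests=361)
        tiers = dict(zip(rep.records["ID"], rep.records["TIER"]))
        assert tiers["a"] == "relaxed"
        assert tiers["b"] == "strict"
        assert tiers["c"] == "none"
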