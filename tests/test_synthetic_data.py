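import numpy as np
import pandas as pd
import pytest

from sexstrat.panel import FEMALE, MALE
from sexstrat.synthetic_data import (
    ArchitectureSpec,
    InvalidConfigError,
    SimulationConfig,
    inject_sexdiff_snp,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_region_panel,
)


class TestSimulateGenotypes:
    def test_female_only_panel_values(self):
        cfg = SimulationConfig(
            n_male=0, n_female=10, m_auto=5, maf_low=0.5, maf_high=0.5,
            missing_rate=0.0, seed=1,
        )
        panel = simulate_genotypes(cfg)
        assert panel.dosages.shape == (10, 5)
        assert not panel.is_male.any()
        assert not np.isnan(panel.dosages).any()
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}

    def test_male_x_binomial_mean(self):
        # binomial sampling oracle: per-variant male-X mean ~ p +/- 3 sd
        cfg = SimulationConfig(
            n_male=1000, n_female=0, m_auto=0, m_x=100,
            maf_low=0.3, maf_high=0.3, seed=7,
        )
        panel = simulate_genotypes(cfg)
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0}
        means = panel.dosages.mean(axis=0)
        tol = 3 * np.sqrt(0.3 * 0.7 / 1000)
        assert np.all(np.abs(means - 0.3) <= tol)

    def test_missing_rate_binomial(self):
        cfg = SimulationConfig(
            n_male=500, n_female=500, m_auto=1000, missing_rate=0.1, seed=3
        )
        panel = simulate_genotypes(cfg)
        frac = np.isnan(panel.dosages).mean()
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 1e6)

    def test_determinism(self):
        cfg = SimulationConfig(n_male=20, n_female=20, m_auto=50, m_x=10, seed=9)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.sex, b.sex)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_male=0, n_female=0, m_auto=5),
            dict(n_male=5, n_female=5, m_auto=0, m_x=0),
            dict(n_male=5, n_female=5, m_auto=5, maf_low=0.0),
            dict(n_male=5, n_female=5, m_auto=5, missing_rate=1.0),
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(InvalidConfigError):
            simulate_genotypes(SimulationConfig(**{"seed": 1, **kwargs}))


class TestSimulatePhenotypes:
    def test_zero_h2_no_genetic_signal(self, mixed_panel):
        arch = ArchitectureSpec(h2_male=0.0, h2_female=0.0, n_causal=50, noise_sd=0.0)
        pheno, truth = simulate_phenotypes(mixed_panel, arch, seed=1)
        assert truth.scale_male == 0.0 and truth.scale_female == 0.0
        np.testing.assert_allclose(pheno["pheno"].to_numpy(), 0.0)

    def test_rg_one_effects_proportional(self, mixed_panel):
        arch = ArchitectureSpec(h2_male=0.4, h2_female=0.4, rg=1.0, n_causal=80)
        _, truth = simulate_phenotypes(mixed_panel, arch, seed=2)
        np.testing.assert_allclose(truth.beta_male, truth.beta_female)

    def test_rg_half_effect_correlation(self):
        # bivariate-normal sampling oracle on the drawn effect pairs
        panel = simulate_genotypes(
            SimulationConfig(n_male=50, n_female=50, m_auto=600, seed=11)
        )
        arch = ArchitectureSpec(h2_male=0.3, h2_female=0.3, rg=0.5, n_causal=500)
        _, truth = simulate_phenotypes(panel, arch, seed=3)
        r = np.corrcoef(truth.beta_male, truth.beta_female)[0, 1]
        assert abs(r - 0.5) <= 2 * (1 - 0.25) / np.sqrt(500)

    def test_mean_sex_gap_and_covariates(self, mixed_panel):
        arch = ArchitectureSpec(
            h2_male=0.0, h2_female=0.0, noise_sd=0.0, mean_sex_gap=2.5,
            covariate_effects=(("age", 0.0),), n_causal=10,
        )
        pheno, _ = simulate_phenotypes(mixed_panel, arch, seed=4)
        male = pheno["sex"].to_numpy() == MALE
        assert np.allclose(pheno.loc[male, "pheno"], 2.5)
        assert np.allclose(pheno.loc[~male, "pheno"], 0.0)
        assert "age" in pheno.columns

    def test_achieved_heritability_tolerance(self):
        # realized genetic-variance fraction within +/- 0.02 of target
        panel = simulate_genotypes(
            SimulationConfig(n_male=1200, n_female=1200, m_auto=500, seed=5)
        )
        arch = ArchitectureSpec(h2_male=0.4, h2_female=0.4, rg=1.0, n_causal=200)
        pheno, truth = simulate_phenotypes(panel, arch, seed=6)
        from sexstrat.synthetic_data import _standardized_dosages
        from sexstrat.grm import DcModel

        Z = _standardized_dosages(panel, DcModel.FDC)[:, truth.causal_indices]
        y = pheno["pheno"].to_numpy()
        for sex_code, beta, scale in (
            (MALE, truth.beta_male, truth.scale_male),
            (FEMALE, truth.beta_female, truth.scale_female),
        ):
            grp = panel.sex == sex_code
            g = (Z[grp] @ beta) * scale
            frac = g.var() / y[grp].var()
            assert abs(frac - 0.4) <= 0.02

    def test_h2_one_with_noise_rejected(self, mixed_panel):
        with pytest.raises(InvalidConfigError):
            simulate_phenotypes(
                mixed_panel, ArchitectureSpec(h2_male=1.0, h2_female=0.4, n_causal=10),
                seed=1,
            )

    def test_determinism(self, mixed_panel):
        arch = ArchitectureSpec(h2_male=0.3, h2_female=0.5, rg=0.8, n_causal=60)
        a, _ = simulate_phenotypes(mixed_panel, arch, seed=10)
        b, _ = simulate_phenotypes(mixed_panel, arch, seed=10)
        pd.testing.assert_frame_equal(a, b)


class TestInjectSexdiffSnp:
    def test_zero_betas_noop(self, mixed_panel):
        arch = ArchitectureSpec(h2_male=0.2, h2_female=0.2, n_causal=20)
        pheno, truth = simulate_phenotypes(mixed_panel, arch, seed=1)
        out, _ = inject_sexdiff_snp(mixed_panel, pheno, 0, 0.0, 0.0, truth)
        np.testing.assert_allclose(out["pheno"], pheno["pheno"])

    def test_male_only_effect_on_zero_phenotype(self, mixed_panel):
        pheno = pd.DataFrame(
            {"IID": mixed_panel.sample_ids, "sex": mixed_panel.sex,
             "pheno": np.zeros(mixed_panel.n_samples)}
        )
        out, truth = inject_sexdiff_snp(mixed_panel, pheno, 3, 1.0, 0.0)
        male = mixed_panel.is_male
        np.testing.assert_allclose(
            out.loc[male, "pheno"], mixed_panel.dosages[male, 3]
        )
        np.testing.assert_allclose(out.loc[~male, "pheno"], 0.0)
        assert truth.injected[0]["variant_index"] == 3

    def test_monomorphic_warning(self, mixed_panel):
        dosages = mixed_panel.dosages.copy()
        dosages[:, 0] = 0.0
        from tests.conftest import make_panel

        panel = make_panel(dosages, mixed_panel.sex,
                           mixed_panel.variants["chrom"].to_numpy())
        pheno = pd.DataFrame(
            {"IID": panel.sample_ids, "sex": panel.sex,
             "pheno": np.zeros(panel.n_samples)}
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            _, truth = inject_sexdiff_snp(panel, pheno, 0, 0.5, 0.0)
        assert truth.warnings


class TestRegionPanel:
    def test_centroids_and_labels(self):
        phenos, annot = simulate_region_panel(40, 5, 0.3, seed=1)
        norms = np.linalg.norm(annot[["x", "y", "z"]].to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert annot["network"].value_counts().sum() == 40
        assert set(annot["network"]) <= set(range(1, 6))
        assert len(phenos) == 40

    def test_mirrored_hemispheres(self):
        _, annot = simulate_region_panel(40, 3, 0.3, seed=2)
        left = annot[annot.hemi == "L"][["x", "y", "z"]].to_numpy()
        right = annot[annot.hemi == "R"][["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(right, left[: len(right)] * [-1, 1, 1])

    def test_invalid(self):
        with pytest.raises(InvalidConfigError):
            simulate_region_panel(3, 5, 0.3, seed=1)

    def test_downstream_reml_recovers_profile(self):
        # constant h2 profile 0.3: mean REML estimate across 20 regions
        # within 2 SE of the mean
        from sexstrat.grm import autosomal_grm
        from sexstrat.reml import fit_reml
        from sexstrat.synthetic_data import SimulationConfig, simulate_genotypes

        panel = simulate_genotypes(
            SimulationConfig(n_male=300, n_female=300, m_auto=800, seed=17)
        )
        phenos, _ = simulate_region_panel(
            20, 3, 0.3, seed=18, panel=panel, arch_kwargs={"n_causal": 300}
        )
        g = autosomal_grm(panel)
        h2s = [
            fit_reml(tab["pheno"].to_numpy(), None, [g], method="eigen").h2_total
            for tab in phenos
        ]
        se_mean = np.std(h2s, ddof=1) / np.sqrt(len(h2s))
        assert abs(np.mean(h2s) - 0.3) <= 2 * se_mean + 0.02
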