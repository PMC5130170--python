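"""Noise regimes: log-normal sampling, covariation, ensembles, attribution."""

import numpy as np
import pandas as pd
import pytest

from erknoise.noise import (
    NoiseConfig,
    classify_sensitivity_types,
    run_ensemble,
    run_ensemble_multidose,
    sample_initials,
)


class TestNoiseConfig:
    @pytest.mark.parametrize(
        "kwargs, regime",
        [
            ({}, "none"),
            ({"intrinsic": True}, "intrinsic"),
            ({"extrinsic_cv": 0.3}, "extrinsic"),
            ({"intrinsic": True, "extrinsic_cv": 0.3}, "both"),
            ({"per_species_cv": {"ERK": 0.25}}, "extrinsic"),
        ],
    )
    def test_regime_derived_from_flags(self, kwargs, regime, egf_network):
        cfg = NoiseConfig(n_cells=2, **kwargs)
        assert cfg.regime == regime

    def test_invalid_cv_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(extrinsic_cv=-0.1)
        with pytest.raises(ValueError):
            NoiseConfig(extrinsic_cv=3.5)

    def test_unknown_protein_group_rejected(self, egf_network):
        cfg = NoiseConfig(per_species_cv={"NotAProtein": 0.2}, n_cells=2)
        with pytest.raises(KeyError):
            cfg.group_cvs(egf_network)


class TestSampler:
    def test_zero_cv_returns_nominal(self, egf_network):
        cfg = NoiseConfig(extrinsic_cv=0.0, n_cells=10)
        out = sample_initials(egf_network, cfg, np.random.default_rng(0))
        assert np.array_equal(out, np.tile(egf_network.initial_state(), (10, 1)))

    def test_moment_matched_lognormal(self, egf_network):
        """cv=0.25, n=5000: per-species mean within 1% of nominal and sample
        CV within one point of the target."""
        cfg = NoiseConfig(extrinsic_cv=0.25, n_cells=5000, master_seed=0)
        out = sample_initials(egf_network, cfg, np.random.default_rng(42))
        nominal = egf_network.initial_state()
        n = cfg.n_cells
        for prot, members in egf_network.protein_groups.items():
            for sid in members:
                i = egf_network.species_index(sid)
                col = out[:, i]
                # 4-SE Monte-Carlo band (~20 species checked on one draw)
                tol = max(0.01 * nominal[i], 4.0 * col.std(ddof=1) / np.sqrt(n))
                assert abs(col.mean() - nominal[i]) < tol
                cv = col.std(ddof=1) / col.mean()
                assert 0.235 <= cv <= 0.265

    def test_full_covariation_correlates_all_proteins(self, egf_network):
        cfg = NoiseConfig(extrinsic_cv=0.25, covariation="full", n_cells=500)
        out = sample_initials(egf_network, cfg, np.random.default_rng(1))
        i = egf_network.species_index("EGFR")
        j = egf_network.species_index("MEK")
        k = egf_network.species_index("Raf")
        assert np.corrcoef(out[:, i], out[:, j])[0, 1] > 0.99
        assert np.corrcoef(out[:, i], out[:, k])[0, 1] > 0.99

    def test_intermediate_rho(self, egf_network):
        cfg = NoiseConfig(extrinsic_cv=0.25, rho=0.5, n_cells=4000)
        out = sample_initials(egf_network, cfg, np.random.default_rng(2))
        i = egf_network.species_index("EGFR")
        j = egf_network.species_index("MEK")
        r = np.corrcoef(np.log(out[:, i]), np.log(out[:, j]))[0, 1]
        assert 0.4 < r < 0.6

    def test_zero_nominal_with_cv_warns_and_stays_zero(self, mini_network):
        net = mini_network.with_initial_counts({"R": 0})
        cfg = NoiseConfig(per_species_cv={"R": 0.3}, n_cells=5)
        with pytest.warns(UserWarning, match="nominal count 0"):
            out = sample_initials(net, cfg, np.random.default_rng(0))
        assert np.all(out[:, net.species_index("R")] == 0)


class TestEnsembles:
    def test_no_noise_regime_gives_identical_cells(self, mini_network):
        cfg = NoiseConfig(n_cells=4, master_seed=0)
        res = run_ensemble(mini_network, 1.0, cfg, t_end=400.0)
        assert res.regime == "none"
        assert np.ptp(res.values) == 0.0
        assert res.cv == 0.0

    def test_summary_invariant_to_cell_order(self, mini_network):
        cfg = NoiseConfig(extrinsic_cv=0.2, n_cells=12, master_seed=3)
        res = run_ensemble(mini_network, 1.0, cfg, t_end=400.0)
        shuffled = res.values.copy()
        np.random.default_rng(0).shuffle(shuffled)
        assert np.mean(shuffled) == pytest.approx(res.mean)
        assert np.std(shuffled, ddof=1) / np.mean(shuffled) == pytest.approx(res.cv)

    def test_extrinsic_broader_than_intrinsic_at_high_dose(self, mini_network):
        """Protein variability dominates reaction-timing noise at these
        molecule numbers (the distribution with extrinsic noise is broader)."""
        intr = run_ensemble(
            mini_network, 1.0,
            NoiseConfig(intrinsic=True, n_cells=15, master_seed=1),
            t_end=400.0, ssa_method="direct",
        )
        extr = run_ensemble(
            mini_network, 1.0,
            NoiseConfig(extrinsic_cv=0.30, n_cells=15, master_seed=1),
            t_end=400.0,
        )
        assert extr.cv > 3.0 * intr.cv

    def test_dose_zero_steady_state_fold_change_unaffected_by_covariation(
        self, egf_network
    ):
        """Scaling all proteins by a shared per-cell factor leaves the basal
        nuclear-ERK fold change at exactly 1 (self-normalization)."""
        cfg = NoiseConfig(
            extrinsic_cv=0.25, covariation="full", n_cells=6, master_seed=9
        )
        res = run_ensemble(
            egf_network, 0.0, cfg, t_end=600.0, statistic="endpoint"
        )
        assert np.allclose(res.values, 1.0, atol=1e-5)
        assert res.cv < 1e-5

    def test_covariation_suppresses_high_dose_heterogeneity(self, egf_network):
        """At saturating dose, correlated protein levels produce narrower
        response distributions than independent levels (one-sided check)."""
        cvs = {}
        for cov in ("none", "full"):
            cfg = NoiseConfig(
                extrinsic_cv=0.25, covariation=cov, n_cells=40, master_seed=21
            )
            cvs[cov] = run_ensemble(egf_network, 50.0, cfg, t_end=1800.0).cv
        assert cvs["full"] < cvs["none"]


class TestClassification:
    def test_planted_patterns_recovered(self):
        doses = [0.005, 0.03, 0.06, 0.1, 1.0, 50.0]
        rows = {
            "alpha": [0.00, 0.09, 0.10, 0.08, 0.01, 0.00],   # transition-only
            "beta":  [0.00, 0.08, 0.09, 0.09, 0.00, 0.01],   # transition-only
            "gamma": [0.00, 0.02, 0.04, 0.06, 0.11, 0.12],   # high-dose
            "delta": [0.00, 0.01, 0.01, 0.00, 0.01, 0.00],   # flat
            "eps":   [0.00, 0.00, 0.01, 0.01, 0.00, 0.00],   # flat
        }
        m = pd.DataFrame.from_dict(rows, orient="index", columns=doses)
        types = classify_sensitivity_types(m, ec10=0.02, ec90=0.12)
        assert types == {"alpha": 1, "beta": 1, "gamma": 2, "delta": 3, "eps": 3}

    def test_uncovered_regions_rejected(self):
        m = pd.DataFrame([[0.1, 0.2]], index=["x"], columns=[5.0, 50.0])
        with pytest.raises(ValueError):
            classify_sensitivity_types(m, ec10=0.02, ec90=0.12)
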