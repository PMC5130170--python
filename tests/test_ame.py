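"""Measurement-error model: Gaussian fits, quadrature, application, recovery."""

import numpy as np
import pytest

from erknoise.ame import (
    AMEModel,
    GaussianFit,
    apply_ame,
    estimate_ame,
    fit_gaussian_cv,
    recover_protein_cv,
)
from erknoise.synthetic import fast_surrogate_generator

HILL = {"n": 3.0, "K": 0.05, "R_min": 1.0, "R_max": 2.0}


class TestGaussianFit:
    def test_self_consistency_on_gaussian_samples(self):
        rng = np.random.default_rng(0)
        fit = fit_gaussian_cv(rng.normal(1.0, 0.044, 10_000))
        assert fit.mean == pytest.approx(1.0, abs=0.01)
        assert fit.cv == pytest.approx(0.044, abs=0.003)

    def test_constant_samples_give_zero_cv(self):
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_gaussian_cv(np.full(100, 2.5))
        assert fit.cv == 0.0
        assert fit.mean == 2.5

    def test_curve_fit_close_to_moment_estimates(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 0.3, 5000)
        fit = fit_gaussian_cv(x)
        assert fit.mean == pytest.approx(x.mean(), rel=0.05)
        assert fit.cv == pytest.approx(x.std() / x.mean(), rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_cv(np.ones(10))


class TestEstimateAME:
    def test_equal_widths_give_zero(self):
        f = GaussianFit(mean=1.0, cv=0.02, rss=0.0)
        assert estimate_ame(f, f).cv_ame == 0.0

    def test_zero_simulated_width_gives_observed(self):
        sim = GaussianFit(mean=1.0, cv=0.0, rss=0.0)
        obs = GaussianFit(mean=1.0, cv=0.044, rss=0.0)
        assert estimate_ame(sim, obs).cv_ame == pytest.approx(0.044)

    def test_quadrature_on_basal_widths(self):
        """0.35% simulated, 4.4% observed -> AME approximately 4.386%."""
        sim = GaussianFit(mean=1.0, cv=0.0035, rss=0.0)
        obs = GaussianFit(mean=1.0, cv=0.044, rss=0.0)
        assert estimate_ame(sim, obs).cv_ame == pytest.approx(
            np.sqrt(0.044**2 - 0.0035**2), abs=1e-12
        )
        assert estimate_ame(sim, obs).cv_ame == pytest.approx(0.04386, abs=1e-4)

    def test_overpredicted_basal_noise_rejected(self):
        sim = GaussianFit(mean=1.0, cv=0.06, rss=0.0)
        obs = GaussianFit(mean=1.0, cv=0.044, rss=0.0)
        with pytest.raises(ValueError, match="overpredicts"):
            estimate_ame(sim, obs)


class TestApplyAME:
    def test_zero_ame_is_identity(self):
        x = np.linspace(0.5, 2.0, 100)
        out = apply_ame(x, AMEModel(0.0), np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_variance_adds_in_quadrature(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 0.05, 100_000)
        out = apply_ame(x, AMEModel(0.04), rng)
        cv_out = out.std() / out.mean()
        assert cv_out == pytest.approx(np.sqrt(0.05**2 + 0.04**2), rel=0.02)

    def test_estimate_then_apply_round_trip(self):
        rng = np.random.default_rng(2)
        sim = rng.normal(1.0, 0.0035, 20_000)
        obs = rng.normal(1.0, 0.044, 20_000)
        ame = estimate_ame(fit_gaussian_cv(sim), fit_gaussian_cv(obs))
        noisy = apply_ame(sim, ame, rng)
        assert fit_gaussian_cv(noisy).cv == pytest.approx(0.044, abs=0.004)


class TestAMEDoseDependence:
    def test_ame_matters_where_biological_variability_is_small(self):
        """AME widens the narrow low-dose distribution strongly and the broad
        transition-dose distribution barely (quadrature composition)."""
        rng = np.random.default_rng(3)
        ds = fast_surrogate_generator(
            HILL, basal_cv=0.25, ame_cv=0.0, doses=(0.001, 0.05),
            n_cells=4000, seed=8,
        )
        ame = AMEModel(0.044)
        deltas = {}
        for dose, vals in ds.samples.items():
            cv0 = vals.std() / vals.mean()
            noisy = apply_ame(vals, ame, rng)
            deltas[dose] = abs(noisy.std() / noisy.mean() - cv0)
        assert deltas[0.05] < 0.5 * deltas[0.001]


class TestRecovery:
    def test_rss_profile_matches_independent_resummation(self, egf_network):
        ds = fast_surrogate_generator(HILL, basal_cv=0.2, ame_cv=0.044,
                                      n_cells=300, seed=4)
        res = recover_protein_cv(
            egf_network, ds.samples, cv_grid=[0.1, 0.2], ame=AMEModel(0.044),
            n_cells=15, seed=6,
        )
        observed_cv = np.array(
            [v.std(ddof=1) / v.mean() for _, v in sorted(ds.samples.items())]
        )
        for col, rss in zip(res.cv_grid, res.rss):
            sim_cv = res.cv_curves[col].to_numpy()
            assert rss == pytest.approx(float(np.sum((sim_cv - observed_cv) ** 2)))

    def test_perfect_self_match_recovers_zero_cv(self, egf_network):
        """Noise-free observation with no AME: RSS is minimized at CV 0."""
        from erknoise.synthetic import generate_pseudo_experiment

        ds = generate_pseudo_experiment(
            egf_network, truth_cv=0.0, truth_ame_cv=0.0,
            doses=(0.01, 0.05, 0.1), n_cells=8, seed=12,
        )
        res = recover_protein_cv(
            egf_network, ds.samples, cv_grid=[0.0, 0.15, 0.3],
            ame=AMEModel(0.0), n_cells=12, seed=13,
        )
        assert res.best_cv == 0.0

    def test_out_of_range_grid_rejected(self, egf_network):
        with pytest.raises(ValueError):
            recover_protein_cv(
                egf_network, {0.1: np.ones(5)}, cv_grid=[0.0, 0.7],
            )
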