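"""Hill fitting and effective concentrations: closed forms and oracles."""

import numpy as np
import pytest

from erknoise.doseresponse import (
    DoseResponseCurve,
    HillFit,
    default_dose_grid,
    effective_concentration,
    hill_fit,
)


def hill(d, n, K, rmin, rmax):
    d = np.asarray(d, dtype=float)
    dn = np.power(d, n, where=d > 0, out=np.zeros_like(d))
    return rmin + (rmax - rmin) * dn / (K**n + dn)


def make_curve(n=2.0, K=1.0, rmin=0.0, rmax=10.0, doses=None):
    doses = default_dose_grid(n=20, low=1e-3, high=100.0) if doses is None else doses
    return DoseResponseCurve(
        doses=doses, responses=hill(doses, n, K, rmin, rmax), observable="test"
    )


class TestHillFit:
    @pytest.mark.parametrize("n,K", [(0.8, 0.3), (2.0, 1.0), (4.0, 5.0)])
    def test_exact_recovery_on_noise_free_hill_data(self, n, K):
        fit = hill_fit(make_curve(n=n, K=K, rmin=1.0, rmax=3.0))
        assert fit.n == pytest.approx(n, abs=0.01)
        assert fit.K == pytest.approx(K, rel=0.01)
        assert fit.R_min == pytest.approx(1.0, abs=0.01)
        assert fit.R_max == pytest.approx(3.0, abs=0.01)

    def test_scale_equivariance(self):
        c1 = make_curve(n=1.7, K=0.6, rmin=0.5, rmax=2.5)
        c2 = DoseResponseCurve(
            doses=c1.doses, responses=1000.0 * c1.responses, observable="scaled"
        )
        f1, f2 = hill_fit(c1), hill_fit(c2)
        assert f2.n == pytest.approx(f1.n, rel=1e-4)
        assert f2.K == pytest.approx(f1.K, rel=1e-4)
        assert f2.R_min == pytest.approx(1000.0 * f1.R_min, rel=1e-3)
        assert f2.R_max == pytest.approx(1000.0 * f1.R_max, rel=1e-3)

    def test_matches_dense_grid_search_oracle(self):
        """Least-squares fit reaches the brute-force optimum over (n, K)
        (floor/ceiling solved exactly by linear least squares per grid point)."""
        rng = np.random.default_rng(0)
        doses = default_dose_grid(n=19, low=1e-2, high=30.0)
        truth = hill(doses, 1.6, 0.8, 1.0, 4.0)
        noisy = truth + rng.normal(0, 0.05, truth.size)
        curve = DoseResponseCurve(doses=doses, responses=noisy, observable="t")

        def rss_for(n, K):
            shape = np.power(doses, n, where=doses > 0, out=np.zeros_like(doses))
            shape = shape / (K**n + shape)
            A = np.column_stack([np.ones_like(doses), shape])
            coef, res, *_ = np.linalg.lstsq(A, noisy, rcond=None)
            pred = A @ coef
            return np.sum((pred - noisy) ** 2)

        ns = np.linspace(0.5, 4.0, 120)
        Ks = np.geomspace(0.05, 10.0, 120)
        best = min(rss_for(n, K) for n in ns for K in Ks)
        fit = hill_fit(curve)
        assert fit.residual_norm**2 <= best * (1 + 1e-6)

    def test_too_few_doses_rejected(self):
        curve = make_curve(doses=np.array([0.0, 0.1, 1.0, 10.0]))
        with pytest.raises(ValueError, match="6 distinct"):
            hill_fit(curve)


class TestEffectiveConcentration:
    def test_ec50_equals_K(self):
        fit = HillFit(n=2.3, K=0.7, R_min=0.0, R_max=1.0, residual_norm=0.0)
        assert effective_concentration(fit, 0.5) == pytest.approx(0.7)

    @pytest.mark.parametrize("n", [1.0, 1.46, 2.99])
    def test_ec90_over_ec10_is_81_to_inverse_n(self, n):
        fit = HillFit(n=n, K=1.0, R_min=0.0, R_max=1.0, residual_norm=0.0)
        ratio = effective_concentration(fit, 0.9) / effective_concentration(fit, 0.1)
        assert ratio == pytest.approx(81.0 ** (1.0 / n), rel=1e-10)

    def test_curve_interpolation_matches_closed_form_on_pure_hill(self):
        curve = make_curve(n=2.0, K=1.0, rmin=0.0, rmax=1.0,
                           doses=default_dose_grid(n=60, low=1e-3, high=1e3))
        fit = HillFit(n=2.0, K=1.0, R_min=0.0, R_max=1.0, residual_norm=0.0)
        for f in (0.1, 0.5, 0.9):
            assert effective_concentration(curve, f) == pytest.approx(
                effective_concentration(fit, f), rel=0.02
            )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_rejected(self, bad):
        fit = HillFit(n=1.0, K=1.0, R_min=0.0, R_max=1.0, residual_norm=0.0)
        with pytest.raises(ValueError):
            effective_concentration(fit, bad)


class TestNarrowWindowSteepness:
    def test_window_width_maps_to_hill_coefficient(self):
        """log(EC90/EC10) = log 81 / n: narrower transition, larger n."""
        widths = {}
        for n in (1.0, 3.0):
            fit = HillFit(n=n, K=1.0, R_min=0.0, R_max=1.0, residual_norm=0.0)
            widths[n] = np.log(
                effective_concentration(fit, 0.9) / effective_concentration(fit, 0.1)
            )
        assert widths[3.0] == pytest.approx(widths[1.0] / 3.0)
        assert widths[1.0] == pytest.approx(np.log(81.0))


class TestModelCurves:
    def test_knockout_equalizes_hill_coefficients(self, wt_curves, ko_curves):
        """Removing ERK-to-pore regulation makes the nuclear ERK dose response
        graded, with a Hill coefficient close to that of phospho-ERK."""
        n_perk = hill_fit(wt_curves["pERK"]).n
        n_nerk_wt = hill_fit(wt_curves["nERK"]).n
        n_nerk_ko = hill_fit(ko_curves["nERK"]).n
        assert n_nerk_wt > 2.0 * n_perk * 0.9  # switch-like vs graded
        assert n_nerk_ko == pytest.approx(n_perk, abs=0.15)

    def test_knockout_raises_ec90_not_ec10(self, wt_curves, ko_curves):
        wt_ec90 = effective_concentration(wt_curves["nERK"], 0.9)
        ko_ec90 = effective_concentration(ko_curves["nERK"], 0.9)
        wt_ec10 = effective_concentration(wt_curves["nERK"], 0.1)
        ko_ec10 = effective_concentration(ko_curves["nERK"], 0.1)
        assert ko_ec90 > 3.0 * wt_ec90
        assert ko_ec10 == pytest.approx(wt_ec10, rel=0.6)
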