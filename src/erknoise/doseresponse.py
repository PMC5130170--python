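"""Dose-response construction, Hill fitting and effective concentrations.

The Hill form fitted here is

    R(d) = R_min + (R_max - R_min) * d^n / (K^n + d^n)

with the response floor fitted rather than pinned, so absolute observables
(basal phospho-ERK > 0) and fold changes (basal 1) share one code path.
Effective concentrations can be computed either from the closed Hill form
(EC_f = K * (f/(1-f))^(1/n)) or by monotone interpolation of the raw curve
in log dose; simulated pathway curves are not exactly Hill-shaped, so the
two can legitimately differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .deterministic import integrate, peak_response, pre_equilibrate
from ._kinetics import compile_network
from .network import ReactionNetwork

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "HillFitError",
    "default_dose_grid",
    "build_dose_response",
    "hill_fit",
    "effective_concentration",
]


class HillFitError(RuntimeError):
    """No Hill fit converged from any start; carries residual diagnostics."""


def default_dose_grid(n: int = 24, low: float = 1e-4, high: float = 50.0) -> np.ndarray:
    """0 plus a log-spaced dose grid (ng/mL)."""
    return np.concatenate([[0.0], np.geomspace(low, high, n)])


@dataclass
class HillFit:
    """Fitted Hill parameters for a dose-response curve."""

    n: float            # Hill coefficient
    K: float            # half-maximal dose (ng/mL)
    R_min: float
    R_max: float
    residual_norm: float
    observable: str = ""

    def __post_init__(self):
        if self.n <= 0 or self.K <= 0:
            raise ValueError("Hill fit requires n > 0 and K > 0")
        if self.R_max < self.R_min:
            raise ValueError("R_max must be >= R_min")

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        dn = np.power(d, self.n, where=d > 0, out=np.zeros_like(d))
        return self.R_min + (self.R_max - self.R_min) * dn / (self.K**self.n + dn)

    def summary(self) -> dict:
        return {
            "observable": self.observable,
            "hill_n": round(self.n, 2),
            "K_ng_ml": self.K,
            "R_min": self.R_min,
            "R_max": self.R_max,
            "residual_norm": self.residual_norm,
        }


@dataclass
class DoseResponseCurve:
    """Peak responses on a sorted dose grid."""

    doses: np.ndarray           # ng/mL, sorted, typically includes 0
    responses: np.ndarray
    observable: str
    variant: str = "wildtype"   # or "npc_knockout"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        order = np.argsort(self.doses)
        self.doses = self.doses[order]
        self.responses = self.responses[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose": self.doses, "response": self.responses})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.semilogx(
            np.where(self.doses > 0, self.doses, np.nan), self.responses,
            marker="o", **kwargs,
        )
        ax.set_xlabel("EGF dose (ng/mL)")
        ax.set_ylabel(f"peak {self.observable}")
        return ax


def build_dose_response(
    network: ReactionNetwork,
    dose_grid=None,
    observable: str = "nERK",
    t_end: float = 3600.0,
    output_dt: float = 10.0,
    variant: str = "wildtype",
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> DoseResponseCurve:
    """Deterministic peak response at each dose (one pre-equilibration shared)."""
    doses = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, float)
    compiled = compile_network(network)
    y0 = pre_equilibrate(network, compiled, rtol=rtol, atol=atol)
    peaks = []
    for dose in doses:
        try:
            traj = integrate(
                network, float(dose), t_end=t_end, output_dt=output_dt,
                y0=y0, rtol=rtol, atol=atol, compiled=compiled,
            )
        except Exception as exc:
            raise RuntimeError(f"dose-response failed at dose {dose} ng/mL") from exc
        peaks.append(peak_response(traj, observable))
    return DoseResponseCurve(
        doses=doses, responses=np.array(peaks), observable=observable,
        variant=variant, metadata={"t_end": t_end},
    )


def hill_fit(curve: DoseResponseCurve, n_starts=(0.5, 1.0, 2.0, 4.0)) -> HillFit:
    """Least-squares Hill fit with multi-start over the Hill coefficient."""
    d = curve.doses
    r = curve.responses
    if np.sum(np.unique(d) > 0) < 6:
        raise ValueError("need at least 6 distinct positive doses for a Hill fit")
    pos = d > 0
    rmin0 = float(r.min())
    rmax0 = float(r.max())
    span = max(rmax0 - rmin0, 1e-12)
    # initial K: dose nearest the half response
    k0 = float(d[pos][np.argmin(np.abs(r[pos] - (rmin0 + 0.5 * span)))])
    k0 = max(k0, d[pos].min())

    def resid(p):
        n, logk, rmin, rmax = p
        K = np.exp(logk)
        dn = np.power(d, n, where=pos, out=np.zeros_like(d))
        pred = rmin + (rmax - rmin) * dn / (K**n + dn)
        return pred - r

    best = None
    diagnostics = []
    for n0 in n_starts:
        try:
            sol = least_squares(
                resid,
                x0=[n0, np.log(k0), rmin0, rmax0],
                bounds=([1e-3, np.log(d[pos].min()) - 10, -np.inf, -np.inf],
                        [50.0, np.log(d[pos].max()) + 10, np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # noqa: BLE001
            diagnostics.append((n0, str(exc)))
            continue
        if not sol.success:
            diagnostics.append((n0, sol.message))
            continue
        cost = float(np.linalg.norm(sol.fun))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise HillFitError(f"Hill fit failed from all starts: {diagnostics}")
    cost, (n, logk, rmin, rmax) = best
    if rmax < rmin:  # decreasing curve parameterized upside-down
        rmin, rmax = rmax, rmin
    return HillFit(
        n=float(n), K=float(np.exp(logk)), R_min=float(rmin), R_max=float(rmax),
        residual_norm=cost, observable=curve.observable,
    )


def effective_concentration(fit_or_curve, fraction: float) -> float:
    """Dose where the response crosses R_min + fraction * (R_max - R_min).

    From a :class:`HillFit` this is the closed form
    ``K * (f/(1-f))^(1/n)``; from a :class:`DoseResponseCurve` it is read off
    the raw curve by monotone (PCHIP) interpolation in log dose.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    if isinstance(fit_or_curve, HillFit):
        f = fit_or_curve
        return float(f.K * (fraction / (1.0 - fraction)) ** (1.0 / f.n))
    curve: DoseResponseCurve = fit_or_curve
    d = curve.doses
    r = curve.responses
    pos = d > 0
    dpos, rpos = d[pos], r[pos]
    rmin = float(r.min())
    rmax = float(r.max())
    target = rmin + fraction * (rmax - rmin)
    # cumulative max makes the interpolant monotone against solver ripple
    rmono = np.maximum.accumulate(rpos)
    if target <= rmono[0]:
        return float(dpos[0])
    if target >= rmono[-1]:
        return float(dpos[-1])
    interp = PchipInterpolator(np.log(dpos), rmono)
    lo, hi = np.log(dpos[0]), np.log(dpos[-1])
    for _ in range(200):  # bisection on the monotone interpolant
        mid = 0.5 * (lo + hi)
        if interp(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))
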