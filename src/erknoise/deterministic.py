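"""Deterministic (ODE) simulation of mass-action networks.

The rate equations are integrated with a stiff implicit solver on the
molecule-count scale.  Before stimulation the model is relaxed to its
unstimulated steady state, because the nuclear-ERK observable is a fold
change relative to the pre-stimulus level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._kinetics import CompiledNetwork, compile_network, ode_rhs, ode_jac
from .network import ReactionNetwork

__all__ = [
    "Trajectory",
    "IntegrationError",
    "pre_equilibrate",
    "integrate",
    "peak_response",
    "TruncationWarning",
]

#: id of the clamped ligand species in the packaged EGF models
LIGAND_ID = "EGF"

from .models.egf_builder import EGF_MOLECULES_PER_NG_ML  # noqa: E402


class IntegrationError(RuntimeError):
    """Stiff integrator failed; carries the dose and the time reached."""

    def __init__(self, message, dose=None, t_reached=None):
        super().__init__(message)
        self.dose = dose
        self.t_reached = t_reached


class TruncationWarning(UserWarning):
    """The observable was still rising at the end of the simulated window."""


@dataclass
class Trajectory:
    """Time course of species counts with its originating network."""

    times: np.ndarray                 # seconds, strictly increasing
    states: np.ndarray                # time x species, counts
    network: ReactionNetwork
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, self.network.n_species):
            raise ValueError("states must be (n_times, n_species)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, sid: str) -> np.ndarray:
        return self.states[:, self.network.species_index(sid)]

    def observable(self, name: str) -> np.ndarray:
        """Evaluate a named observable along the trajectory.

        ``"nERK"`` is the nuclear-ERK fold change (total nuclear ERK divided
        by its value at t=0); ``"pERK"`` and any other named observable are
        absolute weighted species sums.
        """
        if name == "nERK":
            total = self.states @ self.network.observable_weights("nuclear_ERK")
            if total[0] <= 0:
                raise ValueError("nuclear ERK is zero at t=0; fold change undefined")
            return total / total[0]
        return self.states @ self.network.observable_weights(name)

    def to_frame(self, wide: bool = True) -> pd.DataFrame:
        """Trajectory as a DataFrame (wide: one column per species; tidy
        otherwise, columns time/species/count)."""
        wide_df = pd.DataFrame(
            self.states, columns=self.network.species_ids,
        ).assign(time=self.times).set_index("time")
        if wide:
            return wide_df
        return (
            wide_df.reset_index()
            .melt(id_vars="time", var_name="species", value_name="count")
        )

    def write_csv(self, path, wide: bool = True) -> None:
        self.to_frame(wide=wide).to_csv(path, index=wide)


def _rhs_wrapper(compiled: CompiledNetwork):
    k, re1, re2, homod, S = (
        compiled.k, compiled.re1, compiled.re2, compiled.homod, compiled.S,
    )

    def rhs(t, y):
        return ode_rhs(y, k, re1, re2, homod, S)

    def jac(t, y):
        return ode_jac(y, k, re1, re2, homod, S)

    return rhs, jac


def _set_dose(network: ReactionNetwork, state: np.ndarray, egf_dose: float) -> np.ndarray:
    state = state.copy()
    try:
        idx = network.species_index(LIGAND_ID)
    except KeyError:
        if egf_dose != 0:
            raise ValueError(
                f"network {network.name!r} has no {LIGAND_ID!r} species; "
                "cannot apply a nonzero dose"
            )
        return state
    state[idx] = egf_dose * EGF_MOLECULES_PER_NG_ML
    return state


def pre_equilibrate(
    network: ReactionNetwork,
    compiled: CompiledNetwork | None = None,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    max_rel_rate: float = 1e-9,
    chunk: float = 50_000.0,
    max_time: float = 5e6,
) -> np.ndarray:
    """Relax the unstimulated (dose 0) model to steady state.

    Starts from ``y0`` (default: the network's nominal initial counts) and
    integrates in chunks until the largest relative rate of change falls
    below ``max_rel_rate`` (relative to the largest pool).
    """
    compiled = compiled or compile_network(network)
    rhs, jac = _rhs_wrapper(compiled)
    if y0 is None:
        y0 = network.initial_state()
    y = _set_dose(network, np.asarray(y0, dtype=float), 0.0)
    t = 0.0
    scale = max(np.max(np.abs(y)), 1.0)
    while t < max_time:
        sol = solve_ivp(
            rhs, (0.0, chunk), y, method="LSODA", jac=jac, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"pre-equilibration failed: {sol.message}", dose=0.0, t_reached=t
            )
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += chunk
        if np.max(np.abs(rhs(0.0, y))) / scale < max_rel_rate:
            return y
    warnings.warn(
        "pre-equilibration hit the time cap before the steady-state "
        "criterion; returning the final state",
        RuntimeWarning,
    )
    return y


def integrate(
    network: ReactionNetwork,
    egf_dose: float,
    t_end: float = 3600.0,
    output_dt: float = 10.0,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    equilibrate: bool = True,
    compiled: CompiledNetwork | None = None,
) -> Trajectory:
    """Integrate the network at a constant EGF dose (ng/mL).

    Unless ``y0`` is given, the model is first relaxed to its dose-0 steady
    state, then the ligand is clamped to the requested dose.
    """
    if egf_dose < 0:
        raise ValueError("dose must be non-negative")
    compiled = compiled or compile_network(network)
    if y0 is None:
        y0 = (
            pre_equilibrate(network, compiled, rtol=rtol, atol=atol)
            if equilibrate
            else network.initial_state()
        )
    y0 = _set_dose(network, np.asarray(y0, dtype=float), egf_dose)
    times = np.arange(0.0, t_end + 0.5 * output_dt, output_dt)
    rhs, jac = _rhs_wrapper(compiled)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", jac=jac,
        t_eval=times, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at dose {egf_dose} ng/mL: {sol.message}",
            dose=egf_dose,
            t_reached=sol.t[-1] if sol.t.size else 0.0,
        )
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(
        times=times,
        states=states,
        network=network,
        metadata={"egf_dose": egf_dose, "engine": "ode", "seed": None},
    )


def peak_response(trajectory: Trajectory, observable: str) -> float:
    """Maximum of an observable over the trajectory's output grid.

    Warns if the maximum sits at the final time point while the observable is
    still rising (possible truncation of the transient).
    """
    values = trajectory.observable(observable)
    imax = int(np.argmax(values))
    if imax == values.size - 1 and values.size > 1 and values[-1] > values[-2]:
        warnings.warn(
            f"{observable} peaks at the last time point; the simulated window "
            "may truncate the transient",
            TruncationWarning,
        )
    return float(values[imax])
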