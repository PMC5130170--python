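"""Pseudo-experimental single-cell datasets.

No public single-cell nuclear-ERK dataset ships with this package, so the
recovery and information-theoretic stages are exercised on synthetic data
with the statistical structure of such measurements: per-dose samples of
nuclear-ERK fold change, a basal distribution that is approximately Gaussian
with mean 1, switch-like dose dependence, extrinsic protein variability and
multiplicative measurement error.  Every dataset records its full generating
parameter set and seed, so regeneration is bitwise identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ame import AMEModel, apply_ame
from .network import ReactionNetwork
from .noise import NoiseConfig, run_ensemble

__all__ = [
    "SyntheticDataset",
    "generate_pseudo_experiment",
    "fast_surrogate_generator",
    "DEFAULT_DOSES",
]

#: default dose set (ng/mL): basal, transition and saturating coverage
DEFAULT_DOSES = (0.0, 0.01, 0.05, 0.1, 0.5, 50.0)


@dataclass
class SyntheticDataset:
    """Per-dose single-cell nuclear-ERK fold-change samples with provenance."""

    samples: dict                 # dose -> 1-D array of fold changes
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = {float(d): np.asarray(v, float) for d, v in self.samples.items()}
        for d, v in self.samples.items():
            if np.any(v <= 0):
                raise ValueError(f"non-positive fold change at dose {d}")

    @property
    def doses(self) -> np.ndarray:
        return np.array(sorted(self.samples), dtype=float)

    def per_dose_cv(self) -> pd.Series:
        return pd.Series(
            {
                d: float(np.std(v, ddof=1) / np.mean(v))
                for d, v in sorted(self.samples.items())
            },
            name="cv",
        )

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "dose": d,
                    "cell_id": np.arange(v.size),
                    "fold_change": v,
                }
            )
            for d, v in sorted(self.samples.items())
        ]
        return pd.concat(frames, ignore_index=True)

    def write(self, csv_path: str | Path) -> None:
        """CSV (dose, cell_id, fold_change) plus a sidecar provenance JSON."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        csv_path.with_suffix(".json").write_text(json.dumps(self.params, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path) -> "SyntheticDataset":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        samples = {
            float(d): g["fold_change"].to_numpy() for d, g in df.groupby("dose")
        }
        side = csv_path.with_suffix(".json")
        params = json.loads(side.read_text()) if side.exists() else {}
        return cls(samples=samples, params=params)


def generate_pseudo_experiment(
    network: ReactionNetwork,
    truth_cv: float,
    truth_ame_cv: float,
    doses=DEFAULT_DOSES,
    n_cells: int = 1000,
    seed: int = 0,
    covariation: str = "none",
    intrinsic: bool = False,
    t_end: float = 3600.0,
    output_dt: float = 10.0,
) -> SyntheticDataset:
    """Simulate a pseudo-experiment from the kinetic model.

    Per dose, an extrinsic-noise ensemble at ``truth_cv`` (optionally with
    reaction-timing noise via the SSA when ``intrinsic=True``; at the
    packaged model's molecule numbers that adds little and is off by
    default), multiplied by independent N(1, truth_ame_cv^2) measurement
    factors.  Dose 0 uses the end-point statistic (basal steady state).
    """
    if truth_cv < 0 or truth_ame_cv < 0:
        raise ValueError("truth parameters must be non-negative")
    rng = np.random.default_rng(seed)
    ame = AMEModel(cv_ame=truth_ame_cv)
    samples = {}
    for di, dose in enumerate(doses):
        cfg = NoiseConfig(
            intrinsic=intrinsic,
            extrinsic_cv=truth_cv,
            covariation=covariation,
            n_cells=n_cells,
            master_seed=seed + 7919 * (di + 1),
        )
        res = run_ensemble(
            network, float(dose), cfg, t_end=t_end, output_dt=output_dt,
            statistic="endpoint" if dose == 0 else "peak",
        )
        vals = apply_ame(res.values, ame, rng)
        samples[float(dose)] = np.clip(vals, 1e-9, None)
    return SyntheticDataset(
        samples=samples,
        params={
            "generator": "kinetic_model",
            "network": network.name,
            "truth_cv": truth_cv,
            "truth_ame_cv": truth_ame_cv,
            "covariation": covariation,
            "intrinsic": intrinsic,
            "n_cells": n_cells,
            "seed": seed,
            "doses": list(map(float, doses)),
        },
    )


def fast_surrogate_generator(
    hill_params: dict,
    basal_cv: float,
    ame_cv: float,
    doses=DEFAULT_DOSES,
    n_cells: int = 1000,
    seed: int = 0,
) -> SyntheticDataset:
    """Model-free surrogate dataset for unit testing downstream stages.

    Per-cell response = Hill(dose; K scaled by a per-cell log-normal factor
    with CV ``basal_cv``) x N(1, ame_cv^2).  This is a statistical fixture
    mimicking switch-like single-cell dose responses, NOT the kinetic
    mechanism; use :func:`generate_pseudo_experiment` for model-based data.

    ``hill_params`` needs keys n, K, R_min, R_max.
    """
    for key in ("n", "K", "R_min", "R_max"):
        if key not in hill_params:
            raise KeyError(f"hill_params missing {key!r}")
    n, K = float(hill_params["n"]), float(hill_params["K"])
    rmin, rmax = float(hill_params["R_min"]), float(hill_params["R_max"])
    if n <= 0 or K <= 0 or rmax < rmin:
        raise ValueError("invalid Hill parameters")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(basal_cv**2)) if basal_cv > 0 else 0.0
    samples = {}
    for dose in doses:
        factor = (
            np.exp(sigma * rng.standard_normal(n_cells) - 0.5 * sigma**2)
            if sigma > 0
            else np.ones(n_cells)
        )
        Kcell = K * factor
        if dose > 0:
            resp = rmin + (rmax - rmin) * dose**n / (Kcell**n + dose**n)
        else:
            resp = np.full(n_cells, rmin)
        if ame_cv > 0:
            resp = resp * rng.normal(1.0, ame_cv, size=n_cells)
        samples[float(dose)] = np.clip(resp, 1e-9, None)
    return SyntheticDataset(
        samples=samples,
        params={
            "generator": "fast_surrogate",
            "hill_params": {"n": n, "K": K, "R_min": rmin, "R_max": rmax},
            "basal_cv": basal_cv,
            "ame_cv": ame_cv,
            "n_cells": n_cells,
            "seed": seed,
            "doses": list(map(float, doses)),
        },
    )
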