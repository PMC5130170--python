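"""Figure-level analysis scenarios as configured, logged, seeded runs.

Each scenario runs one figure-level analysis on the packaged model and
writes its tables (CSV/JSON) plus a run manifest into an output directory.
Scenarios run at two scales: ``smoke`` (seconds to ~2 minutes, for pipeline
verification) and full (the package's desk scale).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ame import AMEModel, ProteinVariabilityModel
from .deterministic import integrate, pre_equilibrate
from .doseresponse import build_dose_response, default_dose_grid, hill_fit, effective_concentration
from .infotheory import ChannelSample, debiased_mi
from .models import load_example_network
from .network import knockout_npc_regulation, load_network
from .noise import NoiseConfig, run_ensemble_multidose, species_sensitivity_sweep, classify_sensitivity_types
from .synthetic import DEFAULT_DOSES, generate_pseudo_experiment

logger = logging.getLogger(__name__)

SCENARIOS = (
    "timecourse",
    "dose_response",
    "knockout",
    "noise_compare",
    "ame_recovery",
    "covariation",
    "sensitivity",
    "mutual_info",
    "synth_data",
)


class ConfigError(ValueError):
    """Invalid or incomplete scenario configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _network(cfg):
    path = cfg.get("model")
    return load_network(path) if path else load_example_network()


def _scale(cfg, smoke, key, smoke_val, full_val):
    if key in cfg:
        return cfg[key]
    return smoke_val if smoke else full_val


def run_scenario(config: dict, out_dir: str | Path, smoke: bool = False) -> dict:
    """Run one named scenario; returns the result summary dict.

    ``config`` must name a ``scenario`` (one of :data:`SCENARIOS`) and an
    integer ``seed``; scenario-specific keys override the scale defaults.
    Validation happens before any compute.
    """
    scenario = config.get("scenario")
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose one of {', '.join(SCENARIOS)}"
        )
    if "seed" not in config or not isinstance(config["seed"], int):
        raise ConfigError("config must set an integer 'seed'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    runner = globals()[f"_run_{scenario}"]
    summary = runner(dict(config), out, smoke)
    manifest = {
        "scenario": scenario,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
        "smoke": smoke,
        "seed": config["seed"],
        "erknoise_version": __version__,
        "python": sys.version.split()[0],
        "wall_time_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


# -- scenarios --------------------------------------------------------------


def _run_timecourse(cfg, out, smoke):
    net = _network(cfg)
    doses = cfg.get("doses", [0.0, 0.01, 0.05, 0.1, 0.5, 50.0])
    t_end = _scale(cfg, smoke, "t_end", 900.0, 3600.0)
    y0 = pre_equilibrate(net)
    frames = []
    for d in doses:
        tr = integrate(net, float(d), t_end=t_end, y0=y0)
        frames.append(
            pd.DataFrame(
                {
                    "time": tr.times,
                    "dose": d,
                    "pERK": tr.observable("pERK"),
                    "nERK": tr.observable("nERK"),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "timecourse.csv", index=False)
    peaks = df.groupby("dose")[["pERK", "nERK"]].max()
    return {"peaks": peaks.to_dict(orient="index")}


def _dose_response_bundle(net, doses, t_end, out, label):
    result = {}
    for obs in ("pERK", "nERK"):
        curve = build_dose_response(net, doses, observable=obs, t_end=t_end)
        curve.write_csv(out / f"dose_response_{label}_{obs}.csv")
        fit = hill_fit(curve)
        result[obs] = {
            **fit.summary(),
            "ec10": effective_concentration(curve, 0.1),
            "ec90": effective_concentration(curve, 0.9),
        }
        (out / f"hill_fit_{label}_{obs}.json").write_text(
            json.dumps(result[obs], indent=1)
        )
    return result


def _run_dose_response(cfg, out, smoke):
    net = _network(cfg)
    n_doses = _scale(cfg, smoke, "n_doses", 12, 24)
    doses = np.asarray(cfg.get("doses", default_dose_grid(n=n_doses)), dtype=float)
    t_end = _scale(cfg, smoke, "t_end", 3600.0, 3600.0)
    return _dose_response_bundle(net, doses, t_end, out, "wildtype")


def _run_knockout(cfg, out, smoke):
    net = _network(cfg)
    n_doses = _scale(cfg, smoke, "n_doses", 12, 24)
    doses = np.asarray(cfg.get("doses", default_dose_grid(n=n_doses)), dtype=float)
    t_end = _scale(cfg, smoke, "t_end", 3600.0, 3600.0)
    wt = _dose_response_bundle(net, doses, t_end, out, "wildtype")
    ko = _dose_response_bundle(
        knockout_npc_regulation(net), doses, t_end, out, "npc_knockout"
    )
    return {"wildtype": wt, "npc_knockout": ko}


def _run_noise_compare(cfg, out, smoke):
    net = _network(cfg)
    doses = cfg.get("doses", [0.0, 0.05, 0.5, 50.0] if smoke else list(DEFAULT_DOSES))
    n_cells = _scale(cfg, smoke, "n_cells", 20, 200)
    extr_cv = cfg.get("extrinsic_cv", 0.30)
    seed = cfg["seed"]
    t_end = _scale(cfg, smoke, "t_end", 900.0, 3600.0)
    rows = []
    for regime, intrinsic, cv in (
        ("none", False, 0.0),
        ("intrinsic", True, 0.0),
        ("extrinsic", False, extr_cv),
        ("both", True, extr_cv),
    ):
        ncfg = NoiseConfig(
            intrinsic=intrinsic, extrinsic_cv=cv, n_cells=n_cells, master_seed=seed
        )
        ensembles = run_ensemble_multidose(net, doses, ncfg, t_end=t_end)
        for d in doses:
            rows.append(ensembles[float(d)].summary())
    df = pd.DataFrame(rows)
    df.to_csv(out / "noise_compare.csv", index=False)
    return {"cv_table": df.to_dict(orient="records")}


def _run_ame_recovery(cfg, out, smoke):
    net = _network(cfg)
    seed = cfg["seed"]
    truth_cv = cfg.get("truth_cv", 0.25)
    truth_ame = cfg.get("truth_ame_cv", 0.044)
    n_obs = _scale(cfg, smoke, "n_obs_cells", 60, 400)
    n_sim = _scale(cfg, smoke, "n_sim_cells", 40, 150)
    grid = cfg.get("cv_grid", [0.15, 0.25, 0.35] if smoke else list(np.arange(0, 0.501, 0.05)))
    dataset = generate_pseudo_experiment(
        net, truth_cv, truth_ame, n_cells=n_obs, seed=seed
    )
    dataset.write(out / "pseudo_experiment.csv")
    model = ProteinVariabilityModel(net, dataset.samples, AMEModel(truth_ame))
    res = model.fit(cv_grid=grid, n_cells=n_sim, seed=seed + 1)
    res.rss_profile().to_csv(out / "rss_profile.csv", index=False)
    res.cv_curves.to_csv(out / "cv_vs_dose.csv")
    (out / "recovery.txt").write_text(res.summary())
    return {"truth_cv": truth_cv, "recovered_cv": res.best_cv}


def _run_covariation(cfg, out, smoke):
    net = _network(cfg)
    seed = cfg["seed"]
    cv = cfg.get("extrinsic_cv", 0.25)
    n_cells = _scale(cfg, smoke, "n_cells", 30, 300)
    doses = cfg.get("doses", [0.0, 50.0])
    rows = []
    for cov in ("none", "full"):
        ncfg = NoiseConfig(
            intrinsic=False, extrinsic_cv=cv, covariation=cov,
            n_cells=n_cells, master_seed=seed,
        )
        ensembles = run_ensemble_multidose(net, doses, ncfg)
        for d in doses:
            s = ensembles[float(d)].summary()
            s["covariation"] = cov
            rows.append(s)
    df = pd.DataFrame(rows)
    df.to_csv(out / "covariation.csv", index=False)
    return {"cv_table": df.to_dict(orient="records")}


def _run_sensitivity(cfg, out, smoke):
    net = _network(cfg)
    doses = cfg.get("doses", [0.005, 0.02, 0.05, 0.08, 0.12, 0.5, 5.0, 50.0])
    n_cells = _scale(cfg, smoke, "n_cells", 25, 100)
    cv = cfg.get("cv", 0.25)
    m = species_sensitivity_sweep(
        net, doses, cv=cv, n_cells=n_cells, master_seed=cfg["seed"]
    )
    m.to_csv(out / "sensitivity_matrix.csv")
    types = classify_sensitivity_types(
        m, ec10=cfg.get("ec10", 0.02), ec90=cfg.get("ec90", 0.12)
    )
    (out / "sensitivity_types.json").write_text(json.dumps(types, indent=1))
    return {"types": types}


def _run_mutual_info(cfg, out, smoke):
    net = _network(cfg)
    seed = cfg["seed"]
    truth_cv = cfg.get("truth_cv", 0.25)
    truth_ame = cfg.get("truth_ame_cv", 0.044)
    n_cells = _scale(cfg, smoke, "n_cells", 60, 400)
    cv_grid = cfg.get("cv_grid", [0.1, 0.25, 0.4] if smoke else [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5])
    pseudo = generate_pseudo_experiment(
        net, truth_cv, truth_ame, n_cells=n_cells, seed=seed
    )
    mi_obs = debiased_mi(ChannelSample.from_dict(pseudo.samples), seed=seed)
    rows = [{"dataset": "pseudo_experimental", "cv": truth_cv, "mi_bits": mi_obs}]
    for cv in cv_grid:
        sim = generate_pseudo_experiment(
            net, float(cv), truth_ame, n_cells=n_cells, seed=seed + 17
        )
        rows.append(
            {
                "dataset": "simulation",
                "cv": float(cv),
                "mi_bits": debiased_mi(ChannelSample.from_dict(sim.samples), seed=seed),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "mutual_information.csv", index=False)
    sims = df[df.dataset == "simulation"]
    best = float(sims.cv.iloc[(sims.mi_bits - mi_obs).abs().argmin()])
    return {"mi_pseudo_experimental": mi_obs, "best_matching_cv": best,
            "table": df.to_dict(orient="records")}


def _run_synth_data(cfg, out, smoke):
    net = _network(cfg)
    seed = cfg["seed"]
    n_cells = _scale(cfg, smoke, "n_cells", 50, 1000)
    ds = generate_pseudo_experiment(
        net,
        cfg.get("truth_cv", 0.25),
        cfg.get("truth_ame_cv", 0.044),
        doses=cfg.get("doses", DEFAULT_DOSES),
        n_cells=n_cells,
        seed=seed,
    )
    ds.write(out / "synthetic_dataset.csv")
    return {"per_dose_cv": ds.per_dose_cv().to_dict(), "params": ds.params}
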