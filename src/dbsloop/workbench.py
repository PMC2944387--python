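"""Run configuration, canonical snapshots and run artifacts.

A :class:`RunConfig` is a nested dict with a fixed schema (sections
``scenario``, ``sm``, ``drive``, ``noise``, ``controller``, ``seeds``,
``output``).  Loading materializes every default into the stored
snapshot and rejects unknown keys by name; ``load_config(snapshot(c))``
round-trips exactly.  Every artifact directory receives the exact
snapshot and seed used, so any run can be reproduced from its artifacts
alone.
"""

from __future__ import annotations

import copy
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

log = logging.getLogger("dbsloop")

DEFAULTS = {
    "scenario": {
        "duration": 4000.0,
        "dt": 0.05,
        "obs_interval": 1.0,
        "settle": 1000.0,
        "noise_sd": 2.0,
        "event_threshold": -40.0,
        "event_separation": 25.0,
        "response_window": 25.0,
    },
    "sm": {
        "mode": "periodic",
        "period": 100.0,
        "width": 5.0,
        "amplitude": 1.2,
    },
    "drive": {
        "mode": "parkinsonian_square",
        "low": 10.0,
        "high": 30.0,
        "period": 250.0,
        "duty": 0.5,
    },
    "noise": {
        "Q": [1e-4, 1e-5, 30.0, 0.01],
        "R": 4.0,
        "inflation": 1.0,
        "kappa": None,
    },
    "controller": {
        "kind": "none",
        "amplitude": 20.0,
        "gain": 150.0,
        "threshold": 0.9,
        "mode": "direct",
        "w_window": 35.0,
        "w_ref": None,
        "short_window": 50.0,
        "long_window": 500.0,
        "target": None,
        "update_interval": 1.0,
    },
    "sweep": {
        "axis": "gain",
        "grid": [50.0, 100.0, 200.0],
        "metric": "reliability",
        "n_seeds": 1,
    },
    "seeds": {"seed": 0},
    "output": {"precision": 9},
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Fully materialized run configuration."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self.data == other.data


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    bad = []
    for k, v in user.items():
        here = f"{path}.{k}" if path else k
        if k not in defaults:
            bad.append(here)
            continue
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            try:
                out[k] = _merge(defaults[k], v, here)
            except ConfigError as exc:
                bad.extend(str(exc).split(": ", 1)[1].split(", "))
        else:
            out[k] = v
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(bad)}")
    return out


def parse_config(user: dict) -> RunConfig:
    """Merge a (possibly partial) config dict over the defaults."""
    return RunConfig(data=_merge(DEFAULTS, user))


def load_config(path) -> RunConfig:
    """Load a JSON config file, materializing all defaults."""
    with open(path) as fh:
        user = json.load(fh)
    return parse_config(user)


def snapshot(config: RunConfig) -> str:
    """Canonical text form (sorted-key JSON); stable round trip."""
    return json.dumps(config.data, indent=1, sort_keys=True)


def config_to_objects(config: RunConfig):
    """Instantiate scenario/controller/noise objects from a config."""
    from dbsloop.assimilation import NoiseConfig
    from dbsloop.control import ControllerSpec, ReducedScenario
    from dbsloop.stimulus import GpiDriveSpec, PulseTrainSpec

    c = config.data
    sm = PulseTrainSpec(duration=c["scenario"]["duration"], seed=c["seeds"]["seed"],
                        **c["sm"])
    drive = GpiDriveSpec(**c["drive"])
    scenario = ReducedScenario(sm=sm, drive=drive, **c["scenario"])
    noise = NoiseConfig(
        Q=tuple(c["noise"]["Q"]),
        R=c["noise"]["R"],
        inflation=c["noise"]["inflation"],
        kappa=c["noise"]["kappa"],
    )
    controller = ControllerSpec(**c["controller"])
    return scenario, controller, noise


def write_artifacts(outdir, config: RunConfig, result, label: str = "run") -> dict:
    """Write the standard artifact set for a closed-loop RunResult.

    Returns the metric summary that was written.  Artifacts: config
    snapshot, trajectory/estimate table, pulse and event times, control
    trace and metrics report.
    """
    os.makedirs(outdir, exist_ok=True)
    prec = config["output"]["precision"]
    fmt = f"%.{prec}g"
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        fh.write(snapshot(config))
    cols = np.column_stack(
        [result.t, result.v, result.w, result.obs, result.est, result.u, result.drive]
    )
    np.savetxt(
        os.path.join(outdir, f"{label}_trajectory.tsv"),
        cols,
        fmt=fmt,
        delimiter="\t",
        comments="",
        header="time_ms\tv\tw\tv_obs\test_v\test_w\test_sGi\test_ISM\tu\tdrive",
    )
    np.savetxt(
        os.path.join(outdir, f"{label}_pulses.tsv"),
        np.column_stack(
            [result.onsets, result.outcomes.success.astype(float)]
        ),
        fmt=fmt,
        delimiter="\t",
        comments="",
        header="onset_ms\tsuccess",
    )
    summary = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
               for k, v in result.summary.items()}
    summary["seed"] = result.seed
    summary["diverged"] = bool(result.diverged)
    with open(os.path.join(outdir, f"{label}_metrics.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("wrote artifacts to %s", outdir)
    return summary
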