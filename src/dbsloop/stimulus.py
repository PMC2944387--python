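"""Input signal generation: sensorimotor pulse trains, GPi drive
profiles for the reduced model, and measurement noise.

All traces are generated on the engine's uniform time grid; pulse onset
times land on grid points.  Random trains and observation noise are
seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from dbsloop.engine import time_grid

__all__ = ["PulseTrainSpec", "GpiDriveSpec", "sm_pulse_train", "gpi_drive", "observe"]

#: default sensorimotor pulse width, ms
DEFAULT_PULSE_WIDTH = 5.0
#: refractory floor for random (Poisson) trains, ms
RANDOM_REFRACTORY = 20.0
#: default observation noise standard deviation, mV
DEFAULT_NOISE_SD = 2.0


@dataclass(frozen=True)
class PulseTrainSpec:
    """Sensorimotor input train: periodic or random square pulses."""

    mode: str = "periodic"  # periodic | random
    period: float = 50.0  # ms (mean inter-onset interval in random mode)
    width: float = DEFAULT_PULSE_WIDTH  # ms
    amplitude: float = 1.0  # uA/cm^2
    duration: float = 1000.0  # ms
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("periodic", "random"):
            raise ValueError(f"unknown pulse train mode {self.mode!r}")
        if self.width >= self.period:
            raise ValueError("pulse width must be < period")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class GpiDriveSpec:
    """GPi drive s_Gi(t) for the reduced TC cell.

    ``normal_constant`` and ``dbs_constant`` are flat at ``low`` and
    ``high`` respectively; ``parkinsonian_square`` alternates between
    the two at the stated period and duty cycle (fraction of the period
    spent at the high level).
    """

    mode: str = "normal_constant"
    low: float = 10.0
    high: float = 30.0
    period: float = 250.0  # ms
    duty: float = 0.5

    def __post_init__(self):
        if self.mode not in ("normal_constant", "parkinsonian_square", "dbs_constant"):
            raise ValueError(f"unknown GPi drive mode {self.mode!r}")
        if self.low < 0 or self.high < 0:
            raise ValueError("drive levels must be >= 0")
        if self.mode == "parkinsonian_square" and not self.high > self.low:
            raise ValueError("parkinsonian square wave requires high > low")


def sm_pulse_train(
    spec: PulseTrainSpec, dt: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the pulse train on the grid.

    Returns ``(t, trace, onsets)``; onsets are the pulse start times
    (ms, on grid points) used for response classification.
    """
    t = time_grid(spec.duration, dt)
    trace = np.zeros_like(t)
    if spec.mode == "periodic":
        onsets = np.arange(0.0, spec.duration, spec.period)
    else:
        rng = np.random.default_rng(spec.seed)
        onsets = []
        tt = 0.0
        # Poisson train with a refractory floor; the exponential mean is
        # reduced so the overall mean interval stays at spec.period.
        mean_exp = max(spec.period - RANDOM_REFRACTORY, 1.0)
        while True:
            tt += RANDOM_REFRACTORY + rng.exponential(mean_exp)
            if tt >= spec.duration - spec.width:
                break
            onsets.append(tt)
        onsets = np.asarray(onsets)
    # snap to grid
    onsets = np.round(np.asarray(onsets) / dt).astype(int) * dt
    width_n = int(round(spec.width / dt))
    for on in onsets:
        i = int(round(on / dt))
        trace[i : i + width_n] = spec.amplitude
    return t, trace, onsets


def gpi_drive(spec: GpiDriveSpec, duration: float, dt: float) -> np.ndarray:
    """Piecewise-constant s_Gi trace on ``time_grid(duration, dt)``."""
    t = time_grid(duration, dt)
    if spec.mode == "normal_constant":
        return np.full_like(t, spec.low)
    if spec.mode == "dbs_constant":
        return np.full_like(t, spec.high)
    phase = np.mod(t, spec.period) / spec.period
    return np.where(phase < spec.duty, spec.high, spec.low)


def observe(v: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Additive i.i.d. Gaussian measurement noise on the voltage trace.

    Only the returned observation is corrupted; the plant state is
    untouched.  ``noise_sd = 0`` is the identity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v = np.asarray(v, dtype=float)
    if noise_sd == 0:
        return v.copy()
    rng = np.random.default_rng(seed)
    return v + rng.normal(0.0, noise_sd, size=v.shape)
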