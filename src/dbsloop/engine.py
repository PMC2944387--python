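"""Fixed-step integration and event detection.

The integrator is classical 4th-order Runge-Kutta on a uniform grid.
Time-varying inputs are sampled zero-order-hold on the same grid: the
value at the step's left edge is held through the whole step, so input
traces must be supplied on the integration grid.

Gate safety: integration does not clamp gating variables.  Callers that
require gates in [0, 1] should check trajectories with
:func:`check_bounds`, which fails loudly on overshoot beyond tolerance
rather than silently clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Trajectory", "integrate", "detect_events", "check_bounds", "time_grid"]

#: default integration steps, ms
DT_FULL = 0.01  # full conductance-based models
DT_REDUCED = 0.05  # reduced two-variable model

#: default spike/event detection (mV, ms)
SPIKE_THRESHOLD_FULL = -20.0
SPIKE_SEPARATION_FULL = 2.0
EVENT_THRESHOLD_REDUCED = -40.0
EVENT_SEPARATION_REDUCED = 25.0


@dataclass
class Trajectory:
    """Uniformly sampled multivariate time series."""

    t: np.ndarray  # ms, uniform
    y: np.ndarray  # (len(t), dim)
    labels: Sequence[str] = field(default_factory=list)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __getitem__(self, label: str) -> np.ndarray:
        return self.y[:, list(self.labels).index(label)]

    def to_text(self, path) -> None:
        header = "time_ms\t" + "\t".join(self.labels)
        np.savetxt(
            path,
            np.column_stack([self.t, self.y]),
            header=header,
            delimiter="\t",
            comments="",
        )


def time_grid(duration: float, dt: float) -> np.ndarray:
    """Uniform grid [0, duration] inclusive of both endpoints."""
    n = int(round(duration / dt))
    return np.arange(n + 1) * dt


def integrate(
    rhs: Callable,
    x0,
    dt: float,
    duration: float,
    inputs: Sequence[np.ndarray] = (),
    labels: Sequence[str] = (),
) -> Trajectory:
    """Integrate ``dx/dt = rhs(x, *u)`` with fixed-step RK4.

    ``inputs`` are arrays on the grid ``time_grid(duration, dt)``; the
    value at each step's start is held constant through the step
    (zero-order hold).  A non-finite state aborts with the offending
    time reported.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = time_grid(duration, dt)
    n = len(t)
    for u in inputs:
        if len(u) < n:
            raise ValueError("input trace does not cover [0, duration]")
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    y = np.empty((n, x.size))
    y[0] = x
    for i in range(n - 1):
        u = tuple(ui[i] for ui in inputs)
        k1 = rhs(x, *u)
        k2 = rhs(x + 0.5 * dt * k1, *u)
        k3 = rhs(x + 0.5 * dt * k2, *u)
        k4 = rhs(x + dt * k3, *u)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at t={t[i + 1]:.3f} ms")
        y[i + 1] = x
    if not labels:
        labels = [f"x{j}" for j in range(x.size)]
    return Trajectory(t=t, y=y, labels=list(labels))


def detect_events(
    t: np.ndarray, v: np.ndarray, threshold: float, min_separation: float
) -> np.ndarray:
    """Upward threshold crossings, merged within ``min_separation`` ms.

    Returns event times on grid points (the first sample at or above
    threshold of each crossing).
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    v = np.asarray(v)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return np.array([])
    times = np.asarray(t)[crossings]
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] > min_separation:
            kept.append(tt)
    return np.array(kept)


def check_bounds(
    y: np.ndarray, columns: Sequence[int], lo=0.0, hi=1.0, tol=1e-9
) -> None:
    """Fail loudly if any gating column leaves [lo, hi] by more than tol."""
    sub = np.asarray(y)[:, list(columns)]
    if sub.min() < lo - tol or sub.max() > hi + tol:
        raise FloatingPointError(
            f"gating variable outside [{lo}, {hi}] beyond tolerance "
            f"(min={sub.min():.3e}, max={sub.max():.3e})"
        )
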