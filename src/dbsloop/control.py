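"""DBS control laws, the closed-loop runner and tuning sweeps.

Controllers act on the reduced thalamocortical plant by adding a
non-negative drive ``u`` to the GPi input channel ``s_Gi`` (inhibitory
stimulation can be added, never subtracted).  The closed loop runs on a
fixed control interval (default 1 ms): integrate the plant, emit a
noisy voltage observation, advance the unscented Kalman filter, let the
controller compute ``u`` from the estimates, and apply ``u`` during the
next interval.

Controller family:

``none``              open simulation, u = 0.
``open_loop_constant``  u = amplitude, constant.
``perfect_dbs``       oracle trough-filler u = max(0, target - true drive).
``w_feedback``        proportional feedback on a moving average of the
                      estimated T-current availability:
                      u = gain * max(0, w_ref - MA(w_hat)).
``dual_moving_average``  on/off: stimulate at constant amplitude while a
                      short-term moving average of the estimated GPi
                      drive sits below a long-term moving average of
                      the same estimate.
``reliability_threshold``  on/off on the running relay reliability
                      estimate; ``direct`` stimulates when reliability
                      drops below the threshold, ``inverse`` when it
                      rises above it (exploiting the delay of the
                      reliability average to anticipate the next
                      inhibition trough).

Ties in every threshold comparison resolve to "off" (least
intervention).
"""

from __future__ import annotations

from collections import deque
from dataclasses import asdict, dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from dbsloop import _kernels, metrics
from dbsloop.assimilation import (
    DEFAULT_INITIAL,
    NoiseConfig,
    StateEstimate,
    make_reduced_propagator,
    ukf_step,
)
from dbsloop.cells import load_reduced_params
from dbsloop.engine import detect_events, time_grid
from dbsloop.stimulus import GpiDriveSpec, PulseTrainSpec, gpi_drive, sm_pulse_train

__all__ = [
    "ControllerSpec",
    "ReducedScenario",
    "RunResult",
    "perfect_dbs",
    "w_feedback",
    "dual_moving_average",
    "reliability_controller",
    "closed_loop_run",
    "sweep",
    "SweepResult",
    "normal_rest_w",
    "NORMAL_SCENARIO",
    "PARKINSONIAN_SCENARIO",
    "TUNED_W_FEEDBACK",
]

CONTROLLER_KINDS = (
    "none",
    "open_loop_constant",
    "perfect_dbs",
    "w_feedback",
    "dual_moving_average",
    "reliability_threshold",
)


@dataclass(frozen=True)
class ControllerSpec:
    """Parameters of one control law (fields unused by a kind are ignored)."""

    kind: str = "none"
    amplitude: float = 20.0  # drive units (on/off controllers, open loop)
    gain: float = 150.0  # w_feedback proportional gain
    threshold: float = 0.9  # reliability threshold
    mode: str = "direct"  # direct | inverse (reliability controller)
    w_window: float = 35.0  # ms, moving average of the w estimate
    w_ref: Optional[float] = None  # None -> normal-regime steady-state w
    short_window: float = 50.0  # ms, dual moving average
    long_window: float = 500.0  # ms
    target: Optional[float] = None  # perfect DBS fill level; None -> drive max
    update_interval: float = 1.0  # ms

    def __post_init__(self):
        if self.kind not in CONTROLLER_KINDS:
            raise ValueError(f"unknown controller kind {self.kind!r}")
        if self.amplitude < 0 or self.gain < 0:
            raise ValueError("amplitude and gain must be >= 0")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.mode not in ("direct", "inverse"):
            raise ValueError("mode must be 'direct' or 'inverse'")
        if min(self.w_window, self.short_window, self.long_window) <= 0:
            raise ValueError("windows must be > 0")
        if self.kind == "dual_moving_average" and not (
            self.short_window < self.long_window
        ):
            raise ValueError("short window must be < long window")


@dataclass(frozen=True)
class ReducedScenario:
    """Study conditions for the reduced-cell closed loop.

    Defaults are the parkinsonian relay scenario: a 10 Hz sensorimotor
    pulse train against a 4 Hz square-wave GPi drive alternating
    between the normal level (10) and a peak level (30), with 2 mV
    observation noise on the voltage.
    """

    duration: float = 4000.0  # ms
    dt: float = 0.05  # ms, plant step
    obs_interval: float = 1.0  # ms, observation/filter/control step
    settle: float = 1000.0  # ms at the drive trough before the run
    sm: PulseTrainSpec = PulseTrainSpec(
        mode="periodic", period=100.0, width=5.0, amplitude=1.2, duration=4000.0
    )
    drive: GpiDriveSpec = GpiDriveSpec(
        mode="parkinsonian_square", low=10.0, high=30.0, period=250.0, duty=0.5
    )
    noise_sd: float = 2.0  # mV
    event_threshold: float = -40.0  # mV
    event_separation: float = 25.0  # ms
    response_window: float = 25.0  # ms


NORMAL_SCENARIO = ReducedScenario(
    drive=GpiDriveSpec(mode="normal_constant", low=10.0, high=30.0)
)
PARKINSONIAN_SCENARIO = ReducedScenario()

#: w-feedback controller tuned on the parkinsonian scenario: gain from
#: the interior optimum of the transmitted-spike gain sweep, amplitude
#: cap from the same sweep over caps (ties broken toward lower energy).
TUNED_W_FEEDBACK = ControllerSpec(
    kind="w_feedback", gain=200.0, w_ref=0.15, amplitude=14.0
)


@dataclass
class RunResult:
    """Everything a closed-loop run produced."""

    t: np.ndarray  # control grid, ms
    v: np.ndarray  # plant voltage on the control grid
    w: np.ndarray  # plant availability on the control grid
    obs: np.ndarray  # noisy observations
    est: np.ndarray  # (n, 4) filter means [v, w, s_Gi, I_SM]
    u: np.ndarray  # control drive per interval
    drive: np.ndarray  # true underlying s_Gi per interval
    onsets: np.ndarray
    outcomes: metrics.ResponseOutcomes
    summary: Dict[str, float]
    config: dict
    seed: int
    diverged: bool = False


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Causal moving average with a growing window at the start."""
    width = max(1, width)
    c = np.cumsum(np.insert(np.asarray(x, dtype=float), 0, 0.0))
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i + 1 - width)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def perfect_dbs(drive: np.ndarray, target: Optional[float] = None) -> np.ndarray:
    """Oracle trough-filling stimulation u = max(0, target - drive).

    Uses the *true* drive, not estimates; ``target`` defaults to the
    drive maximum (fill every trough up to the peak level).
    """
    drive = np.asarray(drive, dtype=float)
    if target is None:
        target = float(drive.max())
    if target < drive.min():
        raise ValueError("target must be at least the trough level")
    return np.maximum(0.0, target - drive)


def w_feedback(
    w_hat: np.ndarray,
    dt: float,
    gain: float,
    w_ref: float,
    window: float = 35.0,
    amplitude: float = 20.0,
) -> np.ndarray:
    """Proportional control on the moving-averaged availability estimate.

    The rectified error is scaled by ``gain`` and saturated at
    ``amplitude``; at high gain the controller takes on the on/off
    character of switching stimulation."""
    if gain < 0:
        raise ValueError("gain must be >= 0")
    ma = _moving_average(w_hat, int(round(window / dt)))
    return np.minimum(amplitude, gain * np.maximum(0.0, w_ref - ma))


def dual_moving_average(
    s_hat: np.ndarray,
    dt: float,
    short_window: float = 50.0,
    long_window: float = 500.0,
    amplitude: float = 20.0,
) -> np.ndarray:
    """On/off stimulation while short-term MA < long-term MA (tie: off)."""
    if not short_window < long_window:
        raise ValueError("short window must be < long window")
    short = _moving_average(s_hat, int(round(short_window / dt)))
    long = _moving_average(s_hat, int(round(long_window / dt)))
    return np.where(short < long, amplitude, 0.0)


def reliability_controller(
    rel: np.ndarray, threshold: float, mode: str = "direct", amplitude: float = 20.0
) -> np.ndarray:
    """On/off stimulation from the running reliability estimate."""
    rel = np.asarray(rel, dtype=float)
    if mode == "direct":
        on = rel < threshold
    elif mode == "inverse":
        on = rel > threshold
    else:
        raise ValueError("mode must be 'direct' or 'inverse'")
    return np.where(on, amplitude, 0.0)


def normal_rest_w(params=None) -> float:
    """Steady-state availability in the normal regime (the reference
    point of the w_feedback controller)."""
    if params is None:
        params = load_reduced_params()
    p = _kernels.reduced_param_array(params)
    n = int(2000.0 / 0.05) + 1
    out = _kernels.simulate_reduced(
        np.array([-70.0, 0.3]), p, np.zeros(n), np.full(n, 10.0), 0.05
    )
    return float(out[-1, 1])


class _OnlineReliability:
    """Running relay reliability computed from the filtered voltage."""

    def __init__(self, onsets, window, threshold, window_events=10):
        self.onsets = np.asarray(onsets, dtype=float)
        self.window = window
        self.threshold = threshold
        self.next_pulse = 0
        self.outcomes: deque = deque(maxlen=window_events)
        self.value = 1.0

    def update(self, t_now: float, t_est: np.ndarray, v_est: np.ndarray) -> float:
        while (
            self.next_pulse < len(self.onsets)
            and t_now >= self.onsets[self.next_pulse] + self.window
        ):
            on = self.onsets[self.next_pulse]
            sel = (t_est > on) & (t_est <= on + self.window)
            success = bool(np.any(v_est[sel] >= self.threshold))
            self.outcomes.append(success)
            self.value = float(np.mean(self.outcomes))
            self.next_pulse += 1
        return self.value


def closed_loop_run(
    controller: ControllerSpec,
    scenario: ReducedScenario = PARKINSONIAN_SCENARIO,
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
    params=None,
) -> RunResult:
    """Run plant + filter + controller over the scenario.

    Per control interval the plant is integrated with the current
    control drive added to its s_Gi channel, a noisy observation is
    emitted, the filter advances (knowing the applied control), and the
    controller computes the next interval's drive.  Controllers read
    only filter estimates — except ``perfect_dbs`` (a deliberate oracle
    that reads the true drive) and the open-loop kinds.
    """
    if noise is None:
        noise = NoiseConfig()
    if params is None:
        params = load_reduced_params()
    p_arr = _kernels.reduced_param_array(params)
    dt = scenario.dt
    stride = max(1, int(round(scenario.obs_interval / dt)))
    t_full = time_grid(scenario.duration, dt)
    n_full = len(t_full)
    sm_spec = replace(scenario.sm, duration=scenario.duration, seed=seed)
    _, sm_trace, onsets = sm_pulse_train(sm_spec, dt)
    drive_full = gpi_drive(scenario.drive, scenario.duration, dt)
    # settle the plant at the trough drive level
    n0 = int(round(scenario.settle / dt)) + 1
    x = _kernels.simulate_reduced(
        np.array([-70.0, 0.3]), p_arr, np.zeros(n0), np.full(n0, scenario.drive.low), dt
    )[-1].copy()

    n_ctrl = (n_full - 1) // stride + 1
    t_ctrl = t_full[::stride]
    rng = np.random.default_rng(seed)
    noise_draws = rng.normal(0.0, scenario.noise_sd, size=n_ctrl)

    v_tr = np.empty(n_ctrl)
    w_tr = np.empty(n_ctrl)
    obs_tr = np.empty(n_ctrl)
    est_tr = np.empty((n_ctrl, 4))
    u_tr = np.zeros(n_ctrl)
    drive_ctrl = drive_full[::stride]

    est = StateEstimate(
        mean=DEFAULT_INITIAL.mean.copy(), cov=DEFAULT_INITIAL.cov.copy()
    )
    v_tr[0], w_tr[0] = x
    obs_tr[0] = x[0] + noise_draws[0]
    est_tr[0] = est.mean

    # precomputed open-loop / oracle control traces
    if controller.kind == "perfect_dbs":
        u_pre = perfect_dbs(drive_ctrl, controller.target)
    elif controller.kind == "open_loop_constant":
        u_pre = np.full(n_ctrl, controller.amplitude)
    else:
        u_pre = None

    w_ref = controller.w_ref
    if controller.kind == "w_feedback" and w_ref is None:
        w_ref = normal_rest_w(params)
    w_ma_width = max(1, int(round(controller.w_window / scenario.obs_interval)))
    short_w = max(1, int(round(controller.short_window / scenario.obs_interval)))
    long_w = max(1, int(round(controller.long_window / scenario.obs_interval)))
    w_hist: deque = deque(maxlen=w_ma_width)
    s_short: deque = deque(maxlen=short_w)
    s_long: deque = deque(maxlen=long_w)
    rel_tracker = _OnlineReliability(
        onsets, scenario.response_window, scenario.event_threshold
    )

    diverged = False
    run_len = 0
    u_now = float(u_pre[0]) if u_pre is not None else 0.0
    u_tr[0] = u_now
    for i in range(1, n_ctrl):
        lo, hi = (i - 1) * stride, i * stride
        seg_sm = sm_trace[lo : hi + 1]
        seg_drive = drive_full[lo : hi + 1] + u_now
        out = _kernels.simulate_reduced(x, p_arr, seg_sm, seg_drive, dt)
        x = out[-1].copy()
        v_tr[i], w_tr[i] = x
        obs_tr[i] = x[0] + noise_draws[i]
        propagate = make_reduced_propagator(
            params, scenario.obs_interval, dt, u_extra=u_now
        )
        est = ukf_step(est, obs_tr[i], propagate, noise)
        if not 0.0 <= est.mean[1] <= 1.0:
            est.mean[1] = min(max(est.mean[1], 0.0), 1.0)
        est_tr[i] = est.mean
        if abs(est.innovation) > 10.0 * scenario.noise_sd:
            run_len += 1
            diverged = diverged or run_len > 100
        else:
            run_len = 0

        # controller output for the next interval
        if u_pre is not None:
            u_next = float(u_pre[i])
        elif controller.kind == "none":
            u_next = 0.0
        elif controller.kind == "w_feedback":
            w_hist.append(est.mean[1])
            u_next = min(
                controller.amplitude,
                controller.gain * max(0.0, w_ref - float(np.mean(w_hist))),
            )
        elif controller.kind == "dual_moving_average":
            s_short.append(est.mean[2])
            s_long.append(est.mean[2])
            u_next = (
                controller.amplitude
                if float(np.mean(s_short)) < float(np.mean(s_long))
                else 0.0
            )
        elif controller.kind == "reliability_threshold":
            rel = rel_tracker.update(t_ctrl[i], t_ctrl[: i + 1], est_tr[: i + 1, 0])
            if controller.mode == "direct":
                on = rel < controller.threshold
            else:
                on = rel > controller.threshold
            u_next = controller.amplitude if on else 0.0
        else:  # pragma: no cover
            raise AssertionError(controller.kind)
        u_now = u_next
        u_tr[i] = u_now

    events = detect_events(
        t_ctrl, v_tr, scenario.event_threshold, scenario.event_separation
    )
    outcomes = metrics.classify_responses(
        onsets, events, window=scenario.response_window
    )
    _, rel_trace = metrics.running_reliability(outcomes)
    _, total_energy = metrics.control_energy(u_tr)
    summary = {
        "reliability": float(np.mean(outcomes.success)),
        "final_running_reliability": float(rel_trace[-1]) if len(rel_trace) else np.nan,
        "error_index": metrics.error_index(outcomes),
        "n_pulses": outcomes.n_pulses,
        "n_miss": outcomes.n_miss,
        "n_bad": outcomes.n_bad,
        "total_energy": float(total_energy),
        "event_threshold": scenario.event_threshold,
        "event_separation": scenario.event_separation,
        "response_window": scenario.response_window,
    }
    if scenario.drive.mode == "parkinsonian_square":
        summary["control_reliability"] = metrics.control_reliability(
            u_tr > 0, drive_ctrl
        )
    config = {
        "controller": asdict(controller),
        "scenario": {
            **asdict(scenario),
            "sm": asdict(scenario.sm),
            "drive": asdict(scenario.drive),
        },
        "noise": {
            "Q": list(noise.Q),
            "R": noise.R,
            "inflation": noise.inflation,
            "kappa": noise.kappa,
        },
    }
    return RunResult(
        t=t_ctrl,
        v=v_tr,
        w=w_tr,
        obs=obs_tr,
        est=est_tr,
        u=u_tr,
        drive=drive_ctrl,
        onsets=onsets,
        outcomes=outcomes,
        summary=summary,
        config=config,
        seed=seed,
        diverged=diverged,
    )


def sweep(
    controller: ControllerSpec,
    axis: str,
    grid: Sequence,
    seeds: Sequence[int] = (0,),
    scenario: ReducedScenario = PARKINSONIAN_SCENARIO,
    noise: Optional[NoiseConfig] = None,
    metric: str = "reliability",
) -> "SweepResult":
    """Grid sweep of a controller/filter parameter.

    ``axis`` is ``gain``, ``amplitude``, ``threshold`` or ``inflation``;
    the per-point value is the chosen summary metric averaged over
    seeds.  Individual failed runs are recorded as missing and the
    sweep continues.
    """
    if len(grid) == 0:
        raise ValueError("sweep grid must be non-empty")
    if noise is None:
        noise = NoiseConfig()
    rows = []
    for g in grid:
        for seed in seeds:
            spec = controller
            nz = noise
            if axis == "inflation":
                nz = NoiseConfig(
                    Q=noise.Q, R=noise.R, inflation=float(g), kappa=noise.kappa
                )
            elif axis in ("gain", "amplitude", "threshold"):
                spec = replace(controller, **{axis: float(g)})
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            try:
                res = closed_loop_run(spec, scenario, nz, seed=seed)
                val = res.summary[metric]
            except (FloatingPointError, np.linalg.LinAlgError):
                val = np.nan
            rows.append((float(g), int(seed), val))
    return SweepResult(axis=axis, metric=metric, rows=rows)


@dataclass
class SweepResult:
    axis: str
    metric: str
    rows: list  # (grid value, seed, metric value or NaN)

    def aggregated(self) -> Tuple[np.ndarray, np.ndarray]:
        """(grid values, seed-mean metric ignoring missing runs)."""
        vals = sorted({r[0] for r in self.rows})
        means = []
        for v in vals:
            xs = [r[2] for r in self.rows if r[0] == v and np.isfinite(r[2])]
            means.append(np.mean(xs) if xs else np.nan)
        return np.asarray(vals), np.asarray(means)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.axis}\tseed\t{self.metric}\n")
            for g, s, v in self.rows:
                fh.write(f"{g:.9g}\t{s}\t{v:.9g}\n")
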