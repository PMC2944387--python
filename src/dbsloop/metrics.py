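"""Relay-fidelity, control-energy, control-reliability, synchrony and
cost metrics.

Response classification: a sensorimotor pulse is a *success* if at
least one relay event falls inside ``(onset, onset + window]``; each
event is attributed to at most one pulse, and events attributable to no
pulse are *bad spikes*.  The error index is
``(n_miss + n_bad) / n_pulses`` and can exceed 1 when bad spikes are
numerous.  The running reliability at each pulse is the fraction of
successes among the most recent ``window_events`` pulses (fewer early
in the run); bad spikes affect the error index but not the running
reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple
import warnings

import numpy as np

__all__ = [
    "ResponseOutcomes",
    "CostSpec",
    "classify_responses",
    "error_index",
    "running_reliability",
    "control_energy",
    "control_reliability",
    "dbs_cost",
    "population_synchrony",
    "DEFAULT_RESPONSE_WINDOW",
]

#: default response window after pulse onset, ms
DEFAULT_RESPONSE_WINDOW = 10.0


@dataclass
class ResponseOutcomes:
    """Per-pulse relay outcomes plus unattributed (bad) events."""

    onsets: np.ndarray  # ms
    success: np.ndarray  # bool per pulse
    bad_times: np.ndarray  # ms, events attributable to no pulse
    window: float  # ms, the response window used

    @property
    def n_pulses(self) -> int:
        return len(self.onsets)

    @property
    def n_miss(self) -> int:
        return int(np.sum(~self.success))

    @property
    def n_bad(self) -> int:
        return len(self.bad_times)


@dataclass(frozen=True)
class CostSpec:
    """Weight of the energy term in the reliability-minus-energy cost.

    The weighting parameter is called ``cost_weight`` here to avoid a
    clash with the T-current availability variable ``w``.
    """

    cost_weight: float = 0.0

    def __post_init__(self):
        if self.cost_weight < 0:
            raise ValueError("cost_weight must be >= 0")


def classify_responses(
    onsets: Sequence[float],
    events: Sequence[float],
    window: float = DEFAULT_RESPONSE_WINDOW,
) -> ResponseOutcomes:
    """Attribute relay events to sensorimotor pulses.

    Response windows of consecutive pulses must not overlap.  An event
    at time ``e`` answers pulse ``p`` if ``p < e <= p + window``; the
    first event in a window claims the pulse, later events in the same
    window are attributed to it as well (a burst answering one pulse is
    one success, not bad spikes).
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    events = np.sort(np.asarray(events, dtype=float))
    if len(onsets) > 1 and np.any(np.diff(onsets) < window):
        raise ValueError("response windows of consecutive pulses overlap")
    success = np.zeros(len(onsets), dtype=bool)
    bad: List[float] = []
    for e in events:
        j = np.searchsorted(onsets, e) - 1  # latest onset strictly before e
        if j >= 0 and e <= onsets[j] + window:
            success[j] = True
        else:
            bad.append(e)
    return ResponseOutcomes(
        onsets=onsets, success=success, bad_times=np.asarray(bad), window=window
    )


def error_index(outcomes: ResponseOutcomes) -> float:
    """(misses + bad spikes) / pulses; >= 0, may exceed 1."""
    if outcomes.n_pulses == 0:
        raise ValueError("error index undefined for zero pulses")
    return (outcomes.n_miss + outcomes.n_bad) / outcomes.n_pulses


def running_reliability(
    outcomes: ResponseOutcomes, window_events: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant reliability over the most recent pulses.

    Returns ``(pulse_times, reliability)`` where the value at pulse k is
    the success fraction of the last ``min(window_events, k+1)`` pulses.
    """
    if window_events < 1:
        raise ValueError("window_events must be >= 1")
    s = outcomes.success.astype(float)
    rel = np.empty_like(s)
    for k in range(len(s)):
        lo = max(0, k + 1 - window_events)
        rel[k] = s[lo : k + 1].mean()
    return outcomes.onsets.copy(), rel


def control_energy(u: np.ndarray) -> Tuple[np.ndarray, float]:
    """Running cumulative sum of u^2 and its total."""
    u = np.asarray(u, dtype=float)
    running = np.cumsum(u**2)
    total = float(running[-1]) if len(running) else 0.0
    return running, total


def control_reliability(
    u_on: np.ndarray, true_drive: np.ndarray, level_tol: float = 0.01
) -> float:
    """Fraction of samples where the control state mirrors the drive.

    ``true_drive`` must be two-valued after snapping each sample to its
    nearest level with relative tolerance ``level_tol``; correct means
    on during troughs and off during peaks.
    """
    u_on = np.asarray(u_on, dtype=bool)
    d = np.asarray(true_drive, dtype=float)
    if u_on.shape != d.shape:
        raise ValueError("traces must share the grid")
    lo, hi = d.min(), d.max()
    if hi - lo <= 0:
        raise ValueError("true drive is constant; troughs/peaks undefined")
    scale = max(abs(lo), abs(hi))
    near_lo = np.abs(d - lo) <= level_tol * scale
    near_hi = np.abs(d - hi) <= level_tol * scale
    if not np.all(near_lo | near_hi):
        raise ValueError("true drive is not two-valued within tolerance")
    correct = (u_on & near_lo) | (~u_on & near_hi)
    return float(np.mean(correct))


def dbs_cost(reliability: float, total_energy: float, spec: CostSpec) -> float:
    """Reliability minus weighted total control energy."""
    return reliability - spec.cost_weight * total_energy


def _binned(train: np.ndarray, bin_ms: float, duration: float) -> np.ndarray:
    n = int(np.ceil(duration / bin_ms))
    counts, _ = np.histogram(train, bins=n, range=(0.0, n * bin_ms))
    return counts.astype(float)


def population_synchrony(
    trains: Sequence[np.ndarray], bin_ms: float = 5.0, max_lag_ms: float = 200.0
) -> float:
    """Oscillatory synchrony of a spiking population.

    Combines (i) the mean peak of the zero-normalized cross-correlation
    between binned pairs of trains over lags up to ``max_lag_ms`` and
    (ii) the mean autocorrelation sideband peak (excluding zero lag),
    averaged: sync = (cross_peak + auto_sideband) / 2.  For a single
    train only the autocorrelation term is returned.  Near-maximal for
    identical periodic trains, near 0 for independent Poisson trains.
    Empty trains are excluded with a warning.
    """
    kept = [np.asarray(tr, dtype=float) for tr in trains if len(np.asarray(tr)) > 0]
    if len(kept) < len(trains):
        warnings.warn("empty spike trains excluded from synchrony metric")
    if not kept:
        raise ValueError("population_synchrony requires at least one non-empty train")
    duration = max(tr.max() for tr in kept) + bin_ms
    binned = [_binned(tr, bin_ms, duration) for tr in kept]
    binned = [b - b.mean() for b in binned]
    max_lag = int(max_lag_ms / bin_ms)

    def _xcorr_peak(a: np.ndarray, b: np.ndarray, exclude_zero: bool) -> float:
        denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
        if denom == 0:
            return 0.0
        full = np.correlate(a, b, mode="full") / denom
        mid = len(full) // 2
        lo, hi = mid - max_lag, mid + max_lag + 1
        seg = full[lo:hi].copy()
        if exclude_zero:
            seg[max_lag] = -np.inf
        return float(seg.max())

    autos = [_xcorr_peak(b, b, exclude_zero=True) for b in binned]
    auto_term = float(np.mean(autos))
    if len(binned) == 1:
        return max(auto_term, 0.0)
    crosses = [
        _xcorr_peak(binned[i], binned[j], exclude_zero=False)
        for i in range(len(binned))
        for j in range(i + 1, len(binned))
    ]
    cross_term = float(np.mean(crosses))
    return max(0.5 * (cross_term + auto_term), 0.0)
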