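"""Unscented Kalman filter tracking of the reduced thalamocortical cell.

The filter state is the 4-vector ``[v, w, s_Gi, I_SM]`` (ordering fixed
throughout): membrane voltage (mV), T-current availability, the
dimensionless GPi drive and the sensorimotor current (uA/cm^2).  Only a
noisy voltage is observed.  The two inputs are tracked as random walks
whose per-step variances (the process-noise apportionment ``Q_sGi``,
``Q_SM``) decide which of the two symmetric input currents the filter
resolves: the voltage equation only constrains their sum, so variance is
deliberately granted to the input one wants reconstructed and starved
from the other.

Covariance inflation multiplies the full predicted covariance by a
factor >= 1 each step, compensating model inadequacy and keeping the
filter responsive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from dbsloop import _kernels
from dbsloop.cells import ReducedTCParams, load_reduced_params, reduced_nullclines

__all__ = [
    "NoiseConfig",
    "StateEstimate",
    "TrackResult",
    "sigma_points",
    "ukf_step",
    "track",
    "estimate_nullclines",
    "STATE_LABELS",
]

STATE_LABELS = ("v", "w", "s_Gi", "I_SM")

#: divergence flag: innovation beyond this many observation sds ...
DIVERGENCE_SDS = 10.0
#: ... for at least this many consecutive steps
DIVERGENCE_STEPS = 100


@dataclass(frozen=True)
class NoiseConfig:
    """Process/observation noise and unscented-transform scaling.

    ``Q`` is the per-filter-step process variance of each augmented
    state component; ``R`` the observation variance (mV^2);
    ``inflation`` the multiplicative covariance inflation factor.
    ``kappa`` defaults to the classical ``3 - n`` when None.
    """

    Q: Tuple[float, float, float, float] = (1e-4, 1e-5, 30.0, 0.01)
    R: float = 4.0
    inflation: float = 1.0
    kappa: Optional[float] = None

    def __post_init__(self):
        if any(q < 0 for q in self.Q):
            raise ValueError("Q entries must be >= 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")


@dataclass
class StateEstimate:
    """Filter mean and covariance over the augmented state."""

    mean: np.ndarray  # (4,)
    cov: np.ndarray  # (4, 4) symmetric PSD
    innovation: float = 0.0


@dataclass
class TrackResult:
    """Filtered trajectories on the observation grid."""

    t: np.ndarray
    mean: np.ndarray  # (n, 4)
    cov_diag: np.ndarray  # (n, 4)
    innovation: np.ndarray  # (n,)
    diverged: bool = False
    n_clipped: int = 0  # w estimates clipped to [0, 1] after update

    def __getitem__(self, label: str) -> np.ndarray:
        return self.mean[:, STATE_LABELS.index(label)]

    def to_text(self, path) -> None:
        header = "time_ms\t" + "\t".join(STATE_LABELS)
        header += "\t" + "\t".join(f"var_{l}" for l in STATE_LABELS) + "\tinnovation"
        np.savetxt(
            path,
            np.column_stack([self.t, self.mean, self.cov_diag, self.innovation]),
            header=header,
            delimiter="\t",
            comments="",
        )


def sigma_points(
    mean: np.ndarray, cov: np.ndarray, kappa: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Julier-Uhlmann sigma points and weights.

    Returns ``(points, weights)`` with ``2n + 1`` rows; the weighted
    sample mean and covariance of the points reproduce the inputs.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = mean.size
    if kappa is None:
        kappa = 3.0 - n
    scale = n + kappa
    if scale <= 0:
        raise ValueError("n + kappa must be > 0")
    m = 0.5 * scale * (cov + cov.T)
    try:
        L = np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        # singular-but-PSD covariances (e.g. zero variance) fall back to
        # an eigendecomposition square root
        vals, vecs = np.linalg.eigh(m)
        if vals.min() < -1e-9 * max(1.0, abs(vals.max())):
            raise np.linalg.LinAlgError(
                f"sigma-point factorization failed: covariance not PSD\n{cov!r}"
            ) from exc
        L = vecs * np.sqrt(np.maximum(vals, 0.0))
    pts = np.empty((2 * n + 1, n))
    pts[0] = mean
    pts[1 : n + 1] = mean + L.T
    pts[n + 1 :] = mean - L.T
    w = np.full(2 * n + 1, 1.0 / (2.0 * scale))
    w[0] = kappa / scale
    return pts, w


def _unscented_moments(pts: np.ndarray, w: np.ndarray):
    mean = w @ pts
    d = pts - mean
    cov = (d * w[:, None]).T @ d
    return mean, cov


def ukf_step(
    est: StateEstimate,
    observation: float,
    propagate: Callable[[np.ndarray], np.ndarray],
    noise: NoiseConfig,
) -> StateEstimate:
    """One predict/update cycle against a scalar voltage observation.

    ``propagate`` maps an array of sigma points (rows) through the model
    over one filter step; input components are held constant inside it
    (random-walk dynamics), their process noise entering through ``Q``.
    The predicted covariance is inflated multiplicatively before the
    update; the innovation is recorded on the returned estimate.
    """
    pts, w = sigma_points(est.mean, est.cov, noise.kappa)
    pts = propagate(pts)
    mean_p, cov_p = _unscented_moments(pts, w)
    cov_p = cov_p + np.diag(noise.Q)
    cov_p = cov_p * noise.inflation
    # observation model: h(x) = x[0], the voltage component.  Because h
    # is linear the update is computed exactly from the predicted
    # covariance (process noise included), which keeps the step
    # identical to the classical Kalman filter on linear dynamics.
    s = float(cov_p[0, 0]) + noise.R
    gain = cov_p[:, 0] / s
    innov = float(observation) - float(mean_p[0])
    mean_u = mean_p + gain * innov
    cov_u = cov_p - np.outer(gain, gain) * s
    cov_u = 0.5 * (cov_u + cov_u.T)
    eigval, eigvec = np.linalg.eigh(cov_u)
    tol = 1e-6 * max(1.0, float(np.trace(cov_u)))
    if eigval.min() < -tol:
        raise np.linalg.LinAlgError(
            f"updated covariance lost positive semidefiniteness "
            f"(min eig {eigval.min():.3e})"
        )
    if eigval.min() < 0.0:
        # repair harmless round-off negativity from the kappa < 0 weights
        cov_u = (eigvec * np.maximum(eigval, 0.0)) @ eigvec.T
        cov_u = 0.5 * (cov_u + cov_u.T)
    return StateEstimate(mean=mean_u, cov=cov_u, innovation=innov)


def make_reduced_propagator(
    params: ReducedTCParams, dt_obs: float, dt_model: float, u_extra: float = 0.0
):
    """Sigma-point propagator through the reduced cell over one filter step.

    ``u_extra`` is a known control drive added to the s_Gi channel
    during the step.  The filter then tracks the *underlying* drive:
    the control contribution is added before propagation and removed
    after, so the estimate stays net of the known stimulation.
    """
    p = _kernels.reduced_param_array(params)
    nsub = max(1, int(round(dt_obs / dt_model)))

    def propagate(pts: np.ndarray) -> np.ndarray:
        pts = np.ascontiguousarray(pts).copy()
        pts[:, 2] += u_extra
        _kernels.propagate_sigma_reduced(pts, p, dt_model, nsub)
        pts[:, 2] -= u_extra
        return pts

    return propagate


DEFAULT_INITIAL = StateEstimate(
    mean=np.array([-70.0, 0.3, 10.0, 0.0]),
    cov=np.diag([25.0, 0.04, 25.0, 1.0]),
)


def track(
    t_obs: np.ndarray,
    observations: np.ndarray,
    noise: NoiseConfig,
    initial: Optional[StateEstimate] = None,
    params: Optional[ReducedTCParams] = None,
    dt_model: float = 0.05,
    u_trace: Optional[np.ndarray] = None,
) -> TrackResult:
    """Run the UKF over a noisy voltage trace.

    ``t_obs`` must be uniform; the model is sub-stepped at ``dt_model``
    between observations.  ``u_trace`` optionally supplies a known
    control drive (added to s_Gi) per observation interval.  Divergence
    (innovation beyond 10 observation sds for more than 100 consecutive
    steps) is flagged in the result; the run continues.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    dts = np.diff(t_obs)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
        raise ValueError("observation grid must be uniform")
    if params is None:
        params = load_reduced_params()
    if initial is None:
        initial = StateEstimate(
            mean=DEFAULT_INITIAL.mean.copy(), cov=DEFAULT_INITIAL.cov.copy()
        )
    dt_obs = float(dts[0]) if len(dts) else dt_model
    n = len(t_obs)
    mean = np.empty((n, 4))
    cov_diag = np.empty((n, 4))
    innov = np.empty(n)
    est = initial
    mean[0] = est.mean
    cov_diag[0] = np.diag(est.cov)
    innov[0] = 0.0
    n_clipped = 0
    run_len = 0
    diverged = False
    obs_sd = float(np.sqrt(noise.R))
    base_prop = make_reduced_propagator(params, dt_obs, dt_model, 0.0)
    for i in range(1, n):
        if u_trace is not None and u_trace[i - 1] != 0.0:
            propagate = make_reduced_propagator(
                params, dt_obs, dt_model, float(u_trace[i - 1])
            )
        else:
            propagate = base_prop
        est = ukf_step(est, float(observations[i]), propagate, noise)
        if not 0.0 <= est.mean[1] <= 1.0:
            est.mean[1] = min(max(est.mean[1], 0.0), 1.0)
            n_clipped += 1
        if abs(est.innovation) > DIVERGENCE_SDS * obs_sd:
            run_len += 1
            if run_len > DIVERGENCE_STEPS:
                diverged = True
        else:
            run_len = 0
        mean[i] = est.mean
        cov_diag[i] = np.diag(est.cov)
        innov[i] = est.innovation
    return TrackResult(
        t=t_obs,
        mean=mean,
        cov_diag=cov_diag,
        innovation=innov,
        diverged=diverged,
        n_clipped=n_clipped,
    )


def estimate_nullclines(
    params: ReducedTCParams,
    s_Gi: float,
    s_Gi_var: float = 0.0,
    I_SM: float = 0.0,
    v_grid=None,
    kappa: Optional[float] = None,
):
    """Nullclines implied by an estimated drive, with uncertainty band.

    The v-nullcline is evaluated at sigma points of the scalar ``s_Gi``
    estimate and recombined, giving a mean curve and standard-deviation
    band; the w-nullcline does not depend on the drive.  Returns
    ``(v_grid, v_null_mean, v_null_sd, w_null)``.
    """
    if s_Gi_var < 0:
        raise ValueError("s_Gi_var must be >= 0")
    pts, wts = sigma_points(np.array([s_Gi]), np.array([[s_Gi_var]]), kappa)
    curves = []
    for s in pts[:, 0]:
        v, vnull, wnull = reduced_nullclines(
            params, s_Gi=max(float(s), 0.0), I_SM=I_SM, v_grid=v_grid
        )
        curves.append(vnull)
    curves = np.asarray(curves)
    mean = wts @ curves
    var = wts @ (curves - mean) ** 2
    return v, mean, np.sqrt(np.maximum(var, 0.0)), wnull
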