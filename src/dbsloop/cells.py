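"""Ionic-current right-hand sides for basal ganglia and thalamic cell models.

Four conductance-based cell types are provided:

``tc_full``
    Thalamocortical relay neuron with leak, fast sodium, rectifying
    potassium and low-threshold T-type calcium currents.  The Rinzel
    reductions are applied: the sodium activation gate is set to its
    steady state ``m = m_inf(v)`` and the potassium gate is replaced by
    ``n = 1 - h`` where ``h`` is the sodium inactivation gate.  State is
    ``[v, h, r, Ca]`` (the calcium pool is inert for this cell type and
    kept only for a homogeneous state layout).
``stn`` / ``gpe`` / ``gpi``
    Subthalamic and pallidal cells with an independent potassium gate
    ``n``, a slow T-current inactivation gate ``r``, a high-threshold
    calcium current and a calcium-activated after-hyperpolarization
    (AHP) potassium current.  State is ``[v, h, n, r, Ca]``.  The
    calcium pool is a single first-order scalar integrating influx from
    the two calcium currents minus first-order removal.
``tc_reduced``
    Two-variable thalamocortical cell ``[v, w]`` in which the fast
    sodium/potassium spike machinery is removed and ``w`` is the
    availability of the T-current.  Relay events are slow excitability
    events rather than sodium spikes.  GPi inhibition enters as a true
    synaptic current ``g_GiTh * s_Gi * (v - E_GiTh)`` so the current
    fluctuates with voltage even for constant drive ``s_Gi``.

Units are fixed throughout: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.

Naming note: the literature calls ``w`` (and ``r``) both "T-current
inactivation" and "availability of T-current".  Here ``w`` is the gate
that multiplies ``I_T`` — high ``w`` means more available current; it is
raised by hyperpolarization (deinactivation) and depleted by sustained
depolarization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "GatingSpec",
    "CellParams",
    "ReducedTCParams",
    "load_cell_params",
    "load_reduced_params",
    "leak_current",
    "gating_rate",
    "sigmoid",
    "tc_full_currents",
    "tc_full_derivatives",
    "stn_derivatives",
    "gpe_derivatives",
    "pallidal_currents",
    "reduced_tc_currents",
    "reduced_tc_derivatives",
]

INSTANTANEOUS = "instantaneous"


def sigmoid(v, theta: float, sigma: float):
    """Boltzmann sigmoid ``1 / (1 + exp(-(v - theta) / sigma))``.

    ``sigma > 0`` gives an increasing activation curve, ``sigma < 0`` a
    decreasing inactivation curve.
    """
    return 1.0 / (1.0 + np.exp(-(v - theta) / sigma))


@dataclass(frozen=True)
class GatingSpec:
    """Voltage-dependent steady state and time constant of one gate.

    ``time_constant`` is either a callable of voltage returning ms or
    the string ``"instantaneous"`` for gates slaved to their steady
    state.
    """

    steady_state: Callable[[float], float]
    time_constant: Union[Callable[[float], float], str]

    @property
    def is_instantaneous(self) -> bool:
        return self.time_constant == INSTANTANEOUS


def gating_rate(x, spec: GatingSpec, v):
    """First-order kinetics ``dx/dt = (x_inf(v) - x) / tau(v)``.

    Raises ``ValueError`` for an instantaneous gate: the caller must
    substitute the steady state directly instead of integrating it.
    """
    if spec.is_instantaneous:
        raise ValueError(
            "instantaneous gate has no kinetics; substitute steady_state(v)"
        )
    return (spec.steady_state(v) - x) / spec.time_constant(v)


def leak_current(v, g_L: float, E_L: float):
    """Ohmic leak ``g_L * (v - E_L)``."""
    return g_L * (v - E_L)


def _sigmoid_tau(tau0: float, tau1: float, theta: float, sigma: float):
    return lambda v: tau0 + tau1 / (1.0 + np.exp(-(v - theta) / sigma))


def _exp_tau(base: float, scale: float, theta: float, sigma: float):
    return lambda v: base + scale * np.exp(-(v - theta) / sigma)


@dataclass(frozen=True)
class CellParams:
    """Conductances, reversal potentials and gating kinetics of one cell type."""

    cell_type: str
    C_m: float
    g_L: float
    E_L: float
    g_Na: float
    E_Na: float
    g_K: float
    E_K: float
    g_T: float
    E_T: float  # pallidal/STN cells use E_Ca for the T current as well
    g_Ca: float
    E_Ca: float
    g_AHP: float
    ahp_k1: float
    ca_eps: float  # calcium influx scale
    ca_k: float  # calcium removal rate
    gating: Mapping[str, GatingSpec] = field(default_factory=dict)
    raw: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("g_L", "g_Na", "g_K", "g_T", "g_Ca", "g_AHP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")


@dataclass(frozen=True)
class ReducedTCParams:
    """Parameters of the two-variable thalamocortical cell.

    ``phi`` is the relative rate constant between the ``w`` and ``v``
    equations (dimensionless, > 0).
    """

    C_m: float
    g_L: float
    E_L: float
    g_T: float
    E_T: float
    g_GiTh: float
    E_GiTh: float
    phi: float
    gating: Mapping[str, GatingSpec] = field(default_factory=dict)
    raw: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if not self.E_GiTh < self.E_L:
            raise ValueError("E_GiTh must lie below E_L (inhibitory reversal)")


def _read_param_file(name: str) -> dict:
    path = resources.files("dbsloop.params").joinpath(f"{name}.json")
    with path.open("r") as fh:
        return json.load(fh)


def load_cell_params(name: str) -> CellParams:
    """Load a full-cell parameter set (``tc_full``, ``stn``, ``gpe``, ``gpi``)."""
    d = _read_param_file(name)
    kind = d["cell_type"]
    if kind == "tc_full":
        a_sc, a_th, a_sg = d["h_a_scale"], d["h_a_theta"], d["h_a_sigma"]
        b_sc, b_th, b_sg = d["h_b_scale"], d["h_b_theta"], d["h_b_sigma"]

        def tau_h(v, a_sc=a_sc, a_th=a_th, a_sg=a_sg, b_sc=b_sc, b_th=b_th, b_sg=b_sg):
            a = a_sc * np.exp(-(v - a_th) / a_sg)
            b = b_sc / (1.0 + np.exp(-(v - b_th) / b_sg))
            return 1.0 / (a + b)

        phi_r = d["phi_r"]
        tau_r_raw = _exp_tau(
            d["tau_r_base"], d["tau_r_scale"], d["tau_r_theta"], d["tau_r_sigma"]
        )
        gating = {
            "m": GatingSpec(
                lambda v: sigmoid(v, d["m_theta"], d["m_sigma"]), INSTANTANEOUS
            ),
            "h": GatingSpec(lambda v: sigmoid(v, d["h_theta"], d["h_sigma"]), tau_h),
            "p": GatingSpec(
                lambda v: sigmoid(v, d["p_theta"], d["p_sigma"]), INSTANTANEOUS
            ),
            "r": GatingSpec(
                lambda v: sigmoid(v, d["r_theta"], d["r_sigma"]),
                lambda v: tau_r_raw(v) / phi_r,
            ),
        }
        return CellParams(
            cell_type=kind,
            C_m=d["C_m"],
            g_L=d["g_L"],
            E_L=d["E_L"],
            g_Na=d["g_Na"],
            E_Na=d["E_Na"],
            g_K=d["g_K"],
            E_K=d["E_K"],
            g_T=d["g_T"],
            E_T=d["E_T"],
            g_Ca=0.0,
            E_Ca=120.0,  # placeholder; no high-threshold Ca current here
            g_AHP=0.0,
            ahp_k1=1.0,
            ca_eps=0.0,
            ca_k=0.0,
            gating=gating,
            raw=d,
        )
    # pallidal / STN family
    gating = {
        "m": GatingSpec(
            lambda v: sigmoid(v, d["m_theta"], d["m_sigma"]), INSTANTANEOUS
        ),
        "a": GatingSpec(
            lambda v: sigmoid(v, d["a_theta"], d["a_sigma"]), INSTANTANEOUS
        ),
        "s": GatingSpec(
            lambda v: sigmoid(v, d["s_theta"], d["s_sigma"]), INSTANTANEOUS
        ),
    }
    for g in ("h", "n", "r"):
        tau = _sigmoid_tau(
            d[f"tau_{g}0"], d[f"tau_{g}1"], d[f"tau_{g}_theta"], d[f"tau_{g}_sigma"]
        )
        phi = d[f"phi_{g}"]
        gating[g] = GatingSpec(
            lambda v, g=g: sigmoid(v, d[f"{g}_theta"], d[f"{g}_sigma"]),
            lambda v, tau=tau, phi=phi: tau(v) / phi,
        )
    return CellParams(
        cell_type=kind,
        C_m=d["C_m"],
        g_L=d["g_L"],
        E_L=d["E_L"],
        g_Na=d["g_Na"],
        E_Na=d["E_Na"],
        g_K=d["g_K"],
        E_K=d["E_K"],
        g_T=d["g_T"],
        E_T=d["E_Ca"],
        g_Ca=d["g_Ca"],
        E_Ca=d["E_Ca"],
        g_AHP=d["g_AHP"],
        ahp_k1=d["ahp_k1"],
        ca_eps=d["ca_eps"],
        ca_k=d["ca_k"],
        gating=gating,
        raw=d,
    )


def load_reduced_params(name: str = "tc_reduced") -> ReducedTCParams:
    """Load the reduced two-variable thalamocortical parameter set."""
    d = _read_param_file(name)
    gating = {
        "p": GatingSpec(
            lambda v: sigmoid(v, d["p_theta"], d["p_sigma"]), INSTANTANEOUS
        ),
        "w": GatingSpec(
            lambda v: sigmoid(v, d["w_theta"], d["w_sigma"]),
            _exp_tau(
                d["tau_w_base"], d["tau_w_scale"], d["tau_w_theta"], d["tau_w_sigma"]
            ),
        ),
    }
    return ReducedTCParams(
        C_m=d["C_m"],
        g_L=d["g_L"],
        E_L=d["E_L"],
        g_T=d["g_T"],
        E_T=d["E_T"],
        g_GiTh=d["g_GiTh"],
        E_GiTh=d["E_GiTh"],
        phi=d["phi"],
        gating=gating,
        raw=d,
    )


def _check_finite(state) -> None:
    if not np.all(np.isfinite(state)):
        raise ValueError(f"non-finite state: {state!r}")


# ---------------------------------------------------------------------------
# Full TC cell, state [v, h, r, Ca]


def tc_full_currents(state, params: CellParams, I_SM=0.0, I_GiTh=0.0) -> dict:
    """Membrane currents of the full TC cell, outward positive.

    The returned dict sums (with external input ``I_SM`` entering with a
    minus sign) to ``-C_m * dv/dt``.
    """
    v, h, r = state[0], state[1], state[2]
    g = params.gating
    m = g["m"].steady_state(v)
    p = g["p"].steady_state(v)
    n = 0.75 * (1.0 - h)  # Rinzel substitution for the potassium gate
    return {
        "I_L": leak_current(v, params.g_L, params.E_L),
        "I_Na": params.g_Na * m**3 * h * (v - params.E_Na),
        "I_K": params.g_K * n**4 * (v - params.E_K),
        "I_T": params.g_T * p**2 * r * (v - params.E_T),
        "I_GiTh": I_GiTh,
        "I_SM": -I_SM,
    }


def tc_full_derivatives(state, params: CellParams, I_SM=0.0, I_GiTh=0.0):
    """State rate of the full TC cell for inputs ``I_SM`` (excitatory,
    depolarizing) and ``I_GiTh`` (inhibitory, outward positive)."""
    _check_finite(state)
    v, h, r = state[0], state[1], state[2]
    cur = tc_full_currents(state, params, I_SM=I_SM, I_GiTh=I_GiTh)
    dv = -sum(cur.values()) / params.C_m
    dh = gating_rate(h, params.gating["h"], v)
    dr = gating_rate(r, params.gating["r"], v)
    return np.array([dv, dh, dr, 0.0])


# ---------------------------------------------------------------------------
# STN / GPe / GPi family, state [v, h, n, r, Ca]


def pallidal_currents(state, params: CellParams, I_syn=0.0, I_ext=0.0) -> dict:
    """Membrane currents of an STN/GPe/GPi cell, outward positive.

    ``I_syn`` is the summed synaptic current (outward positive) and
    ``I_ext`` a depolarizing applied current (striatal drive enters as a
    negative ``I_ext`` for inhibition, DBS as positive drive on STN).
    """
    v, h, n, r, ca = state
    g = params.gating
    m = g["m"].steady_state(v)
    a = g["a"].steady_state(v)
    s = g["s"].steady_state(v)
    return {
        "I_L": leak_current(v, params.g_L, params.E_L),
        "I_Na": params.g_Na * m**3 * h * (v - params.E_Na),
        "I_K": params.g_K * n**4 * (v - params.E_K),
        "I_T": params.g_T * a**3 * r * (v - params.E_Ca),
        "I_Ca": params.g_Ca * s**2 * (v - params.E_Ca),
        "I_AHP": params.g_AHP * (v - params.E_K) * ca / (ca + params.ahp_k1),
        "I_syn": I_syn,
        "I_ext": -I_ext,
    }


def _pallidal_derivatives(state, params: CellParams, I_syn, I_ext):
    _check_finite(state)
    v, h, n, r, ca = state
    cur = pallidal_currents(state, params, I_syn=I_syn, I_ext=I_ext)
    dv = -sum(cur.values()) / params.C_m
    dh = gating_rate(h, params.gating["h"], v)
    dn = gating_rate(n, params.gating["n"], v)
    dr = gating_rate(r, params.gating["r"], v)
    dca = params.ca_eps * (-cur["I_Ca"] - cur["I_T"] - params.ca_k * ca)
    return np.array([dv, dh, dn, dr, dca])


def stn_derivatives(state, params: CellParams, I_GeSn=0.0, I_DBS=0.0):
    """STN state rate; ``I_GeSn`` is GPe inhibition (outward positive),
    ``I_DBS`` a depolarizing stimulation current."""
    return _pallidal_derivatives(state, params, I_syn=I_GeSn, I_ext=I_DBS)


def gpe_derivatives(state, params: CellParams, I_synaptic=0.0, I_app=0.0):
    """GPe/GPi state rate; ``I_app`` models striatal drive (positive
    depolarizes; inhibitory striatal input is a negative ``I_app``)."""
    return _pallidal_derivatives(state, params, I_syn=I_synaptic, I_ext=I_app)


# ---------------------------------------------------------------------------
# Reduced TC cell, state [v, w]


def reduced_tc_currents(state, params: ReducedTCParams, I_SM=0.0, s_Gi=0.0) -> dict:
    """Currents of the reduced TC cell, outward positive."""
    v, w = state[0], state[1]
    p = params.gating["p"].steady_state(v)
    return {
        "I_L": leak_current(v, params.g_L, params.E_L),
        "I_T": params.g_T * p**2 * w * (v - params.E_T),
        "I_GiTh": params.g_GiTh * s_Gi * (v - params.E_GiTh),
        "I_SM": -I_SM,
    }


def reduced_tc_derivatives(state, params: ReducedTCParams, I_SM=0.0, s_Gi=0.0):
    """Rates ``(dv/dt, dw/dt)`` of the reduced TC cell.

    ``s_Gi`` is the dimensionless GPi drive (must be >= 0); the
    inhibitory current it produces is conductance-based, so it
    fluctuates with ``v`` even for constant drive.
    """
    if np.any(np.asarray(s_Gi) < 0):
        raise ValueError("s_Gi must be >= 0")
    _check_finite(state)
    v, w = state[0], state[1]
    cur = reduced_tc_currents(state, params, I_SM=I_SM, s_Gi=s_Gi)
    dv = -sum(cur.values()) / params.C_m
    spec = params.gating["w"]
    dw = params.phi * (spec.steady_state(v) - w) / spec.time_constant(v)
    return np.array([dv, dw])


def reduced_nullclines(
    params: ReducedTCParams, s_Gi: float = 0.0, I_SM: float = 0.0, v_grid=None
):
    """Analytic nullclines of the reduced cell over ``v_grid``.

    Returns ``(v_grid, w_vnull, w_wnull)`` where the v-nullcline solves
    ``dv/dt = 0`` for ``w`` and the w-nullcline is ``w_inf(v)``.
    """
    if v_grid is None:
        v_grid = np.linspace(-95.0, -30.0, 261)
    v = np.asarray(v_grid, dtype=float)
    p = params.gating["p"].steady_state(v)
    denom = params.g_T * p**2 * (v - params.E_T)
    num = (
        I_SM
        - leak_current(v, params.g_L, params.E_L)
        - params.g_GiTh * s_Gi * (v - params.E_GiTh)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w_vnull = num / denom
    w_wnull = params.gating["w"].steady_state(v)
    return v, w_vnull, w_wnull
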