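"""Basal ganglia network assembly: topologies, synapses, regimes.

Three STN-GPe topologies are supported, all with periodic (ring)
boundary conditions for the structured kinds:

``sparse_random``
    Each STN neuron excites one random GPe cell; each GPe neuron
    inhibits three random STN cells; GPe-GPe coupling is all-to-all.
``sparse_structured``
    Each STN neuron excites the single closest GPe cell; each GPe
    neuron inhibits two STN cells, skipping the three closest (one on
    each side at ring distance 4); GPe inhibits its two immediate GPe
    neighbours.  Built to avoid direct reciprocal STN<->GPe pairs.
``tight_structured``
    Each STN neuron excites the three closest GPe cells; each GPe
    neuron inhibits the five closest STN cells; GPe-GPe all-to-all.

"Closest" is circular index distance, ties broken toward the lower
index; cell indices are 0-based.

The GPi receives STN excitation with the same footprint rule as the GPe
and projects to all TC cells (thalamic inhibition is the summed GPi
synaptic output scaled by the projection conductance).  The normal ->
parkinsonian regime switch applies exactly two changes: it increases
the (inhibitory) striatal drive onto the GPe and decreases the
intra-GPe conductance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from dbsloop import _kernels, cells
from dbsloop.engine import time_grid

__all__ = [
    "ConnectionMap",
    "RegimeSpec",
    "SynKinetics",
    "NORMAL",
    "PARKINSONIAN",
    "build_topology",
    "set_regime",
    "synapse_rate",
    "network_derivatives",
    "NetworkModel",
]

TOPOLOGY_KINDS = ("sparse_random", "sparse_structured", "tight_structured")

# default projection strengths (mS/cm^2) and reversals (mV)
DEFAULT_PROJECTIONS: Dict[str, Dict[str, float]] = {
    "stn_to_gpe": {"g": 0.7, "E": 0.0},
    "gpe_to_stn": {"g": 2.0, "E": -85.0},
    "gpe_to_gpe": {"g": 1.0, "E": -85.0},
    "stn_to_gpi": {"g": 1.0, "E": 0.0},
    "gpi_to_tc": {"g": 0.012, "E": -85.0},
}

#: baseline depolarizing bias on GPe/GPi (uA/cm^2); a regime's striatal
#: drive (inhibitory) is subtracted from the GPe bias.
GPE_BIAS = 1.0
GPI_BIAS = 0.0


@dataclass(frozen=True)
class SynKinetics:
    """First-order synapse: ds/dt = alpha*H(v_pre)*(1-s) - beta*s with
    H a steep sigmoid of the presynaptic voltage."""

    alpha: float = 2.0
    beta: float = 0.08
    theta: float = -20.0
    sigma: float = 2.0


# per-population kinetics of the output synapse; the excitatory STN
# synapse decays faster than the pallidal GABAergic ones
DEFAULT_KINETICS: Dict[str, SynKinetics] = {
    "stn": SynKinetics(alpha=2.0, beta=0.18),
    "gpe": SynKinetics(alpha=2.0, beta=0.08),
    "gpi": SynKinetics(alpha=2.0, beta=0.08),
}


@dataclass(frozen=True)
class RegimeSpec:
    """Striatal drive level and intra-GPe conductance scale of a regime."""

    label: str
    striatal_drive: float  # uA/cm^2, inhibitory magnitude onto GPe
    gpe_gpe_scale: float  # multiplies the baseline GPe-GPe conductance


NORMAL = RegimeSpec(label="normal", striatal_drive=0.0, gpe_gpe_scale=1.0)
PARKINSONIAN = RegimeSpec(label="parkinsonian", striatal_drive=1.5, gpe_gpe_scale=0.1)


@dataclass
class ConnectionMap:
    """Boolean adjacency per projection plus projection parameters.

    Convention: ``stn_to_gpe[i, j]`` is True when STN cell i excites
    GPe cell j (row = presynaptic).
    """

    n_stn: int
    n_gpe: int
    n_gpi: int
    n_tc: int
    kind: str
    seed: int
    stn_to_gpe: np.ndarray
    gpe_to_stn: np.ndarray
    gpe_to_gpe: np.ndarray
    stn_to_gpi: np.ndarray
    gpi_to_tc: np.ndarray
    projections: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROJECTIONS.items()}
    )

    def __post_init__(self):
        if np.any(np.diag(self.gpe_to_gpe)):
            raise ValueError("GPe-GPe self-connections are not allowed")
        shapes = {
            "stn_to_gpe": (self.n_stn, self.n_gpe),
            "gpe_to_stn": (self.n_gpe, self.n_stn),
            "gpe_to_gpe": (self.n_gpe, self.n_gpe),
            "stn_to_gpi": (self.n_stn, self.n_gpi),
            "gpi_to_tc": (self.n_gpi, self.n_tc),
        }
        for name, shape in shapes.items():
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"adjacency {name} has shape {getattr(self, name).shape}, "
                    f"expected {shape}"
                )

    def to_dict(self) -> dict:
        def idx(adj):
            return [sorted(map(int, np.flatnonzero(row))) for row in adj]

        return {
            "n_stn": self.n_stn,
            "n_gpe": self.n_gpe,
            "n_gpi": self.n_gpi,
            "n_tc": self.n_tc,
            "kind": self.kind,
            "seed": self.seed,
            "stn_to_gpe": idx(self.stn_to_gpe),
            "gpe_to_stn": idx(self.gpe_to_stn),
            "gpe_to_gpe": idx(self.gpe_to_gpe),
            "stn_to_gpi": idx(self.stn_to_gpi),
            "gpi_to_tc": idx(self.gpi_to_tc),
            "projections": {k: dict(v) for k, v in self.projections.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectionMap":
        def adj(rows, n_pre, n_post):
            a = np.zeros((n_pre, n_post), dtype=bool)
            for i, cols in enumerate(rows):
                a[i, cols] = True
            return a

        return cls(
            n_stn=d["n_stn"],
            n_gpe=d["n_gpe"],
            n_gpi=d["n_gpi"],
            n_tc=d["n_tc"],
            kind=d["kind"],
            seed=d["seed"],
            stn_to_gpe=adj(d["stn_to_gpe"], d["n_stn"], d["n_gpe"]),
            gpe_to_stn=adj(d["gpe_to_stn"], d["n_gpe"], d["n_stn"]),
            gpe_to_gpe=adj(d["gpe_to_gpe"], d["n_gpe"], d["n_gpe"]),
            stn_to_gpi=adj(d["stn_to_gpi"], d["n_stn"], d["n_gpi"]),
            gpi_to_tc=adj(d["gpi_to_tc"], d["n_gpi"], d["n_tc"]),
            projections={k: dict(v) for k, v in d["projections"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConnectionMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _ring_closest(center: int, n: int, k: int) -> np.ndarray:
    """Indices of the k cells closest to ``center`` on a ring of n
    (center included); ties broken toward the lower index."""
    offsets = sorted(range(-(n // 2), n - n // 2), key=lambda o: (abs(o), o))
    return np.array([(center + o) % n for o in offsets[:k]], dtype=int)


def build_topology(
    n_stn: int,
    n_gpe: int,
    kind: str,
    seed: int = 0,
    n_gpi: Optional[int] = None,
    n_tc: int = 2,
) -> ConnectionMap:
    """Build one of the three STN-GPe topologies (plus GPi/TC stages).

    Structured kinds require ``n_stn == n_gpe >= 8`` (ring
    constructions with the skip rule).  Identical arguments and seed
    give an identical map.
    """
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"unknown topology kind {kind!r}")
    if n_gpi is None:
        n_gpi = n_gpe
    if kind != "sparse_random":
        if n_stn != n_gpe:
            raise ValueError("structured topologies require n_stn == n_gpe")
        if n_stn < 8:
            raise ValueError("structured topologies require n >= 8 (skip rule)")
    rng = np.random.default_rng(seed)
    sg = np.zeros((n_stn, n_gpe), dtype=bool)
    gs = np.zeros((n_gpe, n_stn), dtype=bool)
    gg = np.zeros((n_gpe, n_gpe), dtype=bool)
    if kind == "sparse_random":
        for i in range(n_stn):
            sg[i, rng.integers(n_gpe)] = True
        for j in range(n_gpe):
            gs[j, rng.choice(n_stn, size=3, replace=False)] = True
        gg[:] = True
        np.fill_diagonal(gg, False)
    elif kind == "sparse_structured":
        for i in range(n_stn):
            sg[i, i] = True  # the single closest GPe
        for j in range(n_gpe):
            # two STN targets, one per side, skipping the three closest
            gs[j, (j - 4) % n_stn] = True
            gs[j, (j + 4) % n_stn] = True
            gg[j, (j - 1) % n_gpe] = True
            gg[j, (j + 1) % n_gpe] = True
    else:  # tight_structured
        for i in range(n_stn):
            sg[i, _ring_closest(i, n_gpe, 3)] = True
        for j in range(n_gpe):
            gs[j, _ring_closest(j, n_stn, 5)] = True
        gg[:] = True
        np.fill_diagonal(gg, False)

    # GPi receives STN excitation with the same footprint rule as GPe
    if n_gpi == n_gpe:
        sgi = sg.copy()
    else:
        sgi = np.zeros((n_stn, n_gpi), dtype=bool)
        for i in range(n_stn):
            sgi[i, rng.integers(n_gpi)] = True
    git = np.ones((n_gpi, n_tc), dtype=bool)  # summed GPi output to every TC
    return ConnectionMap(
        n_stn=n_stn,
        n_gpe=n_gpe,
        n_gpi=n_gpi,
        n_tc=n_tc,
        kind=kind,
        seed=seed,
        stn_to_gpe=sg,
        gpe_to_stn=gs,
        gpe_to_gpe=gg,
        stn_to_gpi=sgi,
        gpi_to_tc=git,
    )


def set_regime(cm: ConnectionMap, regime: RegimeSpec):
    """Apply a regime to a map and its drives.

    Returns ``(map, drives)``: the map's GPe-GPe conductance is scaled
    from the baseline and ``drives`` holds the applied currents
    ``I_app_gpe``/``I_app_gpi``.  Exactly the two regime quantities
    change; everything else is untouched.
    """
    projections = {k: dict(v) for k, v in cm.projections.items()}
    projections["gpe_to_gpe"]["g"] = (
        DEFAULT_PROJECTIONS["gpe_to_gpe"]["g"] * regime.gpe_gpe_scale
    )
    new = replace(cm, projections=projections)
    drives = {
        "I_app_gpe": GPE_BIAS - regime.striatal_drive,
        "I_app_gpi": GPI_BIAS,
    }
    return new, drives


def synapse_rate(s, v_pre, kin: SynKinetics):
    """ds/dt of the first-order synapse; keeps s in [0, 1]."""
    h = 1.0 / (1.0 + np.exp(-(v_pre - kin.theta) / kin.sigma))
    return kin.alpha * h * (1.0 - s) - kin.beta * s


def network_derivatives(
    state: dict,
    cm: ConnectionMap,
    drives: dict,
    kinetics: Optional[Dict[str, SynKinetics]] = None,
    i_dbs: float = 0.0,
    i_sm: float = 0.0,
) -> dict:
    """Reference (pure NumPy) network right-hand side.

    ``state`` holds arrays ``stn``/``gpe``/``gpi`` of shape (n, 6)
    ([v, h, n, r, Ca, s]) and ``tc`` of shape (n, 4) ([v, h, r, s]).
    Synaptic current into a cell is the projection conductance times
    the sum of presynaptic s times (v_post - E).  With all projection
    conductances zero this is the concatenation of isolated per-cell
    derivatives.  The compiled integrator is pinned against this
    function in the test suite.
    """
    kin = kinetics or DEFAULT_KINETICS
    p = {k: cells.load_cell_params(k) for k in ("stn", "gpe", "gpi")}
    p_tc = cells.load_cell_params("tc_full")
    pr = cm.projections
    stn, gpe, gpi, tc = state["stn"], state["gpe"], state["gpi"], state["tc"]
    out = {k: np.zeros_like(v) for k, v in state.items()}
    for j in range(cm.n_stn):
        pre = np.flatnonzero(cm.gpe_to_stn[:, j])
        isyn = pr["gpe_to_stn"]["g"] * np.sum(gpe[pre, 5]) * (
            stn[j, 0] - pr["gpe_to_stn"]["E"]
        )
        out["stn"][j, :5] = cells.stn_derivatives(stn[j, :5], p["stn"], isyn, i_dbs)
        out["stn"][j, 5] = synapse_rate(stn[j, 5], stn[j, 0], kin["stn"])
    for j in range(cm.n_gpe):
        pre_s = np.flatnonzero(cm.stn_to_gpe[:, j])
        pre_g = np.flatnonzero(cm.gpe_to_gpe[:, j])
        isyn = pr["stn_to_gpe"]["g"] * np.sum(stn[pre_s, 5]) * (
            gpe[j, 0] - pr["stn_to_gpe"]["E"]
        ) + pr["gpe_to_gpe"]["g"] * np.sum(gpe[pre_g, 5]) * (
            gpe[j, 0] - pr["gpe_to_gpe"]["E"]
        )
        out["gpe"][j, :5] = cells.gpe_derivatives(
            gpe[j, :5], p["gpe"], isyn, drives["I_app_gpe"]
        )
        out["gpe"][j, 5] = synapse_rate(gpe[j, 5], gpe[j, 0], kin["gpe"])
    for j in range(cm.n_gpi):
        pre = np.flatnonzero(cm.stn_to_gpi[:, j])
        isyn = pr["stn_to_gpi"]["g"] * np.sum(stn[pre, 5]) * (
            gpi[j, 0] - pr["stn_to_gpi"]["E"]
        )
        out["gpi"][j, :5] = cells.gpe_derivatives(
            gpi[j, :5], p["gpi"], isyn, drives["I_app_gpi"]
        )
        out["gpi"][j, 5] = synapse_rate(gpi[j, 5], gpi[j, 0], kin["gpi"])
    for j in range(cm.n_tc):
        pre = np.flatnonzero(cm.gpi_to_tc[:, j])
        igith = pr["gpi_to_tc"]["g"] * np.sum(gpi[pre, 5]) * (
            tc[j, 0] - pr["gpi_to_tc"]["E"]
        )
        d4 = cells.tc_full_derivatives(
            np.array([tc[j, 0], tc[j, 1], tc[j, 2], 0.0]), p_tc, i_sm, igith
        )
        out["tc"][j, :3] = d4[:3]
        out["tc"][j, 3] = 0.0
    return out


class NetworkModel:
    """Packs cell parameters, a ConnectionMap and regime drives into the
    compiled network integrator."""

    def __init__(
        self,
        cm: ConnectionMap,
        regime: RegimeSpec = NORMAL,
        kinetics: Optional[Dict[str, SynKinetics]] = None,
    ):
        self.cm, self.drives = set_regime(cm, regime)
        self.regime = regime
        self.kinetics = kinetics or DEFAULT_KINETICS
        self.p_stn = _kernels.pallidal_param_array(cells.load_cell_params("stn"))
        self.p_gpe = _kernels.pallidal_param_array(cells.load_cell_params("gpe"))
        self.p_gpi = _kernels.pallidal_param_array(cells.load_cell_params("gpi"))
        self.p_tc = _kernels.tc_param_array(cells.load_cell_params("tc_full"))

    @staticmethod
    def _csr(adj_pre_post: np.ndarray):
        """Postsynaptic-major (indptr, indices) of a pre x post matrix."""
        post = adj_pre_post.T
        indptr = np.zeros(post.shape[0] + 1, dtype=np.int64)
        idx: list = []
        for j in range(post.shape[0]):
            idx.extend(np.flatnonzero(post[j]))
            indptr[j + 1] = len(idx)
        return indptr, np.asarray(idx, dtype=np.int64)

    def initial_state(self, seed: int = 0):
        rng = np.random.default_rng(seed)

        def pop(n):
            st = np.empty((n, 6))
            st[:, 0] = -62.0 + 8.0 * rng.random(n)
            st[:, 1] = 0.6
            st[:, 2] = 0.2
            st[:, 3] = 0.2
            st[:, 4] = 0.1
            st[:, 5] = 0.0
            return st

        tc = np.empty((self.cm.n_tc, 4))
        tc[:, 0] = -70.0
        tc[:, 1] = 0.95
        tc[:, 2] = 0.05
        tc[:, 3] = 0.0
        return pop(self.cm.n_stn), pop(self.cm.n_gpe), pop(self.cm.n_gpi), tc

    def simulate(
        self,
        duration: float,
        dt: float = 0.01,
        seed: int = 0,
        i_dbs: Optional[np.ndarray] = None,
        i_sm: Optional[np.ndarray] = None,
        record_stride: int = 10,
        state=None,
    ) -> dict:
        """Integrate the network, recording every ``record_stride``
        steps; returns voltage matrices per population plus the summed
        GPi synaptic output (the thalamic inhibition waveform)."""
        t = time_grid(duration, dt)
        n = len(t)
        zeros = np.zeros(n)
        i_dbs = zeros if i_dbs is None else np.asarray(i_dbs, dtype=float)
        i_sm = zeros if i_sm is None else np.asarray(i_sm, dtype=float)
        if len(i_dbs) < n or len(i_sm) < n:
            raise ValueError("input traces do not cover the duration")
        stn, gpe, gpi, tc = state if state is not None else self.initial_state(seed)
        pr = self.cm.projections
        kin = self.kinetics
        syn_par = np.array(
            [
                [kin["stn"].alpha, kin["stn"].beta, kin["stn"].theta, kin["stn"].sigma],
                [kin["gpe"].alpha, kin["gpe"].beta, kin["gpe"].theta, kin["gpe"].sigma],
                [kin["gpi"].alpha, kin["gpi"].beta, kin["gpi"].theta, kin["gpi"].sigma],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        sg_ptr, sg_idx = self._csr(self.cm.stn_to_gpe)
        gs_ptr, gs_idx = self._csr(self.cm.gpe_to_stn)
        gg_ptr, gg_idx = self._csr(self.cm.gpe_to_gpe)
        sgi_ptr, sgi_idx = self._csr(self.cm.stn_to_gpi)
        git_ptr, git_idx = self._csr(self.cm.gpi_to_tc)
        v_stn, v_gpe, v_gpi, v_tc, s_gpi = _kernels.simulate_network(
            stn, gpe, gpi, tc,
            self.p_stn, self.p_gpe, self.p_gpi, self.p_tc,
            sg_ptr, sg_idx, gs_ptr, gs_idx, gg_ptr, gg_idx,
            sgi_ptr, sgi_idx, git_ptr, git_idx,
            pr["stn_to_gpe"]["g"], pr["stn_to_gpe"]["E"],
            pr["gpe_to_stn"]["g"], pr["gpe_to_stn"]["E"],
            pr["gpe_to_gpe"]["g"], pr["gpe_to_gpe"]["E"],
            pr["stn_to_gpi"]["g"], pr["stn_to_gpi"]["E"],
            pr["gpi_to_tc"]["g"], pr["gpi_to_tc"]["E"],
            syn_par,
            np.full(n, self.drives["I_app_gpe"]),
            np.full(n, self.drives["I_app_gpi"]),
            i_dbs, i_sm, dt, record_stride,
        )
        return {
            "t": t[::record_stride],
            "v_stn": v_stn,
            "v_gpe": v_gpe,
            "v_gpi": v_gpi,
            "v_tc": v_tc,
            "s_gpi_sum": s_gpi,
            "final_state": (stn, gpe, gpi, tc),
        }
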