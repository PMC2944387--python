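"""Numba-compiled numerical cores.

These kernels mirror the reference right-hand sides in
:mod:`dbsloop.cells` (consistency is asserted by the test suite) and
provide the fixed-step RK4 loops used by long simulations, the network
integrator and the closed-loop filter.  Parameters travel as flat
float64 arrays with layouts fixed by the ``*_PAR`` builders below.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter flattening

_TC_KEYS = [
    "C_m", "g_L", "E_L", "g_Na", "E_Na", "g_K", "E_K", "g_T", "E_T",
    "m_theta", "m_sigma", "h_theta", "h_sigma",
    "h_a_scale", "h_a_theta", "h_a_sigma", "h_b_scale", "h_b_theta", "h_b_sigma",
    "p_theta", "p_sigma", "r_theta", "r_sigma",
    "tau_r_base", "tau_r_scale", "tau_r_theta", "tau_r_sigma", "phi_r",
]

_PAL_KEYS = [
    "C_m", "g_L", "E_L", "g_Na", "E_Na", "g_K", "E_K", "g_T", "g_Ca", "E_Ca",
    "g_AHP", "ahp_k1", "ca_eps", "ca_k",
    "m_theta", "m_sigma", "h_theta", "h_sigma", "n_theta", "n_sigma",
    "r_theta", "r_sigma", "a_theta", "a_sigma", "s_theta", "s_sigma",
    "tau_h0", "tau_h1", "tau_h_theta", "tau_h_sigma",
    "tau_n0", "tau_n1", "tau_n_theta", "tau_n_sigma",
    "tau_r0", "tau_r1", "tau_r_theta", "tau_r_sigma",
    "phi_h", "phi_n", "phi_r",
]

_RED_KEYS = [
    "C_m", "g_L", "E_L", "g_T", "E_T", "g_GiTh", "E_GiTh",
    "p_theta", "p_sigma", "w_theta", "w_sigma",
    "tau_w_base", "tau_w_scale", "tau_w_theta", "tau_w_sigma", "phi",
]


def tc_param_array(params) -> np.ndarray:
    return np.array([params.raw[k] for k in _TC_KEYS], dtype=np.float64)


def pallidal_param_array(params) -> np.ndarray:
    return np.array([params.raw[k] for k in _PAL_KEYS], dtype=np.float64)


def reduced_param_array(params) -> np.ndarray:
    return np.array([params.raw[k] for k in _RED_KEYS], dtype=np.float64)


# ---------------------------------------------------------------------------
# elementary pieces


@njit(cache=True)
def _sig(v, th, sg):
    return 1.0 / (1.0 + np.exp(-(v - th) / sg))


@njit(cache=True)
def tc_rhs(v, h, r, p, ism, igith):
    """Full TC cell rates (dv, dh, dr)."""
    m = _sig(v, p[9], p[10])
    hinf = _sig(v, p[11], p[12])
    a = p[13] * np.exp(-(v - p[14]) / p[15])
    b = p[16] / (1.0 + np.exp(-(v - p[17]) / p[18]))
    tauh = 1.0 / (a + b)
    pp = _sig(v, p[19], p[20])
    rinf = _sig(v, p[21], p[22])
    taur = (p[23] + p[24] * np.exp(-(v - p[25]) / p[26])) / p[27]
    n = 0.75 * (1.0 - h)
    il = p[1] * (v - p[2])
    ina = p[3] * m**3 * h * (v - p[4])
    ik = p[5] * n**4 * (v - p[6])
    it = p[7] * pp * pp * r * (v - p[8])
    dv = (-il - ina - ik - it - igith + ism) / p[0]
    dh = (hinf - h) / tauh
    dr = (rinf - r) / taur
    return dv, dh, dr


@njit(cache=True)
def pal_rhs(v, h, n, r, ca, p, isyn, iext):
    """STN/GPe/GPi cell rates (dv, dh, dn, dr, dca)."""
    m = _sig(v, p[14], p[15])
    hinf = _sig(v, p[16], p[17])
    ninf = _sig(v, p[18], p[19])
    rinf = _sig(v, p[20], p[21])
    a = _sig(v, p[22], p[23])
    s = _sig(v, p[24], p[25])
    tauh = (p[26] + p[27] / (1.0 + np.exp(-(v - p[28]) / p[29]))) / p[38]
    taun = (p[30] + p[31] / (1.0 + np.exp(-(v - p[32]) / p[33]))) / p[39]
    taur = (p[34] + p[35] / (1.0 + np.exp(-(v - p[36]) / p[37]))) / p[40]
    il = p[1] * (v - p[2])
    ina = p[3] * m**3 * h * (v - p[4])
    ik = p[5] * n**4 * (v - p[6])
    it = p[7] * a**3 * r * (v - p[9])
    ica = p[8] * s * s * (v - p[9])
    iahp = p[10] * (v - p[6]) * ca / (ca + p[11])
    dv = (-il - ina - ik - it - ica - iahp - isyn + iext) / p[0]
    dh = (hinf - h) / tauh
    dn = (ninf - n) / taun
    dr = (rinf - r) / taur
    dca = p[12] * (-ica - it - p[13] * ca)
    return dv, dh, dn, dr, dca


@njit(cache=True)
def reduced_rhs(v, w, p, ism, sgi):
    """Reduced TC cell rates (dv, dw)."""
    pp = _sig(v, p[7], p[8])
    winf = _sig(v, p[9], p[10])
    tauw = p[11] + p[12] * np.exp(-(v - p[13]) / p[14])
    il = p[1] * (v - p[2])
    it = p[3] * pp * pp * w * (v - p[4])
    igith = p[5] * sgi * (v - p[6])
    dv = (-il - it - igith + ism) / p[0]
    dw = p[15] * (winf - w) / tauw
    return dv, dw


# ---------------------------------------------------------------------------
# single-cell simulation loops (RK4, zero-order-hold inputs)


@njit(cache=True)
def simulate_tc_full(x0, p, ism, igith, dt):
    n = ism.shape[0]
    out = np.empty((n, 3))
    v, h, r = x0[0], x0[1], x0[2]
    out[0, 0], out[0, 1], out[0, 2] = v, h, r
    for i in range(n - 1):
        u1, u2 = ism[i], igith[i]
        k1v, k1h, k1r = tc_rhs(v, h, r, p, u1, u2)
        k2v, k2h, k2r = tc_rhs(v + 0.5 * dt * k1v, h + 0.5 * dt * k1h, r + 0.5 * dt * k1r, p, u1, u2)
        k3v, k3h, k3r = tc_rhs(v + 0.5 * dt * k2v, h + 0.5 * dt * k2h, r + 0.5 * dt * k2r, p, u1, u2)
        k4v, k4h, k4r = tc_rhs(v + dt * k3v, h + dt * k3h, r + dt * k3r, p, u1, u2)
        v += dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        h += dt / 6.0 * (k1h + 2 * k2h + 2 * k3h + k4h)
        r += dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        out[i + 1, 0], out[i + 1, 1], out[i + 1, 2] = v, h, r
    return out


@njit(cache=True)
def simulate_pallidal(x0, p, isyn, iext, dt):
    n = isyn.shape[0]
    out = np.empty((n, 5))
    v, h, nn, r, ca = x0[0], x0[1], x0[2], x0[3], x0[4]
    for j in range(5):
        out[0, j] = x0[j]
    for i in range(n - 1):
        u1, u2 = isyn[i], iext[i]
        k1 = pal_rhs(v, h, nn, r, ca, p, u1, u2)
        k2 = pal_rhs(v + 0.5 * dt * k1[0], h + 0.5 * dt * k1[1], nn + 0.5 * dt * k1[2], r + 0.5 * dt * k1[3], ca + 0.5 * dt * k1[4], p, u1, u2)
        k3 = pal_rhs(v + 0.5 * dt * k2[0], h + 0.5 * dt * k2[1], nn + 0.5 * dt * k2[2], r + 0.5 * dt * k2[3], ca + 0.5 * dt * k2[4], p, u1, u2)
        k4 = pal_rhs(v + dt * k3[0], h + dt * k3[1], nn + dt * k3[2], r + dt * k3[3], ca + dt * k3[4], p, u1, u2)
        v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        h += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        nn += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        r += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        ca += dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        out[i + 1, 0] = v
        out[i + 1, 1] = h
        out[i + 1, 2] = nn
        out[i + 1, 3] = r
        out[i + 1, 4] = ca
    return out


@njit(cache=True)
def simulate_reduced(x0, p, ism, sgi, dt):
    n = ism.shape[0]
    out = np.empty((n, 2))
    v, w = x0[0], x0[1]
    out[0, 0], out[0, 1] = v, w
    for i in range(n - 1):
        u1, u2 = ism[i], sgi[i]
        k1v, k1w = reduced_rhs(v, w, p, u1, u2)
        k2v, k2w = reduced_rhs(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w, p, u1, u2)
        k3v, k3w = reduced_rhs(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w, p, u1, u2)
        k4v, k4w = reduced_rhs(v + dt * k3v, w + dt * k3w, p, u1, u2)
        v += dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        w += dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        out[i + 1, 0] = v
        out[i + 1, 1] = w
    return out


# ---------------------------------------------------------------------------
# synapses: first-order activation gated by presynaptic voltage
# ds/dt = alpha * H(v_pre) * (1 - s) - beta * s, H a steep sigmoid


@njit(cache=True)
def syn_rate(s, v_pre, alpha, beta, theta, sigma):
    hh = 1.0 / (1.0 + np.exp(-(v_pre - theta) / sigma))
    return alpha * hh * (1.0 - s) - beta * s


# ---------------------------------------------------------------------------
# full network integrator
#
# State layout: for each population (STN, GPe, GPi) arrays of
# (v, h, n, r, ca, s_out); TC cells (v, h, r).  Connectivity is passed
# as flat index lists with row pointers (CSR-like): for each
# postsynaptic cell, the presynaptic indices that project to it.


@njit(cache=True)
def network_step(
    stn, gpe, gpi, tc,
    p_stn, p_gpe, p_gpi, p_tc,
    # adjacency: indptr/indices pairs, postsynaptic-major
    sg_ptr, sg_idx,   # STN -> GPe (per GPe cell, STN sources)
    gs_ptr, gs_idx,   # GPe -> STN
    gg_ptr, gg_idx,   # GPe -> GPe
    sgi_ptr, sgi_idx, # STN -> GPi
    git_ptr, git_idx, # GPi -> TC
    g_sg, e_sg, g_gs, e_gs, g_gg, e_gg, g_sgi, e_sgi, g_git, e_git,
    syn_par,  # (4, 4): alpha, beta, theta, sigma rows for STN, GPe, GPi exc/inh kin
    iapp_gpe, iapp_gpi, idbs, ism_tc,
    dt,
):
    """One RK4 step of the whole network, in-place on the state arrays.

    ``stn``: (n_stn, 6) [v,h,n,r,ca,s]; ``gpe``/``gpi`` same; ``tc``:
    (n_tc, 4) [v,h,r,s].  Scalar inputs are per-step zero-order-hold
    values (``iapp_*`` striatal drives, ``idbs`` on STN, ``ism_tc`` the
    sensorimotor drive shared by all TC cells).
    """
    n_stn = stn.shape[0]
    n_gpe = gpe.shape[0]
    n_gpi = gpi.shape[0]
    n_tc = tc.shape[0]

    k_stn = np.empty((4, n_stn, 6))
    k_gpe = np.empty((4, n_gpe, 6))
    k_gpi = np.empty((4, n_gpi, 6))
    k_tc = np.empty((4, n_tc, 4))

    stn0 = stn.copy()
    gpe0 = gpe.copy()
    gpi0 = gpi.copy()
    tc0 = tc.copy()

    for stage in range(4):
        if stage == 0:
            cs, cg, ci, ct = stn0, gpe0, gpi0, tc0
        else:
            if stage == 3:
                f = dt
            else:
                f = 0.5 * dt
            cs = stn0 + f * k_stn[stage - 1]
            cg = gpe0 + f * k_gpe[stage - 1]
            ci = gpi0 + f * k_gpi[stage - 1]
            ct = tc0 + f * k_tc[stage - 1]

        # STN cells: inhibition from GPe
        for j in range(n_stn):
            isyn = 0.0
            for q in range(gs_ptr[j], gs_ptr[j + 1]):
                isyn += cg[gs_idx[q], 5] * (cs[j, 0] - e_gs)
            isyn *= g_gs
            dv, dh, dn, dr, dca = pal_rhs(
                cs[j, 0], cs[j, 1], cs[j, 2], cs[j, 3], cs[j, 4], p_stn, isyn, idbs
            )
            k_stn[stage, j, 0] = dv
            k_stn[stage, j, 1] = dh
            k_stn[stage, j, 2] = dn
            k_stn[stage, j, 3] = dr
            k_stn[stage, j, 4] = dca
            k_stn[stage, j, 5] = syn_rate(
                cs[j, 5], cs[j, 0], syn_par[0, 0], syn_par[0, 1], syn_par[0, 2], syn_par[0, 3]
            )

        # GPe cells: excitation from STN, inhibition from GPe
        for j in range(n_gpe):
            isyn = 0.0
            for q in range(sg_ptr[j], sg_ptr[j + 1]):
                isyn += g_sg * cs[sg_idx[q], 5] * (cg[j, 0] - e_sg)
            for q in range(gg_ptr[j], gg_ptr[j + 1]):
                isyn += g_gg * cg[gg_idx[q], 5] * (cg[j, 0] - e_gg)
            dv, dh, dn, dr, dca = pal_rhs(
                cg[j, 0], cg[j, 1], cg[j, 2], cg[j, 3], cg[j, 4], p_gpe, isyn, iapp_gpe
            )
            k_gpe[stage, j, 0] = dv
            k_gpe[stage, j, 1] = dh
            k_gpe[stage, j, 2] = dn
            k_gpe[stage, j, 3] = dr
            k_gpe[stage, j, 4] = dca
            k_gpe[stage, j, 5] = syn_rate(
                cg[j, 5], cg[j, 0], syn_par[1, 0], syn_par[1, 1], syn_par[1, 2], syn_par[1, 3]
            )

        # GPi cells: excitation from STN
        for j in range(n_gpi):
            isyn = 0.0
            for q in range(sgi_ptr[j], sgi_ptr[j + 1]):
                isyn += g_sgi * cs[sgi_idx[q], 5] * (ci[j, 0] - e_sgi)
            dv, dh, dn, dr, dca = pal_rhs(
                ci[j, 0], ci[j, 1], ci[j, 2], ci[j, 3], ci[j, 4], p_gpi, isyn, iapp_gpi
            )
            k_gpi[stage, j, 0] = dv
            k_gpi[stage, j, 1] = dh
            k_gpi[stage, j, 2] = dn
            k_gpi[stage, j, 3] = dr
            k_gpi[stage, j, 4] = dca
            k_gpi[stage, j, 5] = syn_rate(
                ci[j, 5], ci[j, 0], syn_par[2, 0], syn_par[2, 1], syn_par[2, 2], syn_par[2, 3]
            )

        # TC cells: inhibition from GPi, shared sensorimotor drive
        for j in range(n_tc):
            igith = 0.0
            for q in range(git_ptr[j], git_ptr[j + 1]):
                igith += g_git * ci[git_idx[q], 5] * (ct[j, 0] - e_git)
            dv, dh, dr = tc_rhs(ct[j, 0], ct[j, 1], ct[j, 2], p_tc, ism_tc, igith)
            k_tc[stage, j, 0] = dv
            k_tc[stage, j, 1] = dh
            k_tc[stage, j, 2] = dr
            k_tc[stage, j, 3] = 0.0

    for j in range(n_stn):
        for c in range(6):
            stn[j, c] += dt / 6.0 * (
                k_stn[0, j, c] + 2 * k_stn[1, j, c] + 2 * k_stn[2, j, c] + k_stn[3, j, c]
            )
    for j in range(n_gpe):
        for c in range(6):
            gpe[j, c] += dt / 6.0 * (
                k_gpe[0, j, c] + 2 * k_gpe[1, j, c] + 2 * k_gpe[2, j, c] + k_gpe[3, j, c]
            )
    for j in range(n_gpi):
        for c in range(6):
            gpi[j, c] += dt / 6.0 * (
                k_gpi[0, j, c] + 2 * k_gpi[1, j, c] + 2 * k_gpi[2, j, c] + k_gpi[3, j, c]
            )
    for j in range(n_tc):
        for c in range(4):
            tc[j, c] += dt / 6.0 * (
                k_tc[0, j, c] + 2 * k_tc[1, j, c] + 2 * k_tc[2, j, c] + k_tc[3, j, c]
            )


@njit(cache=True)
def simulate_network(
    stn, gpe, gpi, tc,
    p_stn, p_gpe, p_gpi, p_tc,
    sg_ptr, sg_idx, gs_ptr, gs_idx, gg_ptr, gg_idx,
    sgi_ptr, sgi_idx, git_ptr, git_idx,
    g_sg, e_sg, g_gs, e_gs, g_gg, e_gg, g_sgi, e_sgi, g_git, e_git,
    syn_par,
    iapp_gpe, iapp_gpi, idbs, ism_tc,
    dt, record_stride,
):
    """Integrate the network, recording every ``record_stride`` steps.

    ``iapp_gpe``/``iapp_gpi``/``idbs``/``ism_tc`` are per-step input
    arrays of length n_steps.  Returns (v_stn, v_gpe, v_gpi, v_tc,
    s_gpi_sum) sampled on the recording grid.
    """
    n_steps = ism_tc.shape[0]
    n_rec = (n_steps - 1) // record_stride + 1
    v_stn = np.empty((n_rec, stn.shape[0]))
    v_gpe = np.empty((n_rec, gpe.shape[0]))
    v_gpi = np.empty((n_rec, gpi.shape[0]))
    v_tc = np.empty((n_rec, tc.shape[0]))
    s_gpi = np.empty(n_rec)
    rec = 0
    for i in range(n_steps):
        if i % record_stride == 0:
            v_stn[rec] = stn[:, 0]
            v_gpe[rec] = gpe[:, 0]
            v_gpi[rec] = gpi[:, 0]
            v_tc[rec] = tc[:, 0]
            s_gpi[rec] = gpi[:, 5].sum()
            rec += 1
        if i == n_steps - 1:
            break
        network_step(
            stn, gpe, gpi, tc, p_stn, p_gpe, p_gpi, p_tc,
            sg_ptr, sg_idx, gs_ptr, gs_idx, gg_ptr, gg_idx,
            sgi_ptr, sgi_idx, git_ptr, git_idx,
            g_sg, e_sg, g_gs, e_gs, g_gg, e_gg, g_sgi, e_sgi, g_git, e_git,
            syn_par, iapp_gpe[i], iapp_gpi[i], idbs[i], ism_tc[i], dt,
        )
    return v_stn, v_gpe, v_gpi, v_tc, s_gpi


# ---------------------------------------------------------------------------
# sigma-point propagation through the reduced model


@njit(cache=True)
def propagate_sigma_reduced(X, p, dt, nsub):
    """Propagate augmented sigma points [v, w, s_Gi, I_SM] in place.

    The drive and input components follow random-walk dynamics (held
    constant over the step); negative drive values are treated as zero
    inside the model, matching the physical constraint s_Gi >= 0.
    """
    m = X.shape[0]
    for k in range(m):
        v = X[k, 0]
        w = X[k, 1]
        sgi = X[k, 2]
        if sgi < 0.0:
            sgi = 0.0
        ism = X[k, 3]
        for _ in range(nsub):
            k1v, k1w = reduced_rhs(v, w, p, ism, sgi)
            k2v, k2w = reduced_rhs(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w, p, ism, sgi)
            k3v, k3w = reduced_rhs(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w, p, ism, sgi)
            k4v, k4w = reduced_rhs(v + dt * k3v, w + dt * k3w, p, ism, sgi)
            v += dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
            w += dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        X[k, 0] = v
        X[k, 1] = w
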