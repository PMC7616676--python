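"""Numba-compiled inner loops for the intracellular response models.

State layout, oxidative variant (uM): [OxyR_red, GrxA, KatG, AhpC, H2O2_cell].
State layout, general variant (a.u.): [toxin_cell, enzyme].

The intracellular H2O2 balance relaxes on a sub-millisecond-to-second
timescale (scavenging rates reach 1e4-1e5 per minute once KatG accumulates),
far below the 1-minute outer step, so H2O2 is advanced with an exponential
(integrating-factor) update that is exact for the frozen-coefficient
linearisation dH/dt = a - b H and unconditionally stable. The slow gene
species use Heun's method (deterministic path) or Euler-Maruyama (stochastic
path, matching the published scheme).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# packed oxidative parameter vector indices
# 0 K_ox, 1 K_red, 2 h_OxyR, 3 OxyR_total,
# 4 R_grxA_basal, 5 K_grxA_act, 6 h_grxA_act,
# 7 R_katG_basal, 8 K_katG_act, 9 h_katG_act,
# 10 R_ahpC_basal, 11 K_ahpC_act, 12 h_ahpC_act,
# 13 K_AhpC, 14 h_AhpC, 15 K_KatG, 16 h_KatG,
# 17 R_H2O2_basal, 18 R_influx


@njit(cache=True)
def _ox_gene_derivs(y, H, g, p, out):
    """Time derivatives of the four gene species at H2O2 level ``H``."""
    oxy_red = y[0]
    ox = p[3] - oxy_red
    if ox < 0.0:
        ox = 0.0
    out[0] = -p[0] * oxy_red * H + p[1] * y[1] * (ox / (ox + p[2]))
    out[1] = p[4] + p[5] * (ox / (ox + p[6])) - g * y[1]
    out[2] = p[7] + p[8] * (ox / (ox + p[9])) - g * y[2]
    out[3] = p[10] + p[11] * (ox / (ox + p[12])) - g * y[3]


@njit(cache=True)
def _ox_h2o2_ab(y, H, h_ext, p):
    """Production term a and first-order loss coefficient b for H2O2."""
    a = p[18] * h_ext + p[17]
    b = p[13] * y[3] / (H + p[14]) + p[15] * y[2] / (H + p[16])
    return a, b


@njit(cache=True)
def _exp_update(H, a, b, h):
    """Advance dH/dt = a - b*H by h exactly (frozen a, b)."""
    x = b * h
    if x > 1e-10:
        em = -math.expm1(-x)  # 1 - exp(-b h), accurate for small x
        return H * math.exp(-x) + a * em / b
    return H + (a - b * H) * h


@njit(cache=True)
def _clip_ox(y, total):
    for k in range(1, 5):
        if y[k] < 0.0:
            y[k] = 0.0
    if y[0] < 0.0:
        y[0] = 0.0
    elif y[0] > total:
        y[0] = total


@njit(cache=True)
def ox_integrate_cells(Y, h_ext, g, p, dt, n_sub):
    """Advance oxidative states of all cells by ``dt`` (in place).

    Y: (n_cells, 5); h_ext, g: per-cell arrays held fixed over the step.
    """
    n = Y.shape[0]
    h = dt / n_sub
    k1 = np.empty(4)
    k2 = np.empty(4)
    y1 = np.empty(5)
    for i in range(n):
        y = Y[i]
        for _ in range(n_sub):
            H0 = y[4]
            a, b1 = _ox_h2o2_ab(y, H0, h_ext[i], p)
            _ox_gene_derivs(y, H0, g[i], p, k1)
            H1 = _exp_update(H0, a, b1, h)
            for k in range(4):
                y1[k] = y[k] + h * k1[k]
            y1[4] = H1
            _clip_ox(y1, p[3])
            _ox_gene_derivs(y1, H1, g[i], p, k2)
            for k in range(4):
                y[k] = y[k] + 0.5 * h * (k1[k] + k2[k])
            a2, b2 = _ox_h2o2_ab(y1, H1, h_ext[i], p)
            y[4] = _exp_update(H0, 0.5 * (a + a2), 0.5 * (b1 + b2), h)
            _clip_ox(y, p[3])
    return Y


@njit(cache=True)
def ox_sde_cells(Y, h_ext, g, p, sigmas, dt, n_inner, Z):
    """Euler-Maruyama step for all cells (in place).

    The gene species follow the non-dimensionalised Langevin equations: with
    n_inner[i] inner steps of real duration h = dt/n_inner[i], each inner step
    advances non-dimensional time by h_nd = g*h and adds noise
    sigma * Z * sqrt(h_nd). H2O2 is co-integrated deterministically. Z has
    shape (n_cells, max_inner, 4).
    """
    n = Y.shape[0]
    k1 = np.empty(4)
    for i in range(n):
        y = Y[i]
        m = n_inner[i]
        h = dt / m
        sqrt_hnd = math.sqrt(g[i] * h)
        for j in range(m):
            H0 = y[4]
            a, b = _ox_h2o2_ab(y, H0, h_ext[i], p)
            _ox_gene_derivs(y, H0, g[i], p, k1)
            for k in range(4):
                y[k] = y[k] + h * k1[k] + sigmas[k] * Z[i, j, k] * sqrt_hnd
            y[4] = _exp_update(H0, a, b, h)
            _clip_ox(y, p[3])
    return Y


# packed general-model parameter vector indices
# 0 R_influx_tox, 1 K_cat, 2 h_E, 3 K_act, 4 h_act


@njit(cache=True)
def gen_integrate_cells(Y, tox_ext, g, p, dt, n_sub):
    """Advance general-model states [toxin, enzyme] of all cells by ``dt``."""
    n = Y.shape[0]
    h = dt / n_sub
    for i in range(n):
        y = Y[i]
        for _ in range(n_sub):
            T0, E0 = y[0], y[1]
            a = p[0] * tox_ext[i]
            b1 = p[1] * E0 / (T0 + p[2])
            k1 = p[3] * (T0 / (T0 + p[4])) - g[i] * E0
            T1 = _exp_update(T0, a, b1, h)
            E1 = E0 + h * k1
            if E1 < 0.0:
                E1 = 0.0
            k2 = p[3] * (T1 / (T1 + p[4])) - g[i] * E1
            b2 = p[1] * E1 / (T1 + p[2])
            y[1] = E0 + 0.5 * h * (k1 + k2)
            y[0] = _exp_update(T0, a, 0.5 * (b1 + b2), h)
            if y[1] < 0.0:
                y[1] = 0.0
            if y[0] < 0.0:
                y[0] = 0.0
    return Y
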