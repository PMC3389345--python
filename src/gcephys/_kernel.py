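"""Fixed-step exponential-Euler integrator for the granule-cell model.

The integrator advances the membrane equation

    C dV/dt = I_inj + noise - g_L (V - E_L) - g_rect a(V) (V - E_K)
              - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)

with exponential Euler on V (treating the total conductance as frozen
over one step) and the closed-form update
``x <- x_inf + (x - x_inf) exp(-dt / tau_x)`` for each Hodgkin-Huxley
gate.  The rectifying leak activates instantaneously.  All traces of a
batch are integrated in one compiled loop; per-trace parameters are
passed as arrays so a whole population can be run in a single call.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Columns of the per-trace parameter matrix.
P_CAP = 0
P_GL = 1
P_EL = 2
P_GRECT = 3
P_RHALF = 4
P_RSLOPE = 5
P_GNA = 6
P_ENA = 7
P_NASHIFT = 8
P_NASCALE = 9
P_GK = 10
P_EK = 11
P_KSHIFT = 12
P_KSCALE = 13
N_PARAMS = 14


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    # x / (1 - exp(-x/y)), stable near x = 0
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def _m_rates(v: float):
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    return am, bm


@njit(cache=True)
def _h_rates(v: float):
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    return ah, bh


@njit(cache=True)
def _n_rates(v: float):
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return an, bn


@njit(cache=True)
def integrate_batch(
    params: np.ndarray,  # (n_traces, N_PARAMS)
    currents: np.ndarray,  # (n_traces,) step amplitude, pA
    noise: np.ndarray,  # (n_traces, n_steps) current noise, pA; may be empty
    v0: np.ndarray,  # (n_traces,) initial voltage
    dt: float,  # integration step, ms
    n_steps: int,
    onset_step: int,
    offset_step: int,
    record_every: int,
    out: np.ndarray,  # (n_traces, n_record) recorded voltage
) -> int:
    """Integrate all traces; returns -1 on success or the index of the
    first trace whose voltage went non-finite."""
    n_traces = params.shape[0]
    have_noise = noise.shape[1] > 0
    for i in range(n_traces):
        cap = params[i, P_CAP]
        gl = params[i, P_GL]
        el = params[i, P_EL]
        grect = params[i, P_GRECT]
        rhalf = params[i, P_RHALF]
        rslope = params[i, P_RSLOPE]
        gna = params[i, P_GNA]
        ena = params[i, P_ENA]
        nashift = params[i, P_NASHIFT]
        nascale = params[i, P_NASCALE]
        gk = params[i, P_GK]
        ek = params[i, P_EK]
        kshift = params[i, P_KSHIFT]
        kscale = params[i, P_KSCALE]
        i_step = currents[i]

        v = v0[i]
        am, bm = _m_rates(v - nashift)
        ah, bh = _h_rates(v - nashift)
        an, bn = _n_rates(v - kshift)
        m = am / (am + bm)
        h = ah / (ah + bh)
        n = an / (an + bn)

        out[i, 0] = v
        rec = 1
        for k in range(n_steps):
            # gate update (closed-form step at the current voltage)
            if gna > 0.0:
                am, bm = _m_rates(v - nashift)
                ah, bh = _h_rates(v - nashift)
                sm = (am + bm) * nascale
                sh = (ah + bh) * nascale
                m = am / (am + bm) + (m - am / (am + bm)) * math.exp(-dt * sm)
                h = ah / (ah + bh) + (h - ah / (ah + bh)) * math.exp(-dt * sh)
            if gk > 0.0:
                an, bn = _n_rates(v - kshift)
                sn = (an + bn) * kscale
                n = an / (an + bn) + (n - an / (an + bn)) * math.exp(-dt * sn)

            # conductances and driving terms
            g_na = gna * m * m * m * h
            g_k = gk * n * n * n * n
            a_rect = 1.0 / (1.0 + math.exp(-(v - rhalf) / rslope))
            g_rect = grect * a_rect
            g_tot = gl + g_rect + g_na + g_k

            i_inj = i_step if (onset_step <= k < offset_step) else 0.0
            if have_noise:
                i_inj += noise[i, k]

            v_inf = (gl * el + (g_rect + g_k) * ek + g_na * ena + i_inj) / g_tot
            v = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cap)
            if not math.isfinite(v):
                return i

            if (k + 1) % record_every == 0:
                if rec < out.shape[1]:
                    out[i, rec] = v
                rec += 1
    return -1
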