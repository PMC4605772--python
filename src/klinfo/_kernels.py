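"""Numba-compiled closed-loop simulation kernel.

The closed loop couples the circuit to a radial chemical gradient: at every
step the concentration at the body point is sampled, the circuit advances,
and the heading integrates the neck-angle velocity.  The kernel mirrors
:func:`klinfo.circuit.step_circuit` exactly (explicit Euler, same windowed
sensory derivative, same antiphase pattern-generator convention) and exists
because the evolutionary search evaluates tens of thousands of multi-minute
runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# layout of the packed parameter vector consumed by the kernel
PVEC_FIELDS = (
    "tau",
    "w_ON_AIYL", "w_ON_AIYR", "w_OFF_AIYL", "w_OFF_AIYR",
    "w_AIYL_AIZL", "w_AIYR_AIZR",
    "w_AIZL_SMBDL", "w_AIZL_SMBVL", "w_AIZR_SMBDR", "w_AIZR_SMBVR",
    "w_SMBDL_self", "w_SMBDR_self", "w_SMBVL_self", "w_SMBVR_self",
    "g_AIY", "g_AIZ",
    "theta_AIYL", "theta_AIYR", "theta_AIZL", "theta_AIZR",
    "theta_SMBDL", "theta_SMBDR", "theta_SMBVL", "theta_SMBVR",
    "w_PG", "w_NMJ", "T", "v",
)
PVEC_INDEX = {name: i for i, name in enumerate(PVEC_FIELDS)}


def pack_params(params) -> np.ndarray:
    """Pack a CircuitParams into the flat float vector the kernel consumes."""
    return np.array([getattr(params, f) for f in PVEC_FIELDS], dtype=np.float64)


@njit(cache=True)
def _sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _concentration(x, y, px, py, peak, scale, kind):
    r = np.sqrt((x - px) ** 2 + (y - py) ** 2)
    if kind == 0:  # conical: linear decay with distance
        c = peak - scale * r
        return c if c > 0.0 else 0.0
    # gaussian
    return peak * np.exp(-0.5 * (r / scale) ** 2)


@njit(cache=True)
def run_closed_loop_kernel(
    pv,
    N,
    M,
    dt,
    n_steps,
    x0,
    y0,
    mu0,
    field_px,
    field_py,
    field_peak,
    field_scale,
    field_kind,
    arena_radius,
    block_gap_aiy,
    block_gap_aiz,
):
    """Simulate one closed-loop run; returns (x, y, c, d, phi, n_done).

    Arrays have length n_steps; if the worm leaves the arena the run is
    truncated and ``n_done`` reports the number of completed steps.
    """
    tau = pv[0]
    w_on_l, w_on_r, w_off_l, w_off_r = pv[1], pv[2], pv[3], pv[4]
    w_yl_zl, w_yr_zr = pv[5], pv[6]
    w_zl_dl, w_zl_vl, w_zr_dr, w_zr_vr = pv[7], pv[8], pv[9], pv[10]
    w_dl_dl, w_dr_dr, w_vl_vl, w_vr_vr = pv[11], pv[12], pv[13], pv[14]
    g_aiy = 0.0 if block_gap_aiy else pv[15]
    g_aiz = 0.0 if block_gap_aiz else pv[16]
    th = pv[17:25]
    w_pg, w_nmj, T, v = pv[25], pv[26], pv[27], pv[28]

    NM = N + M
    hist = np.empty(NM)
    c0 = _concentration(x0, y0, field_px, field_py, field_peak, field_scale, field_kind)
    for i in range(NM):
        hist[i] = c0
    sum_n = c0 * N
    sum_m = c0 * M

    V = np.zeros(8)
    x, y, mu = x0, y0, mu0
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    cs = np.empty(n_steps)
    ds = np.empty(n_steps)
    phis = np.empty(n_steps)
    n_done = 0
    two_pi = 2.0 * np.pi

    for k in range(n_steps):
        c = _concentration(x, y, field_px, field_py, field_peak, field_scale, field_kind)
        boundary = hist[(k - N) % NM]
        oldest = hist[k % NM]
        sum_n += c - boundary
        sum_m += boundary - oldest
        hist[k % NM] = c
        d = sum_n / N - sum_m / M
        if d > 0.0:
            v_on, v_off = d, 0.0
        else:
            v_on, v_off = 0.0, -d

        s0 = _sigma(V[0] + th[0])
        s1 = _sigma(V[1] + th[1])
        s2 = _sigma(V[2] + th[2])
        s3 = _sigma(V[3] + th[3])
        s4 = _sigma(V[4] + th[4])
        s5 = _sigma(V[5] + th[5])
        s6 = _sigma(V[6] + th[6])
        s7 = _sigma(V[7] + th[7])
        phi = w_nmj * ((s4 + s5) - (s6 + s7))

        xs[k] = x
        ys[k] = y
        cs[k] = c
        ds[k] = d
        phis[k] = phi
        n_done = k + 1

        pg = np.sin(two_pi * (k * dt) / T)
        dt_tau = dt / tau
        nV0 = V[0] + dt_tau * (-V[0] + w_on_l * v_on + w_off_l * v_off + g_aiy * (V[1] - V[0]))
        nV1 = V[1] + dt_tau * (-V[1] + w_on_r * v_on + w_off_r * v_off + g_aiy * (V[0] - V[1]))
        nV2 = V[2] + dt_tau * (-V[2] + w_yl_zl * s0 + g_aiz * (V[3] - V[2]))
        nV3 = V[3] + dt_tau * (-V[3] + w_yr_zr * s1 + g_aiz * (V[2] - V[3]))
        nV4 = V[4] + dt_tau * (-V[4] + w_zl_dl * s2 + w_dl_dl * s4 - w_pg * pg)
        nV5 = V[5] + dt_tau * (-V[5] + w_zr_dr * s3 + w_dr_dr * s5 - w_pg * pg)
        nV6 = V[6] + dt_tau * (-V[6] + w_zl_vl * s2 + w_vl_vl * s6 + w_pg * pg)
        nV7 = V[7] + dt_tau * (-V[7] + w_zr_vr * s3 + w_vr_vr * s7 + w_pg * pg)
        V[0], V[1], V[2], V[3] = nV0, nV1, nV2, nV3
        V[4], V[5], V[6], V[7] = nV4, nV5, nV6, nV7

        x = x + dt * v * np.cos(mu)
        y = y + dt * v * np.sin(mu)
        mu = mu + dt * phi
        if (x - field_px) ** 2 + (y - field_py) ** 2 > arena_radius ** 2:
            break

    return xs, ys, cs, ds, phis, n_done
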