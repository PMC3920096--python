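"""Numba kernels for the inner simulation loop.

One step of the network is ~2k floating point operations on seven
196-channel areas; a trial is 80 steps and a full experiment battery is
tens of thousands of trials, so the per-step sweep and the per-trial
loop are compiled with numba.  The Python-level API in
:mod:`bgaction.circuit` and :mod:`bgaction.experiments` wraps these
kernels; both the single-step path and the whole-trial path execute the
same :func:`step` code, so they cannot drift apart.

State layout: ``a`` and ``y`` are ``(7, 196)`` arrays with area rows
M, T, D1, D2, STN, GPe, SNr (see ``circuit.AREA_ORDER``); ``gains`` is
packed by ``ModelParams.packed()``.
"""

import numpy as np
from numba import njit

# rows of the packed state arrays
M, T, D1, D2, STN, GPE, SNR = 0, 1, 2, 3, 4, 5, 6

# entries of the packed gain vector
(G_EM, G_TM, G_MT, G_SNR_T, G_M_STN, G_C_STN, G_D1_SNR, G_D2_GPE,
 G_STN_SNR, G_STN_GPE, G_GPE_STN, G_GPE_SNR, G_LAM, G_CTX) = range(14)


@njit(cache=True)
def _ramp(u, eps, m):
    v = m * (u - eps)
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True)
def step(a, y, e, w_ctx_d1, w_ctx_d2, w_m_d1, w_m_d2,
         gains, k, eps, m, noise, use_noise):
    """One sweep update of all areas (in place).

    Sweep order: Cortex (from Explorer + Thalamus), cortical noise,
    D1/D2/STN (from noisy Cortex + Context; STN reads last step's GPe),
    GPe and SNr (from the new striatal/STN outputs), Thalamus (from the
    new Cortex and SNr outputs).
    """
    n = a.shape[1]
    lam = gains[G_LAM]
    ctx = gains[G_CTX]

    # Cortex: explorer drive + thalamic feedback
    for i in range(n):
        u = gains[G_EM] * e[i] + gains[G_TM] * y[T, i]
        a[M, i] = (1.0 - k[M]) * a[M, i] + k[M] * u
        v = _ramp(a[M, i], eps[M], m[M])
        if use_noise:
            v = v + v * noise[i]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
        y[M, i] = v

    # striatum (dopamine-scaled) and STN
    for i in range(n):
        drive1 = w_m_d1[i] * y[M, i] + w_ctx_d1[i] * ctx
        drive2 = w_m_d2[i] * y[M, i] + w_ctx_d2[i] * ctx
        a[D1, i] = (1.0 - k[D1]) * a[D1, i] + k[D1] * (1.0 + lam) * drive1
        y[D1, i] = _ramp(a[D1, i], eps[D1], m[D1])
        a[D2, i] = (1.0 - k[D2]) * a[D2, i] + k[D2] * (1.0 - lam) * drive2
        y[D2, i] = _ramp(a[D2, i], eps[D2], m[D2])
        u = (gains[G_M_STN] * y[M, i] + gains[G_C_STN] * ctx
             - gains[G_GPE_STN] * y[GPE, i])
        a[STN, i] = (1.0 - k[STN]) * a[STN, i] + k[STN] * u
        y[STN, i] = _ramp(a[STN, i], eps[STN], m[STN])

    # diffuse STN excitation: every STN unit projects to all GPe/SNr units
    stn_sum = 0.0
    for i in range(n):
        stn_sum += y[STN, i]

    for i in range(n):
        u = gains[G_STN_GPE] * stn_sum - gains[G_D2_GPE] * y[D2, i]
        a[GPE, i] = (1.0 - k[GPE]) * a[GPE, i] + k[GPE] * u
        y[GPE, i] = _ramp(a[GPE, i], eps[GPE], m[GPE])
    for i in range(n):
        u = (gains[G_STN_SNR] * stn_sum - gains[G_D1_SNR] * y[D1, i]
             - gains[G_GPE_SNR] * y[GPE, i])
        a[SNR, i] = (1.0 - k[SNR]) * a[SNR, i] + k[SNR] * u
        y[SNR, i] = _ramp(a[SNR, i], eps[SNR], m[SNR])

    # thalamus, gated by the fresh SNr output
    for i in range(n):
        u = gains[G_MT] * y[M, i] - gains[G_SNR_T] * y[SNR, i]
        a[T, i] = (1.0 - k[T]) * a[T, i] + k[T] * u
        y[T, i] = _ramp(a[T, i], eps[T], m[T])


@njit(cache=True)
def run_trial_steps(a, y, e_fields, w_ctx_d1, w_ctx_d2, w_m_d1, w_m_d2,
                    gains, k, eps, m, noise, use_noise,
                    eta, lam_m, xp, coords):
    """Simulate one trial of ``e_fields.shape[0]`` steps (in place).

    At every step, cortex units above threshold ``eta`` vote for their
    grid location with strength proportional to their (noisy) output; if
    any vote is cast, the motor plant relaxes the position ``xp`` toward
    the population-vector target by fraction ``lam_m``.

    Returns ``True`` if a movement occurred (some cortex unit exceeded
    ``eta`` at some step).
    """
    n_steps = e_fields.shape[0]
    n = a.shape[1]
    moved = False
    for t in range(n_steps):
        step(a, y, e_fields[t], w_ctx_d1, w_ctx_d2, w_m_d1, w_m_d2,
             gains, k, eps, m, noise[t], use_noise)
        sw = 0.0
        sx = 0.0
        sy = 0.0
        for i in range(n):
            v = y[M, i]
            if v > eta:
                sw += v
                sx += v * coords[i, 0]
                sy += v * coords[i, 1]
        if sw > 0.0:
            moved = True
            xp[0] += lam_m * (sx / sw - xp[0])
            xp[1] += lam_m * (sy / sw - xp[1])
    return moved
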