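"""Numba-compiled stochastic-Heun kernel (fast path of the simulator).

Mirrors :func:`slowwave.integrate.run_chunk_numpy` operation for operation;
the two engines are consistency-tested against each other.  Kept free of any
python objects: state, constants and noise arrive as plain float arrays.
The K(Na) gate is evaluated as ``0.37 / (1 + 38.7^3.5 / (Na^3 sqrt(Na)))``
to avoid a fractional power in the inner loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# constants vector layout -- keep in sync with integrate.CONST_NAMES
_QMAX_P, _THETA_P, _SIGMA_P, _TAU_P, _EL_P = 0, 1, 2, 3, 4
_QMAX_I, _THETA_I, _SIGMA_I, _TAU_I, _EL_I = 5, 6, 7, 8, 9
_GAMMA_P, _GAMMA_I = 10, 11
_NPP, _NIP, _NPI, _NII = 12, 13, 14, 15
_GA_P, _GA_I, _GG_P, _GG_I = 16, 17, 18, 19
_EA, _EG = 20, 21
_GKNA, _EK, _TAUNA, _ALPHANA, _RPUMP, _NAEQ, _CM = 22, 23, 24, 25, 26, 27, 28
_C, _BETA, _NPPX, _NIPX = 29, 30, 31, 32

_PUMP_K3 = 15.0 ** 3
_GATE_K35 = 38.7 ** 3.5


@njit(cache=True, inline="always")
def _rate(V, qmax, theta, sigma, C):
    return qmax * 0.5 * (1.0 + np.tanh(C * (V - theta) / sigma))


@njit(cache=True)
def _rhs(y, dy, cst, columns, drive_pp0, noise_mean):
    block = 11 if columns == 1 else 15
    pump_eq = cst[_NAEQ] ** 3 / (cst[_NAEQ] ** 3 + _PUMP_K3)
    qp0 = _rate(y[0], cst[_QMAX_P], cst[_THETA_P], cst[_SIGMA_P], cst[_C])
    qp1 = 0.0
    if columns == 2:
        qp1 = _rate(y[block], cst[_QMAX_P], cst[_THETA_P], cst[_SIGMA_P],
                    cst[_C])
    for c in range(columns):
        o = c * block
        Vp = y[o + 0]; Vi = y[o + 1]; Na = y[o + 2]
        Qp = qp0 if c == 0 else qp1
        Qpo = qp1 if c == 0 else qp0
        Qi = _rate(Vi, cst[_QMAX_I], cst[_THETA_I], cst[_SIGMA_I], cst[_C])

        i_ampa_p = cst[_GA_P] * y[o + 3] * (Vp - cst[_EA])
        i_ampa_i = cst[_GA_I] * y[o + 5] * (Vi - cst[_EA])
        if columns == 2:
            i_ampa_p += cst[_BETA] * cst[_GA_P] * y[o + 11] * (Vp - cst[_EA])
            i_ampa_i += cst[_BETA] * cst[_GA_I] * y[o + 13] * (Vi - cst[_EA])
        i_gaba_p = cst[_GG_P] * y[o + 7] * (Vp - cst[_EG])
        i_gaba_i = cst[_GG_I] * y[o + 9] * (Vi - cst[_EG])
        na3 = Na * Na * Na
        gate = 0.37 / (1.0 + _GATE_K35 / (na3 * np.sqrt(Na)))
        i_kna = cst[_GKNA] * gate * (Vp - cst[_EK])

        dy[o + 0] = (-(Vp - cst[_EL_P]) - i_ampa_p - i_gaba_p
                     - cst[_TAU_P] / cst[_CM] * i_kna) / cst[_TAU_P]
        dy[o + 1] = (-(Vi - cst[_EL_I]) - i_ampa_i - i_gaba_i) / cst[_TAU_I]
        pump = cst[_RPUMP] * (na3 / (na3 + _PUMP_K3) - pump_eq)
        dy[o + 2] = (cst[_ALPHANA] * Qp - pump) / cst[_TAUNA]

        gp = cst[_GAMMA_P]; gi = cst[_GAMMA_I]
        d0 = noise_mean + (drive_pp0 if c == 0 else 0.0)
        # s_pp, s_ip (AMPA, gamma_p) then s_pi, s_ii (GABA, gamma_i)
        dy[o + 3] = y[o + 4]
        dy[o + 4] = gp * gp * (cst[_NPP] * Qp + d0 - y[o + 3]) - 2.0 * gp * y[o + 4]
        dy[o + 5] = y[o + 6]
        dy[o + 6] = gp * gp * (cst[_NIP] * Qp + noise_mean - y[o + 5]) - 2.0 * gp * y[o + 6]
        dy[o + 7] = y[o + 8]
        dy[o + 8] = gi * gi * (cst[_NPI] * Qi - y[o + 7]) - 2.0 * gi * y[o + 8]
        dy[o + 9] = y[o + 10]
        dy[o + 10] = gi * gi * (cst[_NII] * Qi - y[o + 9]) - 2.0 * gi * y[o + 10]
        if columns == 2:
            dy[o + 11] = y[o + 12]
            dy[o + 12] = gp * gp * (cst[_NPPX] * Qpo - y[o + 11]) - 2.0 * gp * y[o + 12]
            dy[o + 13] = y[o + 14]
            dy[o + 14] = gp * gp * (cst[_NIPX] * Qpo - y[o + 13]) - 2.0 * gp * y[o + 14]


@njit(cache=True)
def run_chunk_numba(y, cst, columns, dt, noise_amp, noise, stim, noise_mean,
                    rec, record, chunk_start, burn_steps):
    n_trials, D = y.shape
    chunk = noise.shape[1]
    block = 11 if columns == 1 else 15
    f1 = np.empty(D)
    f2 = np.empty(D)
    yp = np.empty(D)
    for i in range(n_trials):
        yi = y[i]
        for k in range(chunk):
            _rhs(yi, f1, cst, columns, stim[k], noise_mean)
            for j in range(D):
                yp[j] = yi[j] + dt * f1[j]
            for c in range(columns):
                yp[c * block + 4] += noise_amp * noise[i, k, 2 * c]
                yp[c * block + 6] += noise_amp * noise[i, k, 2 * c + 1]
            _rhs(yp, f2, cst, columns, stim[k], noise_mean)
            for j in range(D):
                yi[j] = yi[j] + 0.5 * dt * (f1[j] + f2[j])
            for c in range(columns):
                yi[c * block + 4] += noise_amp * noise[i, k, 2 * c]
                yi[c * block + 6] += noise_amp * noise[i, k, 2 * c + 1]
            if record:
                r = chunk_start + k - burn_steps
                if r >= 0:
                    for c in range(columns):
                        o = c * block
                        Vp = yi[o + 0]; Vi = yi[o + 1]
                        i_ampa_p = cst[_GA_P] * yi[o + 3] * (Vp - cst[_EA])
                        i_ampa_i = cst[_GA_I] * yi[o + 5] * (Vi - cst[_EA])
                        if columns == 2:
                            i_ampa_p += (cst[_BETA] * cst[_GA_P] * yi[o + 11]
                                         * (Vp - cst[_EA]))
                            i_ampa_i += (cst[_BETA] * cst[_GA_I] * yi[o + 13]
                                         * (Vi - cst[_EA]))
                        i_gaba_p = cst[_GG_P] * yi[o + 7] * (Vp - cst[_EG])
                        i_gaba_i = cst[_GG_I] * yi[o + 9] * (Vi - cst[_EG])
                        rec[5 * c + 0, i, r] = Vp
                        rec[5 * c + 1, i, r] = Vi
                        rec[5 * c + 2, i, r] = yi[o + 2]
                        rec[5 * c + 3, i, r] = abs(i_ampa_p) + abs(i_gaba_p)
                        rec[5 * c + 4, i, r] = abs(i_ampa_i) + abs(i_gaba_i)
    return y
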