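"""Stochastic Heun integration.

Two interchangeable engines advance the packed state vector:

* a pure-numpy reference engine built directly on :func:`slowwave.model.full_rhs`
  (vectorized over trials), and
* a numba-compiled kernel (:mod:`slowwave._kernels`) with identical update
  order, used by default when numba imports.

Both use the predictor-corrector (Heun) scheme in which the additive white
noise increment enters the predictor and the corrector with the same draw:

    y_pred  = y + dt f(y)      + G dW
    y_next  = y + dt/2 (f(y) + f(y_pred)) + G dW

The noise acts only on the first derivatives of the intra-column AMPAergic
synaptic activities, with amplitude gamma_p^2 * std * sqrt(dt) per step
(continuous-time white-noise convention).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from . import model
from .params import ColumnParameters, CouplingSpec

#: indices into the packed per-engine constants vector
CONST_NAMES = (
    "Qmax_p", "theta_p", "sigma_p", "tau_p", "EL_p",
    "Qmax_i", "theta_i", "sigma_i", "tau_i", "EL_i",
    "gamma_p", "gamma_i",
    "Npp", "Nip", "Npi", "Nii",
    "gA_p", "gA_i", "gG_p", "gG_i",
    "EA", "EG",
    "gKNa", "EK", "tauNa", "alphaNa", "Rpump", "Naeq", "Cm",
    "C", "beta", "Nppx", "Nipx",
)


def pack_constants(params: ColumnParameters,
                   coupling: Optional[CouplingSpec] = None,
                   C: float = model.C_SIGMOID) -> np.ndarray:
    p, i = params.pyramidal, params.inhibitory
    s, a = params.synapses, params.adaptation
    beta = coupling.beta if coupling is not None else 0.0
    nppx = coupling.N_pp_inter if coupling is not None else 0.0
    nipx = coupling.N_ip_inter if coupling is not None else 0.0
    vals = (p.Qmax, p.theta, p.sigma, p.tau, p.E_L,
            i.Qmax, i.theta, i.sigma, i.tau, i.E_L,
            s.gamma_p, s.gamma_i,
            s.N["p"]["p"], s.N["i"]["p"], s.N["p"]["i"], s.N["i"]["i"],
            s.g_AMPA_p, s.g_AMPA_i, s.g_GABA_p, s.g_GABA_i,
            s.E_AMPA, s.E_GABA,
            a.g_KNa, a.E_K, a.tau_Na, a.alpha_Na, a.R_pump, a.Na_eq, a.Cm,
            C, beta, nppx, nipx)
    return np.asarray(vals, dtype=np.float64)


def heun_integrate(f: Callable, y0: np.ndarray, dt: float, n_steps: int,
                   noise: Optional[np.ndarray] = None,
                   record: bool = False):
    """Generic (stochastic) Heun integrator for ``dy/dt = f(y) + noise``.

    ``noise`` holds pre-scaled additive increments per step with shape
    ``(n_steps,) + y0.shape``; the same increment is used in predictor and
    corrector.  With ``record=True`` returns the trajectory including y0,
    otherwise the final state.
    """
    y = np.array(y0, dtype=float)
    traj = np.empty((n_steps + 1,) + y.shape) if record else None
    if record:
        traj[0] = y
    for k in range(n_steps):
        f1 = np.asarray(f(y), float)
        y_pred = y + dt * f1
        if noise is not None:
            y_pred = y_pred + noise[k]
        f2 = np.asarray(f(y_pred), float)
        y = y + 0.5 * dt * (f1 + f2)
        if noise is not None:
            y = y + noise[k]
        if record:
            traj[k + 1] = y
    return traj if record else y


def _noise_indices(columns: int):
    """State indices receiving noise (u_pp, u_ip per column) and the matching
    column index of each draw."""
    block = model.NVAR_INTRA + (model.NVAR_INTER if columns == 2 else 0)
    idx = []
    for c in range(columns):
        idx += [c * block + 4, c * block + 6]
    return np.asarray(idx, dtype=np.int64)


def run_chunk_numpy(y: np.ndarray, params: ColumnParameters,
                    coupling: Optional[CouplingSpec], columns: int,
                    dt: float, noise_amp: float, noise: np.ndarray,
                    stim: np.ndarray, noise_mean: float,
                    rec: Optional[np.ndarray], chunk_start: int,
                    burn_steps: int, C: float = model.C_SIGMOID) -> np.ndarray:
    """Advance all trials through one chunk of steps (reference engine).

    ``y`` is ``(n_trials, D)`` and is returned updated; ``noise`` is
    ``(n_trials, chunk, 2*columns)`` of standard-normal draws; ``stim`` is the
    per-step stimulus drive (ms^-1) added to the perturbed column's s_pp
    equation; ``rec`` (if given) is the float32 recording array
    ``(5*columns, n_trials, n_rec)`` filled at post-burn-in steps.
    """
    idx = _noise_indices(columns)
    chunk = noise.shape[1]
    for k in range(chunk):
        g = chunk_start + k
        d_pp = (noise_mean + stim[k], noise_mean)
        d_ip = (noise_mean, noise_mean)
        f1 = model.full_rhs(y, params, coupling, columns, d_pp, d_ip, C)
        y_pred = y + dt * f1
        y_pred[:, idx] += noise_amp * noise[:, k, :]
        f2 = model.full_rhs(y_pred, params, coupling, columns, d_pp, d_ip, C)
        y = y + 0.5 * dt * (f1 + f2)
        y[:, idx] += noise_amp * noise[:, k, :]
        r = g - burn_steps
        if rec is not None and r >= 0:
            block = model.NVAR_INTRA + (model.NVAR_INTER if columns == 2 else 0)
            lfp = model.lfp_from_state(y, params, coupling, columns)
            for c in range(columns):
                o = c * block
                rec[5 * c + 0, :, r] = y[:, o + 0]
                rec[5 * c + 1, :, r] = y[:, o + 1]
                rec[5 * c + 2, :, r] = y[:, o + 2]
                rec[5 * c + 3, :, r] = lfp[:, 2 * c + 0]
                rec[5 * c + 4, :, r] = lfp[:, 2 * c + 1]
    return y


def get_numba_chunk_runner():
    """Return the numba chunk runner, or None if numba is unavailable."""
    try:
        from ._kernels import run_chunk_numba
    except Exception:  # pragma: no cover - numba is an expected dependency
        return None
    return run_chunk_numba
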