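"""Right-hand-side mathematics of the cortical-column neural-mass model.

Everything here is deterministic and free of integration logic: sigmoidal
rate functions, leak/synaptic/adaptation currents, critically damped
second-order synaptic kinetics, and the assembled state derivative for one or
two symmetrically coupled columns.  The stochastic drive enters only through
the ``drive_pp`` / ``drive_ip`` arguments supplied by the integrator.

State vector layout (per column, ``NVAR_INTRA = 11`` intra variables)::

    0 Vp   1 Vi   2 Na
    3 s_pp 4 u_pp 5 s_ip 6 u_ip 7 s_pi 8 u_pi 9 s_ii 10 u_ii

where ``u = ds/dt``.  In two-column mode each column carries four extra
variables for the inter-column AMPAergic synapses::

    11 s_pp_x 12 u_pp_x 13 s_ip_x 14 u_ip_x

and the full vector is the concatenation of the two 15-variable blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .params import (AdaptationParams, ColumnParameters, CouplingSpec,
                     PopulationParams, SynapticParams)

#: Sigmoid slope constant linking the inverse neural gain to the tanh slope.
C_SIGMOID = math.pi / (2.0 * math.sqrt(3.0))

NVAR_INTRA = 11
NVAR_INTER = 4

#: Hill half-activation constant of the sodium pump, (15 mM)^3.
_NA_PUMP_K3 = 15.0 ** 3


@dataclass
class ColumnState:
    """Dynamical variables of one column (scalars or trial-vectors)."""

    Vp: float
    Vi: float
    Na: float
    s_pp: float = 0.0
    u_pp: float = 0.0
    s_ip: float = 0.0
    u_ip: float = 0.0
    s_pi: float = 0.0
    u_pi: float = 0.0
    s_ii: float = 0.0
    u_ii: float = 0.0
    s_pp_inter: Optional[float] = None
    u_pp_inter: Optional[float] = None
    s_ip_inter: Optional[float] = None
    u_ip_inter: Optional[float] = None

    @property
    def has_inter(self) -> bool:
        return self.s_pp_inter is not None


def firing_rate(V, pop: PopulationParams, C: float = C_SIGMOID):
    """Population firing rate (ms^-1): sigmoid of the membrane potential.

    ``Q(V) = Qmax * (1 + tanh(C (V - theta) / sigma)) / 2`` — strictly
    increasing and bounded in (0, Qmax).
    """
    return pop.Qmax * 0.5 * (1.0 + np.tanh(C * (np.asarray(V, float) - pop.theta)
                                           / pop.sigma))


def leak_current(V, pop: PopulationParams):
    """Leak current with implicit unit conductance: ``I_L = V - E_L``."""
    return np.asarray(V, float) - pop.E_L


def kna_current(Vp, Na, adapt: AdaptationParams):
    """Sodium-dependent potassium current of the pyramidal population.

    ``I_KNa = g_KNa * 0.37 / (1 + (38.7/Na)^3.5) * (Vp - E_K)``; the sodium
    gate saturates at 0.37 for large [Na] and vanishes as [Na] -> 0+.
    """
    Na = np.asarray(Na, float)
    if np.any(Na <= 0):
        raise ValueError("sodium concentration must be positive")
    gate = 0.37 / (1.0 + (38.7 / Na) ** 3.5)
    return adapt.g_KNa * gate * (np.asarray(Vp, float) - adapt.E_K)


def na_pump(Na, adapt: AdaptationParams):
    """Sodium extrusion through pumps (Hill form with 15 mM half activation).

    Constructed so that the pump exactly balances zero influx at
    ``Na = Na_eq``: the resting concentration is a fixed point.
    """
    Na = np.asarray(Na, float)
    eq = adapt.Na_eq ** 3 / (adapt.Na_eq ** 3 + _NA_PUMP_K3)
    return adapt.R_pump * (Na ** 3 / (Na ** 3 + _NA_PUMP_K3) - eq)


def na_dynamics(Na, Qp, adapt: AdaptationParams):
    """d[Na]/dt (mM/ms): firing-driven influx minus pump extrusion."""
    Na = np.asarray(Na, float)
    if np.any(Na <= 0):
        raise ValueError("sodium concentration must be positive")
    return (adapt.alpha_Na * np.asarray(Qp, float) - na_pump(Na, adapt)) / adapt.tau_Na


def synapse_rhs(s, u, Q_pre, N, gamma, drive=0.0):
    """Critically damped second-order synaptic kinetics.

    ``s'' = gamma^2 (N Q_pre + drive - s) - 2 gamma s'`` whose impulse
    response is the alpha function ``gamma^2 t exp(-gamma t)``.  Returns
    (ds/dt, du/dt).
    """
    ds = u
    du = gamma * gamma * (N * Q_pre + drive - s) - 2.0 * gamma * u
    return ds, du


def synaptic_currents(state: ColumnState, syn: SynapticParams,
                      coupling: Optional[CouplingSpec] = None):
    """AMPAergic and GABAergic currents onto both populations of a column.

    Returns ``(I_AMPA_p, I_AMPA_i, I_GABA_p, I_GABA_i)``.  In two-column mode
    the AMPAergic currents gain the inter-column term scaled by
    ``beta * g_AMPA``.
    """
    if state.has_inter and coupling is None:
        raise ValueError("inter-column synaptic activities present but no "
                         "coupling given (one-column mode)")
    dv_a_p = state.Vp - syn.E_AMPA
    dv_a_i = state.Vi - syn.E_AMPA
    i_ampa_p = syn.g_AMPA_p * state.s_pp * dv_a_p
    i_ampa_i = syn.g_AMPA_i * state.s_ip * dv_a_i
    if coupling is not None:
        s_pp_x = state.s_pp_inter if state.s_pp_inter is not None else 0.0
        s_ip_x = state.s_ip_inter if state.s_ip_inter is not None else 0.0
        i_ampa_p = i_ampa_p + coupling.beta * syn.g_AMPA_p * s_pp_x * dv_a_p
        i_ampa_i = i_ampa_i + coupling.beta * syn.g_AMPA_i * s_ip_x * dv_a_i
    i_gaba_p = syn.g_GABA_p * state.s_pi * (state.Vp - syn.E_GABA)
    i_gaba_i = syn.g_GABA_i * state.s_ii * (state.Vi - syn.E_GABA)
    return i_ampa_p, i_ampa_i, i_gaba_p, i_gaba_i


# ---------------------------------------------------------------------------
# Packed-vector RHS used by the integrators and the fixed-point solver.
# ---------------------------------------------------------------------------

def state_size(columns: int) -> int:
    if columns == 1:
        return NVAR_INTRA
    if columns == 2:
        return 2 * (NVAR_INTRA + NVAR_INTER)
    raise ValueError("columns must be 1 or 2")


def full_rhs(y: np.ndarray, params: ColumnParameters,
             coupling: Optional[CouplingSpec] = None, columns: int = 1,
             drive_pp: Sequence[float] = (0.0, 0.0),
             drive_ip: Sequence[float] = (0.0, 0.0),
             C: float = C_SIGMOID) -> np.ndarray:
    """State derivative for the packed one- or two-column state vector.

    ``y`` has shape ``(D,)`` or ``(n_trials, D)``; the derivative is
    vectorized over the leading axis.  ``drive_pp``/``drive_ip`` are the mean
    rate drives (noise mean plus any stimulus) entering the intra-column
    AMPAergic equations of each column; inter-column synapses receive no
    extrinsic drive.  The inhibitory membrane equation carries no adaptation
    current.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to full_rhs")
    D = state_size(columns)
    if y.shape[-1] != D:
        raise ValueError(f"state vector must have {D} components for "
                         f"{columns} column(s)")
    if columns == 2 and coupling is None:
        raise ValueError("two-column mode requires a CouplingSpec")

    pyr, inh = params.pyramidal, params.inhibitory
    syn, adapt = params.synapses, params.adaptation
    Npp = syn.N["p"]["p"]; Npi = syn.N["p"]["i"]
    Nip = syn.N["i"]["p"]; Nii = syn.N["i"]["i"]
    gp, gi = syn.gamma_p, syn.gamma_i
    beta = coupling.beta if coupling is not None else 0.0

    dy = np.empty_like(y)
    block = NVAR_INTRA + (NVAR_INTER if columns == 2 else 0)
    for c in range(columns):
        o = c * block
        oo = (1 - c) * block  # other column's offset
        Vp = y[..., o + 0]; Vi = y[..., o + 1]; Na = y[..., o + 2]
        Qp = firing_rate(Vp, pyr, C)
        Qi = firing_rate(Vi, inh, C)

        dv_a_p = Vp - syn.E_AMPA
        dv_a_i = Vi - syn.E_AMPA
        i_ampa_p = syn.g_AMPA_p * y[..., o + 3] * dv_a_p
        i_ampa_i = syn.g_AMPA_i * y[..., o + 5] * dv_a_i
        if columns == 2:
            i_ampa_p = i_ampa_p + beta * syn.g_AMPA_p * y[..., o + 11] * dv_a_p
            i_ampa_i = i_ampa_i + beta * syn.g_AMPA_i * y[..., o + 13] * dv_a_i
        i_gaba_p = syn.g_GABA_p * y[..., o + 7] * (Vp - syn.E_GABA)
        i_gaba_i = syn.g_GABA_i * y[..., o + 9] * (Vi - syn.E_GABA)
        i_kna = kna_current(Vp, Na, adapt)

        dy[..., o + 0] = (-(Vp - pyr.E_L) - i_ampa_p - i_gaba_p
                          - pyr.tau / adapt.Cm * i_kna) / pyr.tau
        dy[..., o + 1] = (-(Vi - inh.E_L) - i_ampa_i - i_gaba_i) / inh.tau
        dy[..., o + 2] = (adapt.alpha_Na * Qp - na_pump(Na, adapt)) / adapt.tau_Na

        pairs = [
            (3, Qp, Npp, gp, drive_pp[c]),   # s_pp  (AMPA onto p)
            (5, Qp, Nip, gp, drive_ip[c]),   # s_ip  (AMPA onto i)
            (7, Qi, Npi, gi, 0.0),           # s_pi  (GABA onto p)
            (9, Qi, Nii, gi, 0.0),           # s_ii  (GABA onto i)
        ]
        if columns == 2:
            Qp_other = firing_rate(y[..., oo + 0], pyr, C)
            pairs += [
                (11, Qp_other, coupling.N_pp_inter, gp, 0.0),
                (13, Qp_other, coupling.N_ip_inter, gp, 0.0),
            ]
        for k, Q_pre, N, gamma, drv in pairs:
            s = y[..., o + k]; u = y[..., o + k + 1]
            dy[..., o + k] = u
            dy[..., o + k + 1] = gamma * gamma * (N * Q_pre + drv - s) - 2.0 * gamma * u
    return dy


def lfp_from_state(y: np.ndarray, params: ColumnParameters,
                   coupling: Optional[CouplingSpec] = None,
                   columns: int = 1) -> np.ndarray:
    """Pyramidal and inhibitory LFP per column from a packed state.

    ``LFP_k = |I_AMPA_k| + |I_GABA_k|``; returns an array with last axis
    ``[lfp_p_0, lfp_i_0, (lfp_p_1, lfp_i_1)]``.
    """
    y = np.asarray(y, float)
    syn = params.synapses
    beta = coupling.beta if coupling is not None else 0.0
    block = NVAR_INTRA + (NVAR_INTER if columns == 2 else 0)
    out = []
    for c in range(columns):
        o = c * block
        Vp = y[..., o + 0]; Vi = y[..., o + 1]
        i_ampa_p = syn.g_AMPA_p * y[..., o + 3] * (Vp - syn.E_AMPA)
        i_ampa_i = syn.g_AMPA_i * y[..., o + 5] * (Vi - syn.E_AMPA)
        if columns == 2:
            i_ampa_p = i_ampa_p + beta * syn.g_AMPA_p * y[..., o + 11] * (Vp - syn.E_AMPA)
            i_ampa_i = i_ampa_i + beta * syn.g_AMPA_i * y[..., o + 13] * (Vi - syn.E_AMPA)
        i_gaba_p = syn.g_GABA_p * y[..., o + 7] * (Vp - syn.E_GABA)
        i_gaba_i = syn.g_GABA_i * y[..., o + 9] * (Vi - syn.E_GABA)
        out.append(np.abs(i_ampa_p) + np.abs(i_gaba_p))
        out.append(np.abs(i_ampa_i) + np.abs(i_gaba_i))
    return np.stack(out, axis=-1)


def steady_sodium(Qp: float, adapt: AdaptationParams) -> float:
    """Sodium concentration at which the pump balances a constant firing rate."""
    f = lambda na: adapt.alpha_Na * Qp - float(na_pump(na, adapt))
    if Qp <= 0:
        return adapt.Na_eq
    hi = adapt.Na_eq
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("sodium influx exceeds maximal pump capacity")
    return optimize.brentq(f, adapt.Na_eq, hi, xtol=1e-12)


def initial_guess(params: ColumnParameters,
                  coupling: Optional[CouplingSpec] = None, columns: int = 1,
                  Vp: float = -60.0, Vi: float = -60.0) -> np.ndarray:
    """Consistent state guess with synapses at their algebraic steady state."""
    syn = params.synapses
    Qp = float(firing_rate(Vp, params.pyramidal))
    Qi = float(firing_rate(Vi, params.inhibitory))
    block = NVAR_INTRA + (NVAR_INTER if columns == 2 else 0)
    y = np.zeros(columns * block)
    for c in range(columns):
        o = c * block
        y[o + 0], y[o + 1] = Vp, Vi
        y[o + 2] = steady_sodium(Qp, params.adaptation)
        y[o + 3] = syn.N["p"]["p"] * Qp
        y[o + 5] = syn.N["i"]["p"] * Qp
        y[o + 7] = syn.N["p"]["i"] * Qi
        y[o + 9] = syn.N["i"]["i"] * Qi
        if columns == 2:
            y[o + 11] = coupling.N_pp_inter * Qp
            y[o + 13] = coupling.N_ip_inter * Qp
    return y


def fixed_point(params: ColumnParameters,
                coupling: Optional[CouplingSpec] = None, columns: int = 1,
                guess: Optional[np.ndarray] = None,
                drive_pp: Sequence[float] = (0.0, 0.0),
                drive_ip: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """Noise-free fixed point of the full RHS (multivariate root find)."""
    if guess is None:
        guess = initial_guess(params, coupling, columns)
    block = NVAR_INTRA + (NVAR_INTER if columns == 2 else 0)
    na_idx = [c * block + 2 for c in range(columns)]

    def objective(y):
        y = y.copy()
        y[na_idx] = np.maximum(y[na_idx], 1e-6)  # keep the solver in-domain
        return full_rhs(y, params, coupling, columns, drive_pp, drive_ip)

    guesses = [guess] + [initial_guess(params, coupling, columns, Vp=v, Vi=v)
                         for v in (-55.0, -52.0, -58.0, -62.0)]
    last = None
    for g in guesses:
        sol = optimize.root(objective, g, method="hybr", tol=1e-13)
        if sol.success and np.max(np.abs(objective(sol.x))) < 1e-9:
            return sol.x
        last = sol
    raise RuntimeError(f"fixed-point search failed: {last.message}")
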