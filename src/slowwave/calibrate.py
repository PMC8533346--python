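"""GABAergic-conductance calibration across brain states.

The wake regime is defined operationally: upscale the AMPAergic conductance
(following synaptic-homeostasis downscaling in the reverse direction) and
retune both GABAergic conductances so that the noise-free steady state of the
membrane potentials sits at the NREM Up-state values.  The Up-state targets
are the peak bins (0.5 mV) of the Vp and Vi distributions restricted to
Up-labeled samples of an NREM ensemble; the steady-state solve holds the
noise at its mean, in which case the two balance equations are *linear* in
(g_GABA_p, g_GABA_i) and solve in closed form.  The same solve with the
inter-column terms included counterbalances two-column coupling for any
inter/intra conductance ratio beta, in which the calibrated conductances are
exactly linear.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import analysis, model
from .params import (INTER_COLUMN_COUNTS, ColumnParameters, CouplingSpec,
                     column_preset, gaba_preset)
from .simulate import EnsembleTraces, NetworkConfig, StimulusSpec


@dataclass
class SteadyStateTargets:
    """Up-state membrane-potential targets (mV) with their provenance."""

    Vp_star: float
    Vi_star: float
    provenance: dict = dataclasses.field(default_factory=dict)

    def validate(self, E_GABA: float = -70.0, E_AMPA: float = 0.0) -> None:
        for v in (self.Vp_star, self.Vi_star):
            if not E_GABA < v < E_AMPA:
                raise ValueError("targets must lie between the GABA and AMPA "
                                 "reversal potentials")


def estimate_up_state_targets(ens: EnsembleTraces,
                              bin_mv: float = analysis.DEFAULT_BIN_MV,
                              c: float = analysis.SMOOTH_C["p"]
                              ) -> SteadyStateTargets:
    """Peak of the Up-state Vp and Vi distributions of an NREM ensemble.

    Up/Down labels come from thresholding the pooled (per-trial demeaned)
    pyramidal LFP at the half distance between its two smoothed modes.
    Fails explicitly if the LFP distribution is not bimodal (no Up states).
    """
    pre = slice(0, ens.n_samples)
    lfp = analysis.demean_prestimulus(ens.get("lfp_p", 0), pre)
    res, labels = analysis.updown_labels(lfp, c=c, bin_width=bin_mv)
    if labels is None:
        raise RuntimeError("no bimodality in the pooled LFP: cannot detect "
                           "Up states (is this an NREM ensemble?)")
    targets = []
    for name in ("Vp", "Vi"):
        v = np.asarray(ens.get(name, 0), float)
        dist = analysis.histogram(v[labels], bin_mv)
        targets.append(dist.mode)
    prov = dict(state=ens.network.state, n_trials=ens.n_trials,
                master_seed=ens.config.master_seed, bin_mv=bin_mv,
                threshold=res.threshold)
    t = SteadyStateTargets(targets[0], targets[1], prov)
    t.validate(ens.network.params.synapses.E_GABA,
               ens.network.params.synapses.E_AMPA)
    return t


def calibrate_g_gaba(targets: SteadyStateTargets, params: ColumnParameters,
                     g_ampa: float, beta: float = 0.0,
                     coupling: Optional[CouplingSpec] = None,
                     C: float = model.C_SIGMOID) -> Tuple[float, float]:
    """Solve the mean-drive steady state for (g_GABA_p, g_GABA_i).

    With both columns symmetric and the noise at its mean, setting the
    membrane and sodium derivatives to zero at (Vp*, Vi*) gives one balance
    equation per population; each is linear in its GABAergic conductance:

        0 = -(V* - E_L) - g_AMPA (N_intra + beta N_inter) Q (V* - E_AMPA)
            - g_GABA N Q (V* - E_GABA) [- (tau_p/Cm) I_KNa, pyramidal only]

    Raises if a target is unreachable with a positive conductance.
    """
    if g_ampa <= 0:
        raise ValueError("g_ampa must be positive")
    targets.validate(params.synapses.E_GABA, params.synapses.E_AMPA)
    pyr, inh = params.pyramidal, params.inhibitory
    syn, adapt = params.synapses, params.adaptation
    mean = params.noise.mean
    nppx = coupling.N_pp_inter if coupling is not None else 0.0
    nipx = coupling.N_ip_inter if coupling is not None else 0.0
    if beta and coupling is None:
        raise ValueError("beta > 0 requires inter-column connection counts")

    Vp, Vi = targets.Vp_star, targets.Vi_star
    Qp = float(model.firing_rate(Vp, pyr, C))
    Qi = float(model.firing_rate(Vi, inh, C))
    na_star = model.steady_sodium(Qp, adapt)
    i_kna = float(model.kna_current(Vp, na_star, adapt))

    s_pp = syn.N["p"]["p"] * Qp + mean
    s_ip = syn.N["i"]["p"] * Qp + mean
    s_pi = syn.N["p"]["i"] * Qi
    s_ii = syn.N["i"]["i"] * Qi
    s_ppx = nppx * Qp
    s_ipx = nipx * Qp

    num_p = (-(Vp - pyr.E_L)
             - g_ampa * (s_pp + beta * s_ppx) * (Vp - syn.E_AMPA)
             - pyr.tau / adapt.Cm * i_kna)
    num_i = (-(Vi - inh.E_L)
             - g_ampa * (s_ip + beta * s_ipx) * (Vi - syn.E_AMPA))
    den_p = s_pi * (Vp - syn.E_GABA)
    den_i = s_ii * (Vi - syn.E_GABA)
    g_gaba_p = num_p / den_p
    g_gaba_i = num_i / den_i
    if not (g_gaba_p > 0 and g_gaba_i > 0):
        raise RuntimeError(
            f"targets unreachable with positive GABA conductances "
            f"(residual solve gave g_GABA_p={g_gaba_p:.4g}, "
            f"g_GABA_i={g_gaba_i:.4g})")
    return float(g_gaba_p), float(g_gaba_i)


def fixed_point_targets(params: ColumnParameters,
                        coupling: Optional[CouplingSpec] = None,
                        columns: int = 1) -> SteadyStateTargets:
    """Targets taken from the model's own noise-free fixed point (for
    round-trip checks of the calibration solve)."""
    y = model.fixed_point(params, coupling, columns,
                          drive_pp=(params.noise.mean,) * 2,
                          drive_ip=(params.noise.mean,) * 2)
    return SteadyStateTargets(float(y[0]), float(y[1]),
                              dict(source="fixed_point"))


def build_state_preset(state: str, columns: int = 1,
                       g_ampa: Optional[float] = None,
                       beta: Optional[float] = None,
                       stimulus: Optional[StimulusSpec] = None,
                       targets: Optional[SteadyStateTargets] = None
                       ) -> NetworkConfig:
    """NetworkConfig for a brain state, table-exact where tabulated.

    One-column presets and the two-column beta = 1 operating points are taken
    from the published per-state tables; the wake two-column grid over
    g_AMPA in {2, 6, 10} x beta in {1..5} uses the tabulated calibrated
    GABAergic conductances.  Any other (g_ampa, beta) combination requires
    explicit Up-state ``targets`` and is calibrated on demand.
    """
    params = column_preset(state, columns)
    if columns == 1:
        if g_ampa is not None or beta is not None:
            raise ValueError("one-column presets are fixed per state")
        return NetworkConfig(params, 1, None, stimulus, state)

    beta = 1.0 if beta is None else float(beta)
    coupling = CouplingSpec(beta=beta, **INTER_COLUMN_COUNTS)
    g_ampa = params.synapses.g_AMPA_p if g_ampa is None else float(g_ampa)

    default_g = column_preset(state, 2).synapses.g_AMPA_p
    if g_ampa == default_g and beta == 1.0:
        pass  # table-exact two-column operating point
    elif state == "wake":
        try:
            gp, gi = gaba_preset(g_ampa, beta)
        except KeyError:
            if targets is None:
                raise
            gp, gi = calibrate_g_gaba(targets, params, g_ampa, beta, coupling)
        params = params.with_conductances(g_ampa, gp, gi)
    else:
        if targets is None:
            raise KeyError(f"no tabulated NREM conductances for "
                           f"g_AMPA={g_ampa}, beta={beta}")
        gp, gi = calibrate_g_gaba(targets, params, g_ampa, beta, coupling)
        params = params.with_conductances(g_ampa, gp, gi)
    return NetworkConfig(params, 2, coupling, stimulus, state)
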