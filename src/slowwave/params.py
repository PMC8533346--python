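"""Parameter containers and brain-state presets for the cortical-column model.

A cortical column couples one pyramidal and one inhibitory neural mass through
AMPAergic and GABAergic synapses.  The NREM/wake dichotomy is controlled by the
average AMPAergic conductance ``g_AMPA`` (upscaled in wake, following the
synaptic-homeostasis picture), with GABAergic conductances co-tuned so that the
wake operating point sits at the NREM Up-state membrane potentials.

All time constants are in ms, voltages in mV, rates in ms^-1, sodium in mM.
Conductances are dimensionless scaling factors multiplying activity times
driving force (their tabulated unit "ms" is carried along but not interpreted).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import TextIO, Union

import yaml


@dataclass
class PopulationParams:
    """Sigmoidal rate function and passive membrane of one neural mass."""

    Qmax: float   # maximal firing rate (ms^-1)
    theta: float  # rate threshold / half activation (mV)
    sigma: float  # inverse neural gain (mV)
    tau: float    # membrane time constant (ms)
    E_L: float    # leak reversal (mV)

    def __post_init__(self) -> None:
        if not (self.Qmax > 0 and self.sigma > 0 and self.tau > 0):
            raise ValueError("Qmax, sigma and tau must be positive")


@dataclass
class SynapticParams:
    """Second-order (critically damped) synaptic kinetics and conductances.

    ``N`` holds mean connection counts indexed ``N[post][pre]`` with
    populations named 'p' (pyramidal) and 'i' (inhibitory).
    """

    gamma_p: float  # AMPA synaptic rate constant (ms^-1)
    gamma_i: float  # GABA synaptic rate constant (ms^-1)
    N: dict = field(default_factory=dict)
    g_AMPA_p: float = 1.0
    g_AMPA_i: float = 1.0
    g_GABA_p: float = 1.0
    g_GABA_i: float = 1.0
    E_AMPA: float = 0.0    # mV
    E_GABA: float = -70.0  # mV

    def __post_init__(self) -> None:
        if not (self.gamma_p > 0 and self.gamma_i > 0):
            raise ValueError("synaptic rate constants must be positive")
        for post in ("p", "i"):
            for pre in ("p", "i"):
                if self.N.get(post, {}).get(pre, 0) < 0:
                    raise ValueError("connection counts must be >= 0")
        for g in (self.g_AMPA_p, self.g_AMPA_i, self.g_GABA_p, self.g_GABA_i):
            if g < 0:
                raise ValueError("conductances must be >= 0")
        if not self.E_AMPA > self.E_GABA:
            raise ValueError("E_AMPA must exceed E_GABA")


@dataclass
class AdaptationParams:
    """Sodium-gated potassium adaptation of the pyramidal mass.

    The K(Na) current hyperpolarizes the pyramidal population as intracellular
    sodium accumulates with firing; its slow build-up terminates Up states and
    underlies the slow oscillation of the NREM regime.
    """

    g_KNa: float    # mS/cm^2
    E_K: float      # mV (negative)
    tau_Na: float   # ms
    alpha_Na: float  # mM*ms, Na influx per unit firing rate
    R_pump: float   # mM, pump strength
    Na_eq: float    # mM, resting sodium
    Cm: float = 1.0  # uF/cm^2

    def __post_init__(self) -> None:
        if self.E_K >= 0:
            raise ValueError("E_K must be negative")
        for name in ("g_KNa", "tau_Na", "alpha_Na", "R_pump", "Na_eq", "Cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NoiseSpec:
    """White-noise drive entering the intra-column AMPAergic synapse equations.

    The drive is a zero-mean Gaussian white process added to the presynaptic
    rate; its standard deviation is state dependent (1.8 ms^-1 in NREM versus
    1 ms^-1 in wake, reflecting the larger rate fluctuations of NREM sleep).
    """

    mean: float = 0.0  # baseline drive (ms^-1)
    std: float = 1.0   # white-noise amplitude (ms^-1)

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise std must be >= 0")


@dataclass
class CouplingSpec:
    """Symmetric excitatory coupling between the two cortical columns.

    ``beta`` is the ratio of the inter-column to the intra-column average
    AMPAergic conductance; the inter-column projections originate exclusively
    from pyramidal populations.
    """

    beta: float = 1.0
    N_pp_inter: float = 8.0
    N_ip_inter: float = 2.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.N_pp_inter < 0 or self.N_ip_inter < 0:
            raise ValueError("inter-column connection counts must be >= 0")


@dataclass
class ColumnParameters:
    """All per-column constants: populations, synapses, adaptation, noise."""

    pyramidal: PopulationParams
    inhibitory: PopulationParams
    synapses: SynapticParams
    adaptation: AdaptationParams
    noise: NoiseSpec

    def replace(self, **kwargs) -> "ColumnParameters":
        return dataclasses.replace(self, **kwargs)

    def with_conductances(self, g_ampa=None, g_gaba_p=None, g_gaba_i=None
                          ) -> "ColumnParameters":
        syn = dataclasses.replace(self.synapses)
        if g_ampa is not None:
            syn.g_AMPA_p = syn.g_AMPA_i = float(g_ampa)
        if g_gaba_p is not None:
            syn.g_GABA_p = float(g_gaba_p)
        if g_gaba_i is not None:
            syn.g_GABA_i = float(g_gaba_i)
        return dataclasses.replace(self, synapses=syn)


# ---------------------------------------------------------------------------
# Presets.  The per-state one-column parameter sets, the two-column coupling
# counts, and the calibrated GABAergic conductance grids over (g_AMPA, beta).
# ---------------------------------------------------------------------------

_COMMON = dict(
    Qmax_p=0.03, Qmax_i=0.06, theta=-58.5, sigma_p=6.7, sigma_i=6.0,
    tau=30.0, E_L_p=-66.0, E_L_i=-64.0,
    gamma_p=70e-3, gamma_i=58.6e-3,
    Npp=160.0, Nip=40.0, Npi=160.0, Nii=40.0,
    E_AMPA=0.0, E_GABA=-70.0,
    g_KNa=1.9, E_K=-100.0, tau_Na=1.7, alpha_Na=2.0,
    R_pump=0.09, Na_eq=9.5, Cm=1.0,
)

# state -> (noise std, g_AMPA, g_GABA_p, g_GABA_i), one-column operating points
_ONE_COLUMN = {
    "nrem": dict(std=1.8, g_ampa=1.0, g_gaba_p=1.0, g_gaba_i=1.0),
    "wake": dict(std=1.0, g_ampa=2.0, g_gaba_p=2.294, g_gaba_i=2.313),
}

# two-column operating points at beta = 1 (baseline coupling)
_TWO_COLUMN = {
    "nrem": dict(std=1.8, g_ampa=1.0, g_gaba_p=1.082, g_gaba_i=1.066),
    "wake": dict(std=1.0, g_ampa=2.0, g_gaba_p=2.446, g_gaba_i=2.445),
}

INTER_COLUMN_COUNTS = dict(N_pp_inter=8.0, N_ip_inter=2.0)

# Calibrated wake GABAergic conductances on the (g_AMPA, beta) grid:
# GABA_GRID[g_ampa][pop][beta - 1]
GABA_GRID = {
    2.0: {"p": [2.446, 2.599, 2.752, 2.905, 3.058],
          "i": [2.445, 2.576, 2.708, 2.840, 2.971]},
    6.0: {"p": [8.869, 9.327, 9.786, 10.245, 10.704],
          "i": [7.972, 8.367, 8.761, 9.156, 9.551]},
    10.0: {"p": [15.291, 16.055, 16.820, 17.585, 18.349],
           "i": [13.499, 14.157, 14.815, 15.473, 16.131]},
}

STATES = ("nrem", "wake")


def _column_from(values: dict) -> ColumnParameters:
    c = _COMMON
    return ColumnParameters(
        pyramidal=PopulationParams(c["Qmax_p"], c["theta"], c["sigma_p"],
                                   c["tau"], c["E_L_p"]),
        inhibitory=PopulationParams(c["Qmax_i"], c["theta"], c["sigma_i"],
                                    c["tau"], c["E_L_i"]),
        synapses=SynapticParams(
            gamma_p=c["gamma_p"], gamma_i=c["gamma_i"],
            N={"p": {"p": c["Npp"], "i": c["Npi"]},
               "i": {"p": c["Nip"], "i": c["Nii"]}},
            g_AMPA_p=values["g_ampa"], g_AMPA_i=values["g_ampa"],
            g_GABA_p=values["g_gaba_p"], g_GABA_i=values["g_gaba_i"],
            E_AMPA=c["E_AMPA"], E_GABA=c["E_GABA"]),
        adaptation=AdaptationParams(c["g_KNa"], c["E_K"], c["tau_Na"],
                                    c["alpha_Na"], c["R_pump"], c["Na_eq"],
                                    c["Cm"]),
        noise=NoiseSpec(mean=0.0, std=values["std"]),
    )


def column_preset(state: str, columns: int = 1) -> ColumnParameters:
    """Per-column parameter preset for a brain state ('nrem' or 'wake')."""
    state = state.lower()
    if state not in STATES:
        raise KeyError(f"unknown state {state!r}; expected one of {STATES}")
    table = _ONE_COLUMN if columns == 1 else _TWO_COLUMN
    return _column_from(table[state])


def gaba_preset(g_ampa: float, beta: int) -> tuple:
    """Tabulated wake (g_GABA_p, g_GABA_i) for the two-column model."""
    grid = GABA_GRID.get(float(g_ampa))
    if grid is None or not 1 <= int(beta) <= 5 or beta != int(beta):
        raise KeyError(f"no tabulated conductances for g_AMPA={g_ampa}, "
                       f"beta={beta}")
    b = int(beta) - 1
    return grid["p"][b], grid["i"][b]


# ---------------------------------------------------------------------------
# Human-readable (YAML) serialization with exact round-trip.
# ---------------------------------------------------------------------------

def to_dict(params: ColumnParameters) -> dict:
    return dataclasses.asdict(params)


def from_dict(d: dict) -> ColumnParameters:
    return ColumnParameters(
        pyramidal=PopulationParams(**d["pyramidal"]),
        inhibitory=PopulationParams(**d["inhibitory"]),
        synapses=SynapticParams(**d["synapses"]),
        adaptation=AdaptationParams(**d["adaptation"]),
        noise=NoiseSpec(**d["noise"]),
    )


def dump_yaml(params: ColumnParameters, stream: Union[str, TextIO, None] = None):
    """Serialize a parameter set to YAML (path, stream, or returned string)."""
    d = to_dict(params)
    if stream is None:
        return yaml.safe_dump(d, sort_keys=True)
    if isinstance(stream, (str, bytes)):
        with open(stream, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return None
    yaml.safe_dump(d, stream, sort_keys=True)
    return None


def load_yaml(source: Union[str, TextIO]) -> ColumnParameters:
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            return from_dict(yaml.safe_load(fh))
    if isinstance(source, str):
        return from_dict(yaml.safe_load(io.StringIO(source)))
    return from_dict(yaml.safe_load(source))
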