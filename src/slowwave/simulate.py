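"""Seeded one- and two-column simulations.

An ensemble is a set of independent trials.  Each trial owns a
``numpy.random.SeedSequence`` child of the master seed; from it, each column
draws two dedicated substreams (initial conditions and noise), so a trial is
bit-reproducible in isolation, independent of ensemble size, execution order
and chunking, and column 0 of a decoupled two-column run reproduces a matched
one-column run exactly.

Each trial integrates ``burn_in + trial_length`` seconds with the stochastic
Heun scheme and records only the post-burn-in part: membrane potentials, [Na]
and the pyramidal/inhibitory LFP per column (firing rates are instantaneous
functions of V and are derived on demand).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from . import integrate, model
from .params import ColumnParameters, CouplingSpec

SIGNAL_NAMES = ("Vp", "Vi", "Na", "lfp_p", "lfp_i")


@dataclass
class StimulusSpec:
    """Square mean-shift of the noise drive to one pyramidal population."""

    onset: float = 5.0        # s, relative to trial start (after burn-in)
    duration: float = 100.0   # ms
    amplitude: float = 1.0    # ms^-1
    column: int = 0           # perturbed column

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")


@dataclass
class IntegrationConfig:
    dt: float = 0.1            # ms
    trial_length: float = 10.0  # s
    burn_in: float = 10.0      # s
    n_trials: int = 500
    master_seed: int = 0
    engine: str = "auto"       # auto | numba | numpy
    chunk_steps: int = 20000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.burn_in < 0 or self.trial_length <= 0:
            raise ValueError("dt/trial_length must be positive, burn_in >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class NetworkConfig:
    """Wiring of the simulated network: per-column parameters plus coupling."""

    params: ColumnParameters
    columns: int = 1
    coupling: Optional[CouplingSpec] = None
    stimulus: Optional[StimulusSpec] = None
    state: str = ""            # descriptive label ('nrem'/'wake')

    def __post_init__(self) -> None:
        if self.columns not in (1, 2):
            raise ValueError("columns must be 1 or 2")
        if self.columns == 2 and self.coupling is None:
            raise ValueError("two-column network requires a CouplingSpec")

    @property
    def g_ampa(self) -> float:
        return self.params.synapses.g_AMPA_p

    @property
    def beta(self) -> float:
        return self.coupling.beta if self.coupling is not None else 0.0


class SimulationDiverged(RuntimeError):
    def __init__(self, trials: Sequence[int], master_seed):
        self.trials = list(trials)
        super().__init__(f"non-finite state in trials {self.trials} "
                         f"(master_seed={master_seed})")


@dataclass
class EnsembleTraces:
    """Recorded per-trial time series for every column and population."""

    data: np.ndarray                 # (5*columns, n_trials, n_samples) f32
    dt: float                        # ms
    network: NetworkConfig
    config: IntegrationConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, relative to trial start (post burn-in)."""
        return (np.arange(1, self.n_samples + 1) * self.dt) / 1000.0

    def get(self, name: str, column: int = 0) -> np.ndarray:
        """(n_trials, n_samples) series for one signal of one column."""
        if name not in SIGNAL_NAMES:
            raise KeyError(f"unknown signal {name!r}; expected {SIGNAL_NAMES}")
        if not 0 <= column < self.network.columns:
            raise IndexError("column out of range")
        return self.data[5 * column + SIGNAL_NAMES.index(name)]

    def rate(self, pop: str = "p", column: int = 0, hz: bool = False
             ) -> np.ndarray:
        """Instantaneous firing rate from the membrane potential (ms^-1/Hz)."""
        params = (self.network.params.pyramidal if pop == "p"
                  else self.network.params.inhibitory)
        v = self.get("Vp" if pop == "p" else "Vi", column)
        q = model.firing_rate(v.astype(np.float64), params)
        return q * 1000.0 if hz else q

    def window(self, t0: float, t1: float) -> slice:
        """Index slice for the half-open time window [t0, t1) in seconds."""
        i0 = int(round(t0 * 1000.0 / self.dt))
        i1 = int(round(t1 * 1000.0 / self.dt))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def save(self, path: str) -> None:
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                            data=self.data, dt=self.dt)
        meta = dict(self.meta)
        meta.update(state=self.network.state, columns=self.network.columns,
                    g_ampa=self.network.g_ampa, beta=self.network.beta,
                    n_trials=self.n_trials, dt=self.dt,
                    master_seed=self.config.master_seed)
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=float)


def trial_seed_sequences(master_seed: int, n_trials: int
                         ) -> List[np.random.SeedSequence]:
    return list(np.random.SeedSequence(master_seed).spawn(n_trials))


def _draw_initial(ic_rng: np.random.Generator, columns: int,
                  na_eq: float) -> np.ndarray:
    """Uniform initial conditions: V in [-80, -50] mV, small nonnegative
    synaptic activities, [Na] within 0.5 mM of rest, zero derivatives."""
    block = model.NVAR_INTRA + (model.NVAR_INTER if columns == 2 else 0)
    y = np.zeros(columns * block)
    for c in range(columns):
        o = c * block
        y[o + 0] = ic_rng.uniform(-80.0, -50.0)
        y[o + 1] = ic_rng.uniform(-80.0, -50.0)
        y[o + 2] = ic_rng.uniform(na_eq - 0.5, na_eq + 0.5)
        for k in (3, 5, 7, 9):
            y[o + k] = ic_rng.uniform(0.0, 1.0)
        if columns == 2:
            for k in (11, 13):
                y[o + k] = ic_rng.uniform(0.0, 1.0)
    return y


def run_ensemble(network: NetworkConfig, cfg: IntegrationConfig,
                 trial_seeds: Optional[Sequence[np.random.SeedSequence]] = None
                 ) -> EnsembleTraces:
    """Simulate ``cfg.n_trials`` independent trials (vectorized over trials)."""
    cols = network.columns
    params, coupling = network.params, network.coupling
    dt = cfg.dt
    n_rec = int(round(cfg.trial_length * 1000.0 / dt))
    burn_steps = int(round(cfg.burn_in * 1000.0 / dt))
    n_total = burn_steps + n_rec

    stim = network.stimulus
    if stim is not None:
        if stim.column >= cols:
            raise ValueError("stimulus targets a non-existent column")
        on = burn_steps + int(round(stim.onset * 1000.0 / dt))
        off = on + int(round(stim.duration / dt))
        if off > n_total:
            raise ValueError("stimulus extends past the end of the trial")
        if stim.column != 0:
            raise NotImplementedError("stimulus is delivered to column 0")
    else:
        on = off = -1

    if trial_seeds is None:
        trial_seeds = trial_seed_sequences(cfg.master_seed, cfg.n_trials)
    elif len(trial_seeds) != cfg.n_trials:
        raise ValueError("trial_seeds length must equal n_trials")

    # per-trial, per-column substreams: (ic, noise) x column
    ic_rngs, noise_rngs = [], []
    for ss in trial_seeds:
        children = ss.spawn(2 * cols)
        ic_rngs.append([np.random.default_rng(children[2 * c])
                        for c in range(cols)])
        noise_rngs.append([np.random.default_rng(children[2 * c + 1])
                           for c in range(cols)])

    na_eq = params.adaptation.Na_eq
    y = np.zeros((cfg.n_trials, model.state_size(cols)))
    block = model.NVAR_INTRA + (model.NVAR_INTER if cols == 2 else 0)
    for i in range(cfg.n_trials):
        for c in range(cols):
            o = c * block
            sub = _draw_initial(ic_rngs[i][c], 1, na_eq)
            y[i, o:o + model.NVAR_INTRA] = sub
            if cols == 2:
                y[i, o + 11] = ic_rngs[i][c].uniform(0.0, 1.0)
                y[i, o + 13] = ic_rngs[i][c].uniform(0.0, 1.0)

    noise_amp = (params.synapses.gamma_p ** 2 * params.noise.std
                 * np.sqrt(dt))
    noise_mean = params.noise.mean
    rec = np.zeros((5 * cols, cfg.n_trials, n_rec), dtype=np.float32)

    runner = None
    if cfg.engine in ("auto", "numba"):
        runner = integrate.get_numba_chunk_runner()
        if runner is None and cfg.engine == "numba":
            raise RuntimeError("numba engine requested but unavailable")
    consts = integrate.pack_constants(params, coupling)

    start = 0
    while start < n_total:
        chunk = min(cfg.chunk_steps, n_total - start)
        noise = np.empty((cfg.n_trials, chunk, 2 * cols))
        for i in range(cfg.n_trials):
            for c in range(cols):
                noise[i, :, 2 * c:2 * c + 2] = \
                    noise_rngs[i][c].standard_normal((chunk, 2))
        stim_drive = np.zeros(chunk)
        if stim is not None:
            k0 = max(on - start, 0)
            k1 = min(off - start, chunk)
            if k1 > k0:
                stim_drive[k0:k1] = stim.amplitude
        if runner is not None:
            runner(y, consts, cols, dt, noise_amp, noise, stim_drive,
                   noise_mean, rec, True, start, burn_steps)
        else:
            y = integrate.run_chunk_numpy(
                y, params, coupling, cols, dt, noise_amp, noise, stim_drive,
                noise_mean, rec, start, burn_steps)
        start += chunk

    bad = np.flatnonzero(~np.all(np.isfinite(y), axis=1))
    if bad.size:
        raise SimulationDiverged(bad, cfg.master_seed)

    meta = dict(state=network.state, columns=cols, g_ampa=network.g_ampa,
                beta=network.beta, master_seed=cfg.master_seed,
                n_trials=cfg.n_trials, dt=dt, trial_length=cfg.trial_length,
                burn_in=cfg.burn_in,
                stimulus=dataclasses.asdict(stim) if stim else None,
                engine="numba" if runner is not None else "numpy")
    return EnsembleTraces(rec, dt, network, cfg, meta)


def run_trial(network: NetworkConfig, cfg: IntegrationConfig,
              seed: Union[int, np.random.SeedSequence, None] = None
              ) -> EnsembleTraces:
    """Simulate a single trial (an ensemble of one)."""
    cfg1 = dataclasses.replace(cfg, n_trials=1)
    if seed is None:
        seeds = None
    elif isinstance(seed, np.random.SeedSequence):
        seeds = [seed]
    else:
        cfg1 = dataclasses.replace(cfg1, master_seed=int(seed))
        seeds = trial_seed_sequences(int(seed), 1)
    return run_ensemble(network, cfg1, trial_seeds=seeds)
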