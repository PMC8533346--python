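"""End-to-end reproductions of the simulation experiments.

Each experiment runs ensembles, analyses and statistics from a single master
seed and emits a JSON-serializable report embedding the fully resolved
configuration.  The default profile is desk-scale (100 trials, 500
permutations); ``full_scale=True`` switches to 500 trials / 1000
permutations (the publication-scale profile).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import analysis, calibrate, cluster
from .params import gaba_preset
from .simulate import (EnsembleTraces, IntegrationConfig, StimulusSpec,
                       run_ensemble)

DESK_TRIALS, DESK_PERMS = 100, 500
FULL_TRIALS, FULL_PERMS = 500, 1000

EXPERIMENTS = ("fig2", "fig3", "fig4", "fig5", "fig6", "tables")


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def simulate_state(state: str, columns: int = 1, g_ampa=None, beta=None,
                   stimulus: Optional[StimulusSpec] = None, trials: int = 100,
                   seed: int = 0, trial_length: float = 10.0,
                   burn_in: float = 10.0, engine: str = "auto",
                   targets=None) -> EnsembleTraces:
    """Convenience wrapper: preset network + integration config + run."""
    net = calibrate.build_state_preset(state, columns, g_ampa, beta,
                                       stimulus, targets)
    cfg = IntegrationConfig(trial_length=trial_length, burn_in=burn_in,
                            n_trials=trials, master_seed=seed, engine=engine)
    return run_ensemble(net, cfg)


def _windows(ens: EnsembleTraces):
    stim = ens.network.stimulus
    onset = stim.onset if stim is not None else 5.0
    pre = ens.window(0.0, onset)
    post = ens.window(onset, 2 * onset)
    return pre, post


def _evoked_test(ens: EnsembleTraces, signal: str, column: int,
                 perms: int, rng: np.random.Generator,
                 demean: bool = False) -> cluster.ClusterTestResult:
    if signal == "rate":
        x = ens.rate("p", column)
    else:
        x = np.asarray(ens.get(signal, column), float)
    pre, post = _windows(ens)
    if demean:
        x = analysis.demean_prestimulus(x, pre)
    return cluster.cluster_permutation_test(
        x[:, post], x[:, pre], ens.dt, n_perm_min=perms, rng=rng)


def _cluster_summary(res: cluster.ClusterTestResult) -> dict:
    def rec(c):
        if c is None:
            return None
        return dict(p=c.p, area_s=c.area, length_ms=c.length_ms,
                    start_s=c.start_s, sign=c.sign)
    return dict(n_clusters=len(res.clusters),
                baseline_area=res.baseline_area,
                first=rec(res.first()),
                first_positive=rec(res.first_of_sign(+1)),
                first_negative=rec(res.first_of_sign(-1)))


def reproduce(name: str, trials: int = DESK_TRIALS, perms: int = DESK_PERMS,
              seed: int = 0, full_scale: bool = False,
              engine: str = "auto", betas=(1, 2, 3, 4, 5),
              g_ampas=(2.0, 6.0, 10.0)) -> dict:
    """Run one named experiment and return its machine-readable report."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; expected {EXPERIMENTS}")
    if full_scale:
        trials, perms = FULL_TRIALS, FULL_PERMS
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    report = dict(experiment=name, trials=trials, perms=perms, seed=seed,
                  engine=engine)
    fn = globals()[f"_exp_{name}"]
    report.update(fn(trials, perms, seed, rng, engine, betas, g_ampas))
    return _jsonable(report)


def _exp_fig2(trials, perms, seed, rng, engine, betas, g_ampas):
    out = {}
    for state in ("nrem", "wake"):
        ens = simulate_state(state, trials=trials, seed=seed, engine=engine)
        lfp = analysis.demean_prestimulus(ens.get("lfp_p"),
                                          slice(0, ens.n_samples))
        res, labels = analysis.updown_labels(lfp)
        spec = analysis.spectrogram(lfp, ens.dt)
        ratio = analysis.band_ratio(spec.freqs, spec.psd_trials)
        entry = dict(bimodal=res.bimodal, threshold=res.threshold,
                     band_ratio_mean=float(ratio.mean()),
                     psd_low=float(spec.psd_mean[spec.freqs < 4.0].mean()),
                     psd_high=float(spec.psd_mean[spec.freqs > 30.0].mean()))
        if labels is not None:
            rate_hz = ens.rate("p", hz=True)
            dists = analysis.split_distributions(rate_hz, labels, 0.5)
            vdists = analysis.split_distributions(ens.get("Vp"), labels, 0.5)
            entry.update(
                down_rate_mode_hz=dists["down"].mode,
                up_rate_mode_hz=dists["up"].mode,
                up_fraction=dists["up"].mass,
                up_vp_mode=vdists["up"].mode,
                down_vp_mode=vdists["down"].mode)
        out[state] = entry
    out["nrem_bimodal"] = out["nrem"]["bimodal"]
    out["wake_bimodal"] = out["wake"]["bimodal"]
    return out


def _exp_fig3(trials, perms, seed, rng, engine, betas, g_ampas):
    stim = StimulusSpec()
    out = {}
    ensembles = {}
    for state in ("nrem", "wake"):
        ens = simulate_state(state, stimulus=stim, trials=trials, seed=seed,
                             engine=engine)
        ensembles[state] = ens
        out[state] = {sig: _cluster_summary(
            _evoked_test(ens, sig, 0, perms, rng))
            for sig in ("lfp_p", "rate", "Vp")}
    # cross-state deflection amplitudes on prestimulus-demeaned averages
    amp = {}
    for sig in ("lfp_p", "rate", "Vp"):
        amp[sig] = {}
        for state, ens in ensembles.items():
            x = ens.rate("p") if sig == "rate" else np.asarray(
                ens.get(sig, 0), float)
            pre, post = _windows(ens)
            x = analysis.demean_prestimulus(x, pre)
            m = x[:, post].mean(axis=0)
            amp[sig][state] = dict(pos=float(m.max()), neg=float(m.min()))
    out["deflection_amplitudes"] = amp
    return out


def _exp_fig4(trials, perms, seed, rng, engine, betas, g_ampas):
    stim = StimulusSpec()
    out = {}
    for state in ("nrem", "wake"):
        ens = simulate_state(state, columns=2, beta=1, stimulus=stim,
                             trials=trials, seed=seed, engine=engine)
        out[state] = dict(
            perturbed={sig: _cluster_summary(
                _evoked_test(ens, sig, 0, perms, rng))
                for sig in ("lfp_p", "rate", "Vp")},
            unperturbed={sig: _cluster_summary(
                _evoked_test(ens, sig, 1, perms, rng))
                for sig in ("lfp_p", "rate", "Vp")})
    return out


def _propagation_point(g_ampa, beta, trials, perms, seed, rng, engine):
    ens = simulate_state("wake", columns=2, g_ampa=g_ampa, beta=beta,
                         stimulus=StimulusSpec(), trials=trials, seed=seed,
                         engine=engine)
    x = ens.rate("p", column=1)
    pre, post = _windows(ens)
    prop = cluster.propagation_metrics(x[:, post], x[:, pre], ens.dt,
                                       n_perm_min=perms, rng=rng)
    return prop.as_dict()


def _exp_fig5(trials, perms, seed, rng, engine, betas, g_ampas):
    out = {}
    for g in (2.0, 6.0):
        for b in (1, 2):
            out[f"g{g:g}_beta{b}"] = _propagation_point(
                g, b, trials, perms, seed, rng, engine)
    return out


def _exp_fig6(trials, perms, seed, rng, engine, betas, g_ampas):
    out = {}
    for g in g_ampas:
        for b in betas:
            out[f"g{g:g}_beta{b}"] = _propagation_point(
                g, b, trials, perms, seed, rng, engine)
    return out


def _exp_tables(trials, perms, seed, rng, engine, betas, g_ampas):
    nrem = simulate_state("nrem", trials=trials, seed=seed, engine=engine)
    targets = calibrate.estimate_up_state_targets(nrem)
    params = calibrate.build_state_preset("wake", 2).params
    coupling = calibrate.build_state_preset("wake", 2).coupling
    out = dict(targets=dict(Vp_star=targets.Vp_star, Vi_star=targets.Vi_star))
    grid = {}
    for g in g_ampas:
        for b in betas:
            gp, gi = calibrate.calibrate_g_gaba(targets, params, g, b,
                                                coupling)
            ref_p, ref_i = gaba_preset(g, b)
            grid[f"g{g:g}_beta{b}"] = dict(
                g_gaba_p=gp, g_gaba_i=gi,
                table_p=ref_p, table_i=ref_i,
                rel_err_p=abs(gp - ref_p) / ref_p,
                rel_err_i=abs(gi - ref_i) / ref_i)
    out["grid"] = grid
    return out


def make_fixtures(scale: str = "unit", seed: int = 0,
                  engine: str = "auto") -> dict:
    """Tiny deterministic bundles for tests: seeded mini-ensembles plus
    synthetic bimodal and null datasets."""
    if scale not in ("unit", "smoke"):
        raise ValueError("scale must be 'unit' or 'smoke'")
    trials, length, burn = (8, 2.0, 2.0) if scale == "unit" else (16, 10.0, 5.0)
    rng = np.random.default_rng(seed)
    nrem = simulate_state("nrem", trials=trials, seed=seed,
                          trial_length=length, burn_in=burn, engine=engine)
    wake = simulate_state("wake", trials=trials, seed=seed + 1,
                          trial_length=length, burn_in=burn, engine=engine)
    bimodal = np.concatenate([rng.normal(-40.0, 3.0, 4000),
                              rng.normal(40.0, 3.0, 6000)])
    null_a = rng.normal(size=(16, 400))
    null_b = rng.normal(size=(16, 400))
    return dict(nrem=nrem, wake=wake, bimodal_samples=bimodal,
                null_groups=(null_a, null_b), seed=seed, scale=scale)
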