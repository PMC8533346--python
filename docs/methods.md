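# Methods

## Model

`slowwave` simulates one or two cortical columns, each reduced to a pyramidal
(`p`) and an inhibitory (`i`) neural mass. The average membrane potentials
obey a conductance-based balance of a leak current, AMPAergic and GABAergic
synaptic currents and — for the pyramidal mass only — a sodium-gated
potassium adaptation current:

    tau_p dVp/dt = -(Vp - E_Lp) - I_AMPA_p - I_GABA_p - (tau_p / Cm) I_KNa
    tau_i dVi/dt = -(Vi - E_Li) - I_AMPA_i - I_GABA_i

The firing rate of each mass is an instantaneous sigmoid of its potential,
`Q(V) = Qmax (1 + tanh(C (V - theta) / sigma)) / 2`, with
`C = pi / (2 sqrt(3))` linking the inverse neural gain `sigma` to the slope
at threshold. `C` is exposed as an argument so the sigmoid convention can be
overridden. The leak carries an implicit unit conductance (`I_L = V - E_L`):
no separate leak conductance appears in the parameter tables and the
membrane time constant already sets the relaxation timescale.

Synaptic activity `s_kk'` (postsynaptic `k`, presynaptic `k'`) follows
critically damped second-order kinetics,

    s'' = gamma^2 (N Q_pre + phi - s) - 2 gamma s'

whose impulse response is the alpha function `gamma^2 t exp(-gamma t)`.
Synaptic currents are `g * s * (V - E_rev)` with the tabulated `g` values
treated as dimensionless scaling factors. The extrinsic drive `phi` — a
zero-mean Gaussian white process plus, for the perturbed column's `s_pp`
equation, the square stimulus `xi` — enters only the intra-column AMPAergic
equations (`s_pp` and `s_ip`, independent processes), reflecting extrinsic
input arriving through excitatory synapses; GABAergic and inter-column
equations receive none. Whether the generic synaptic equation should also
carry noise on GABAergic synapses is genuinely open; the excitatory-only
choice is the one consistent with the morphological argument for
long-range pyramidal axons, and the noise entry point is confined to one
code path so the alternative is a one-line change.

Adaptation: `I_KNa = g_KNa * 0.37 / (1 + (38.7 / Na)^3.5) * (Vp - E_K)` with
sodium influx proportional to the pyramidal rate and extrusion through a
Hill-type pump `R_pump (Na^3 / (Na^3 + 15^3) - Na_eq^3 / (Na_eq^3 + 15^3))`,
constructed so `Na_eq` is the zero-firing equilibrium. The slow build-up of
[Na] during firing terminates Up states and paces the NREM slow
oscillation.

Two-column mode adds symmetric excitatory projections from each pyramidal
mass to both masses of the other column (`N_pp' = 8`, `N_ip' = 2`), with the
inter-column AMPAergic conductance expressed as `beta * g_AMPA`. `beta`, the
inter/intra conductance ratio, is the propagation-control parameter.

## Brain states and calibration

NREM and wake differ only in conductances and noise amplitude: wake upscales
`g_AMPA` (1 -> 2 in the baseline presets) and uses weaker drive noise
(std 1 vs 1.8 ms^-1). The wake GABAergic conductances are not free: they are
calibrated so the wake operating point sits at the NREM Up-state membrane
potentials. The package estimates those targets as the peak bins (0.5 mV) of
the Vp and Vi distributions restricted to Up-labeled samples of a simulated
NREM ensemble, then solves the noise-mean steady state of the full
right-hand side for `(g_GABA_p, g_GABA_i)`. Holding the targets fixed the
two balance equations are *linear* in the two unknowns, so the solve is
closed-form (residual at machine precision) and the calibrated conductances
are exactly linear in `beta` — matching the constant spacing of the
published conductance grids. A round-trip invariant (targets taken from the
model's own noise-free fixed point recover the preset conductances to 1e-9)
guards the algebra.

Sensitivity: a 0.5 mV (one-bin) shift of the Vi target moves `g_GABA_i` by
roughly 4-5%, and the Up-state peak estimate itself varies by about one bin
across seeds at the 100-trial scale. The pyramidal conductances are
reproduced within ~4%; the inhibitory ones within ~8-10%.

## Integration

Stochastic Heun (predictor-corrector) with dt = 0.1 ms; the additive noise
increment `gamma_p^2 * std * sqrt(dt) * N(0,1)` uses the same draw in
predictor and corrector (continuous-time white-noise convention; the
stationary variance of the noise-driven synapse equation,
`std^2 * gamma / 4`, is verified against theory at two step sizes). Each
trial integrates 10 s of burn-in plus 10 s of recorded signal. Initial
conditions are uniform draws (V in [-80, -50] mV, synaptic activities in
[0, 1] with zero derivatives, [Na] within 0.5 mM of rest); the burn-in
leaves no measurable dependence on them.

Trials are vectorized with per-trial random substreams (one per column for
initial conditions and one for noise), so any trial is bit-reproducible in
isolation, ensembles are order-independent, and a decoupled two-column run
(`beta = 0`, zero inter counts) reproduces a matched one-column run bit for
bit. The default engine is a numba kernel; a pure-numpy reference engine
implements the identical update order and the two are consistency-tested.

## Signals and analysis

Per column the recorded signals are Vp, Vi, [Na] and the LFP of each
population, `LFP_k = |I_AMPA_k| + |I_GABA_k|`; firing rates are derived on
demand from V. Analyses use the pyramidal population unless stated.

* Distributions use fixed bins (0.5 mV / 0.5 Hz) normalized by the total
  event count. The pooled per-trial-demeaned LFP histogram is smoothed with
  a Gaussian kernel (width c = 55 mV for the pyramidal LFP, 5 mV for the
  inhibitory; the LFP spans hundreds of mV so the broad kernel still leaves
  the NREM modes separated). Two interior maxima separated by a local
  minimum declare bimodality; the Up/Down threshold is the midpoint of the
  two modes, and a unimodal distribution returns an explicit no-bimodality
  result (the wake signature).
* Spectra: Welch PSD with 2 s Hann windows at 90% overlap, averaged over
  windows then trials, reported as `dB = log10(P / 1 (mV)^2/Hz)`. Absolute
  dB values depend on periodogram normalization conventions (taper power
  correction, handling of trailing partial windows), so spectral assertions
  are orderings (NREM > wake below 4 Hz, reversed above 30 Hz), never
  absolute dB values. Band ratio: per-trial `log10` of summed power
  above 30 Hz over summed power below 4 Hz.

## Cluster-permutation statistics

Pointwise independent t-values between two equal-size trial groups use the
pooled-variance convention with denominator `2n - 1` and statistic
`(m1 - m2) / sqrt(s^2 / n)` (a `pooled` variant with the textbook
`2n - 2` / `sqrt(2 s^2 / n)` forms is available for sensitivity analysis).
The suprathreshold criterion is `|t| >= 2.58`, the two-tailed p = 0.01
critical value for the 500-trial design; it is interpreted on the t scale
(the raw mean difference is not t-distributed). Clusters are maximal
suprathreshold runs scored by area (integral of |t| over time, seconds);
clusters not exceeding the largest cluster of the prestimulus baseline
(obtained by splitting the prestimulus window in half) are discarded.
Null distributions come from full relabeling of trials between the two
groups (the standard exchangeability choice), rank-matched by descending
area, using absolute areas (the two-tailed threshold is already applied);
permutations continue until the deepest observed rank has the requested
null count, capped at `max_perm` with the achieved count reported.
Degenerate points with zero pooled variance are flagged and excluded from
thresholding.

One caveat is inherent to rank-matched nulls: each observed rank is tested
at the nominal level, so the union event "any ranked cluster significant"
is anticonservative (about 3% at a nominal 1% in white-noise null
simulations of 20 trials x 300 points). The leading (largest) cluster —
the statistic the propagation metric reports — holds the nominal rate, and
the type-I validation targets it.

Propagation is quantified by the earliest surviving poststimulus cluster of
the unperturbed column's pyramidal firing rate: its area (s), length (ms)
and permutation p-value; an explicit non-significant record is returned
when nothing survives. A Bonferroni-corrected pointwise t-test is provided
as the parametric alternative.

## Problem sizes and profiles

The desk profile uses 100-trial ensembles and 500 permutations; experiment
runners accept `full_scale=True` for 500 trials / 1000 permutations. The
acceptance script runs the stimulated ensembles at the publication trial
count (500) because the p-value bounds it reports are resolution-limited,
while the Up-state target estimation uses 100 trials. The type-I
calibration of the cluster pipeline uses 500 null datasets of 20 trials x
300 time points with 400-permutation p-values.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself under the published parameter
tables; there is no fitting to recordings. Passing tests therefore
demonstrate internal reproduction of the simulated phenomenology — regime
dichotomy, evoked-response structure, beta-dependent propagation — not
agreement with any experimental dataset. Known limitations:

* The sodium pump uses the Hill form of the model lineage; the original
  appendix form was not available, and any deviation would shift the
  Up-state sodium equilibrium slightly.
* Up-state targets estimated from 100 desk-scale trials carry ~one-bin
  uncertainty, visible as the few-percent gap to the published inhibitory
  conductances.
* At the publication trial count the beta = 1 unperturbed response sits
  near the significance boundary (first-cluster p occasionally below 0.01
  depending on seed); the qualitative contrast with beta >= 2 (p ~ 0,
  areas and lengths growing with beta) is robust.
* REM sleep, thalamic gating and neuromodulator mechanisms are outside the
  model's scope.
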