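# Methods

This note documents the models, the numerical choices, and — importantly —
which defaults are physical constants, which are study conditions, and
which were calibrated once and frozen.

## Structural model: lesion and rebound operators

The connectome is a nonnegative weighted directed matrix `w[i, j]`
(coupling from region j onto region i), zero diagonal, with one designated
stroke region.

* **Lesion.** `apply_stroke` multiplies every afferent and efferent link of
  the stroke region by the retain fraction `s ∈ [0, 1]`; damage is
  homogeneous across the infarct's links. Both link directions are damaged
  by default because the downstream functional readout (calcium PLV) is
  undirected; `direction='afferent'/'efferent'` restricts the damage for
  sensitivity analyses. The operator composes multiplicatively
  (s₁ then s₂ ≡ s₁·s₂) and never touches links between two intact regions.
* **Rebound.** `apply_rebound` adds back a budget `B = r × (total lost
  weight)`, `r ∈ [0, 5]`. The budget is split across the regions that had a
  nonzero link to the stroke region in the *healthy* connectome,
  proportionally to that prior link strength; each region's share is then
  spread over its remaining non-stroke links proportionally to their
  current weights. No new links are created, and total added weight equals
  B exactly (checked to 1e-9 relative in the tests). A donor region with no
  other links cannot absorb its share; shares are renormalized over the
  donors that can (if none can, the operator raises). The alternative
  reading of rebound — restoring the damaged stroke links themselves — is
  available as `mode='restore'`.

### Synthetic connectome

`generate_synthetic_connectome` draws random off-diagonal links
(default density 0.3) with log-normal weights of shape σ=2 — spanning
orders of magnitude, as tract-tracing connectomes do — and makes region 0 a
hub: its links are always present and boosted ×10. Nonzero weights are
rescaled to mean 4.0.

These three numbers are *design parameters of the synthetic study*, chosen
so that the inference problem the package exists for is well posed, and
then frozen:

* the hub boost guarantees that lesioning the stroke region has a
  network-wide functional effect (an isolated stroke node would produce FC
  changes indistinguishable from noise on the analysis subset);
* the heavy tail (σ=2) makes different region pairs saturate at different
  damage levels, so the *shape* (not just the amplitude) of the FC-change
  pattern depends on `s` — necessary because the fit metric, Pearson
  correlation, is scale-invariant;
* the mean weight places the default oscillator working point (K=4.3, D=1)
  in the partially synchronized regime, median pairwise PLV ≈ 0.4 (the
  mid-range seen in empirical calcium FC), where FC is most informative
  about structure. With weaker weights the model sits near the incoherent
  state and seed-to-seed PLV variability swamps the lesion signal.

## Phase network model

Each region is a Kuramoto oscillator with identical natural frequency
f = 2 Hz, global coupling K = 4.3, and white phase noise of strength D = 1
(⟨η_i(t) η_j(t′)⟩ = 2D δ(t−t′) δ_ij) — the working point used throughout
the lesion-fit analyses. Couplings are instantaneous: transmission delays
are ignored, which is defensible at delta-band frequencies where delays are
a small fraction of a cycle. The 1/N prefactor on the coupling sum is kept
explicit, not absorbed into K.

**Integration.** Euler–Maruyama at dt = 1 ms (f·dt = 0.002), noise
increment √(2D dt)·N(0,1), initial phases uniform; a 10 s transient is
discarded. The integrator state is the unit phasor (cos θ, sin θ) per
oscillator, advanced each step by a polynomial rotation (Taylor degree 6/7
with renormalization). For the step angles that occur (≲0.3 rad) the
rotation error is below 1e−13 rad/step, orders of magnitude beneath the
O(dt²) discretization error; the test suite pins the kernel against an
independent plain sin/cos Euler reference on the same noise stream. Kernels
are numba-compiled.

**Batched, paired seeds.** The grid fit and the ground-truth generator
simulate a whole seed list in one pass; initial phases and noise are drawn
from a single stream keyed on the seed list. Healthy and lesioned runs
therefore see *identical* noise realizations (paired seeds), which cancels
most of the realization variance from the FC difference and makes the
shared-seed closure (fit correlation exactly 1 at the true parameters)
exact.

## Functional connectivity and the lesion-parameter fit

* **Band-pass**: zero-phase (forward–backward) 4th-order Butterworth;
  empirical calcium analyses use the upper delta band 2.5–5 Hz at 25 Hz
  sampling.
* **Phases**: Hilbert-transform analytic phase, per channel.
* **PLV**: modulus of the time-averaged phase-difference phasor. For model
  phases the PLV is accumulated on the fly every 5 ms (acc_every=5);
  subsampling a 2 Hz phase process at 200 Hz loses nothing while saving a
  third of the runtime. The generator and the fit share this stride.
* **Surrogates**: Fourier phase-randomization per channel (spectrum
  preserved, cross-channel phases destroyed), default 100 surrogates,
  0.95 quantile per pair. Note a fundamental limit exercised in the tests:
  two pure tones of equal frequency have PLV 1 by construction, so the
  surrogate floor for nearly-monochromatic signals is ≈1; significance
  testing needs broadband (stochastic) phases.
* **FC change**: condition minus reference (`difference`, default, bounded
  and robust to small reference PLVs) or `(cond − ref)/ref` (`relative`).
* **Grid fit**: for each (s, r), lesion+rebound the healthy connectome,
  simulate with the shared seed list, average the per-seed FC change, and
  correlate (Pearson) the strictly-upper-triangle change vectors of model
  vs. data on the analysis region subset. Argmax ties break toward smaller
  damage (larger s), then smaller r. A lesion with no structural effect
  (s=1) predicts a constant change; its correlation is undefined and the
  cell is scored 0 (no evidence). Constant *data* raises instead. K is held
  fixed; an outer loop over K is the caller's one-liner if needed.

**Ground-truth experiments** exclude the stroke node and its strongest
neighbors (the peri-infarct core) and analyze the remaining 12 regions,
mirroring the empirical practice of dropping regions whose signals are
corrupted by tissue displacement. Observation noise is additive truncated
Gaussian on the PLV entries of each condition (σ=0.02 by default in the
recovery study), applied symmetrically. With the frozen defaults the
recovery study — truth (s*=0.3, r*=1.0), grid 0:1:0.1 × 0:5:0.5, 10 paired
seeds per estimate, 120 s per run at N=18 — recovered the truth within one
grid cell in 10/10 replicates (8 exact) when it was run to validate the
design; the test suite re-runs this end to end.

## Adex spiking network

Neuron model (per population): Cm = 150 pF, Gl = 10 nS, El = −60 mV (RS) /
−65 mV (FS), Δ_V = 2.0 / 0.5 mV, V_thre = −50 mV, V_reset = −65 mV,
T_refrac = 5 ms, τ_w = 500 ms, a = 4 nS and spike increment b on RS cells
only (FS: a = b = 0). b is the anesthesia knob: 60 pA deep, 20 pA light.
Synapses are conductance-based (I = g(E − V), E_exc = 0 mV,
E_inh = −80 mV), exponential decay τ_syn = 5 ms, incremented by a quantum
Q on each presynaptic spike.

Two formulation choices follow the standard model, with alternative
variants kept behind flags:

* the adaptation ODE is dw/dt = (a(V−El) − w)/τ_w with τ_w = 500 ms
  (`literal_adaptation=True` switches to a decay rate Gl/Cm ≈ (15 ms)⁻¹
  with an un-normalized a(V−El) term — a much stiffer, sparser-firing
  variant);
* spikes are detected at V ≥ V_thre (upward crossing, recorded before
  reset).

**Integration**: forward Euler at dt = 0.1 ms with the exponential
argument capped (overflow guard) and skipped when ≤ −30 (contribution
< 1e−12 of leak scale); dt above Δ_V/2 is rejected. Membrane noise is
Gaussian white current noise of amplitude σ (pA·√ms), i.e. a per-step
voltage kick σ√dt·ξ/Cm. The refractory clamp bounds every neuron's rate by
1/T_refrac, which also bounds the spike buffer a priori. The state is
advanced in 10 000-step chunks so the noise array never exceeds a few
hundred MB.

**Architecture and calibration.** Sizes and wiring (1600 RS, 400 FS,
p = 0.02, random directed, no autapses) are literature-style defaults — not
values from any experiment. Three knobs were calibrated once against the
target rhythm and frozen: σ = 230 pA·√ms, Q_exc = 1.5 nS, Q_inh = 10 nS.
The calibration target was the deep-anesthesia slow oscillation at
≈2.1 Hz in the *population fluorescence* (below), with the light-anesthesia
network faster. Two findings from the calibration are worth recording:
with weak inhibition (Q_inh = 5 nS) the b = 20 pA network runs in
sustained asynchronous firing instead of Up–Down cycling and the frequency
ordering inverts — strong inhibition is what lets weak adaptation still
terminate Up states; and the spectral peak of the *spike rate* is an
unreliable calibration readout because the burst-like waveform puts most
power into harmonics, whereas the slow calcium indicator (τ_Ca = 760 ms)
low-passes the signal to its fundamental. With the frozen defaults, the
median fluorescence spectral peak over seeds 0–9 is 2.03 Hz (b = 60) and
2.48 Hz (b = 20), faster in the light-anesthesia regime in 10/10 seeds.

With adaptation removed (a = b = 0) the same network fires tonically
(~70 Hz) with no sub-4 Hz spectral peak — the slow rhythm is
adaptation-generated, not an artifact of the architecture.

## Calcium / fluorescence forward model

Units: mV, ms, μA/cm², nM. Constants: E_Ca = 120 mV, g_Ca = 5 mS/cm²,
V_half = −25 mV, ρ = 5 mV, k_Ca = 0.002 (nM/ms)/(μA/cm²), τ_Ca = 760 ms,
basal [Ca] = 0; fluorescence dF = 0, K_F = 10, k_d = 375 nM, n_H = 2.3
(GCaMP6f).

1. **Spike reconstruction**: integrate-and-fire traces clip the action
   potential at threshold, so each spike overwrites 1 ms of the trace with
   a +30 mV rectangular pulse. The exact waveform is immaterial downstream:
   the Boltzmann activation is already > 0.99 at +30 mV, so the calcium
   influx per spike is set by the pulse width, not its shape. Overlapping
   reconstructed spikes violate the upstream refractory contract and raise.
2. **Calcium current**: I_Ca = g_Ca · s(V) · (V − E_Ca) with
   s(V) = 1/(1 + exp(−(V − V_half)/ρ)); inward (negative) below reversal.
3. **Calcium**: d[Ca]/dt = −k_Ca I_Ca − ([Ca] − basal)/τ_Ca, forward Euler
   at the recording step (1 ms by default; dt/τ_Ca ≈ 1.3e−3, and the
   scheme's fixed point equals the analytic steady state k_Ca τ_Ca |I|
   exactly). Negative concentrations (possible only under sustained
   outward current) are clamped at zero with a warning.
4. **Fluorescence**: Hill saturation F = dF + K_F·Ca^n_H/(Ca^n_H + k_d^n_H),
   exactly half-saturated at Ca = k_d. A dimensionally inconsistent
   variant with an unexponentiated k_d in the denominator exists behind
   `literal_hill=True` for comparison only.

Subthreshold fluctuations contribute to I_Ca between spikes (the Boltzmann
is evaluated on the full trace), which is negligible at rest
(s(−65) ≈ 3e−4) but not during depolarized Up states — this is intended:
the empirical indicator integrates all calcium influx.

For population signals, every excitatory neuron's trace is pushed through
the chain (in cell chunks to bound memory) and averaged per time point;
the slow-oscillation frequency is the Welch spectral peak in 0.5–10 Hz
(10 s segments, quadratic interpolation around the peak bin), with a NaN
sentinel when no in-band peak exceeds 4× the in-band median power.

## Synthetic data: what it does and does not emulate

The calcium-like signal generator produces sin(θ) of simulated phases,
resampled to 25 Hz (Nyquist 12.5 Hz, the wide-field recording regime),
plus white noise at a chosen SNR and an optional slow (<0.5 Hz) common
confound to exercise the band-pass stage. It reproduces the *statistical*
structure the pipeline consumes — band-limited phase-coherent signals with
realistic sampling — but not the spatial block structure of real cortical
FC (somatosensory/visual modules), hemodynamic or motion artifacts, or
indicator nonlinearity at the wide-field level. Recovery results on
synthetic data therefore validate the inference machinery, not the
biological conclusions one would draw from real recordings.

Poisson spike trains are homogeneous with exact per-train counts drawn
from the Poisson law; ground-truth experiment manifests record every
parameter and seed, and regeneration from a manifest is bit-identical.

## Problem sizes

Defaults are sized for a workstation CPU: 120 s of simulated network time
per FC estimate (PLV standard error ≲0.01), 10 seeds per estimate, 121-cell
lesion grid (~1 min per full fit), 30 s and 10 seeds per adex
slow-oscillation estimate (~30 s per run including the forward model).

## Known limitations

* Lesion fitting holds K fixed; co-fitting global coupling (a third grid
  axis) is supported by the API shape but not run by default.
* The rebound operator redistributes weight only to first neighbors of the
  infarct; longer-range sprouting strategies are out of scope.
* The adex network is a single local population pair — no long-range
  connectome embedding or mean-field reduction.
* The fluorescence model uses the stated GCaMP6f constants; indicator
  kinetics (binding delay) beyond the single-pool calcium decay are not
  modeled, so sub-100 ms fluorescence timing should not be interpreted.
* The mean-ensemble-frequency identity (average phase velocity = f at
  D = 0) holds only for symmetric connectomes, where the antisymmetric
  sine couplings cancel pairwise; on directed connectomes the ensemble
  frequency shifts slightly.
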