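# strokesim

Computational models of how an ischemic stroke reshapes mouse cortical
activity, and of how candidate structural rewiring strategies would show up
in calcium-imaging functional connectivity.

The package is aimed at computational neuroscientists who want to (a) test
hypotheses about post-stroke white-matter rewiring against wide-field
calcium functional connectivity, and (b) model the slow oscillations that
peri-infarct (and anesthetized) cortex generates, down to the two-photon
fluorescence signal an experimenter would record.

## What is inside

**Structural layer** (`strokesim.connectome`). A weighted directed
connectome `w_ij` with two operators: a stroke lesion that scales every
link of the infarcted region by a retain fraction `s` (`s=0` complete
damage), and rebound rewiring that redistributes a budget of `r` times the
lost weight across the remaining links of the regions formerly connected
to the infarct (`r` up to 5, allowing over-compensation). A synthetic
generator stands in for atlas connectomes.

**Network layer** (`strokesim.kuramoto`, `strokesim.fc`). Each region is a
stochastic Kuramoto phase oscillator on the connectome,

    dθ_i = [2πf + (1/N) Σ_j K w_ij sin(θ_j − θ_i)] dt + √(2D dt) ξ_i ,

with identical natural frequency f, global coupling K, and noise strength
D. Functional connectivity is the phase locking value

    PLV_ij = |(1/M) Σ_m exp(i(θ_i(m) − θ_j(m)))| ,

computed either from model phases or from band-passed signals via the
Hilbert transform, with phase-randomized surrogates providing the
significance floor. `fit_parameter_grid` scans the `(s, r)` lesion plane,
simulates healthy and lesioned models with paired noise realizations, and
scores each cell by the Pearson correlation between the model's and the
data's FC-change upper triangles — identifying which structural alteration
best explains an observed functional reorganization.

**Microcircuit layer** (`strokesim.adex`, `strokesim.calcium`). A network
of 1600 regular-spiking (adapting) and 400 fast-spiking adex
(adaptive exponential integrate-and-fire) neurons generates
anesthesia-like Up–Down slow oscillations; the spike-triggered adaptation
increment `b` controls the rhythm (`b=60 pA` models deep anesthesia,
`b=20 pA` light anesthesia). A forward model converts each neuron's
membrane trace into what a two-photon microscope would see: reconstructed
spike waveforms → L-type calcium current with Boltzmann activation →
intracellular calcium (decay τ_Ca = 760 ms) → saturating Hill fluorescence
of GCaMP6f (k_d = 375 nM, n_H = 2.3).

**Fixtures** (`strokesim.synthetic_data`). Ground-truth lesion experiments
for parameter recovery, calcium-like 25 Hz region signals, and Poisson
spike trains — every pipeline stage is testable with no external download.

## Worked example

```python
import numpy as np
from strokesim import (KuramotoParams, fit_parameter_grid,
                       generate_synthetic_connectome)
from strokesim.synthetic_data import generate_ground_truth_experiment

kp = KuramotoParams()           # f=2 Hz, K=4.3, D=1, 120 s per run
exp = generate_ground_truth_experiment(
    n_regions=18, s_true=0.3, r_true=1.0, kp=kp,
    seeds=list(range(1000, 1010)), obs_noise=0.02)

res = fit_parameter_grid(
    exp.data_change_stroke, exp.healthy_conn, kp,
    s_grid=np.arange(0, 1.01, 0.1), r_grid=np.arange(0, 5.01, 0.5),
    seeds=10)
print(f"best fit: s={res.best_s:g}, r={res.best_r:g}, "
      f"corr={res.best_value:.3f}")
```

This simulates a "stroke experiment" whose true structural parameters are
30% retained connectivity and full (1×) rebound of the lost weight,
observes its FC change on 12 regions outside the stroke core under
observation noise, and then recovers the parameters by scanning the grid.
It prints

```
best fit: s=0.3, r=1, corr=0.973
```

i.e. the grid fit finds the true damage level and rebound strength, with a
0.97 correlation between the model's and the observed FC-change patterns
(correlation below 1 because the fit uses simulation seeds independent of
the "experiment").

On the microcircuit side:

```python
from strokesim import (AdexParams, NetworkArchitecture, fluorescence_from_run,
                       oscillation_frequency, simulate_network)
from strokesim.containers import SignalTimeSeries

run = simulate_network(NetworkArchitecture(), AdexParams.rs(b=60.0),
                       AdexParams.fs(), duration=30.0, seed=0,
                       record_vm="exc")
ft = fluorescence_from_run(run)
sig = SignalTimeSeries(ft.f.mean(axis=0)[None, :], fs=1000.0 / ft.dt)
print(f"{oscillation_frequency(sig, band=(0.5, 10.0)):.2f} Hz")
```

prints `2.07 Hz` — the deep-anesthesia slow-oscillation frequency read off
the excitatory population's mean fluorescence; re-running with `b=20.0`
gives `2.49 Hz`, a faster rhythm under weaker adaptation.

A `strokesim` command-line interface wraps the same functionality
(`strokesim lesion`, `simulate-bnm`, `fc`, `fit-grid`, `simulate-adex`,
`forward-calcium`, `make-fixtures`); run `strokesim --help`.

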