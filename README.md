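# groovenet

Why does some music make us want to move? One influential account treats
the "groove" experience as neural resonance: banks of nonlinear oscillators
in auditory and motor cortex entrain to a rhythm's beat, and the wanting-to-
move sensation tracks the mismatch between the rhythm actually heard and the
pulse the motor system expects. `groovenet` is a tested, reusable
implementation of that modelling-and-analysis stack for computational
neuroscientists: the oscillator network itself, the rhythm and stimulus
machinery around it, and the MEG-style analyses used to look for its
signatures in brain data — exercised end-to-end on synthetic recordings with
known ground truth.

## What is inside

* **`rhythms`** — beat-gridded rhythm patterns, Longuet-Higgins–Lee metric
  weights and syncopation index Σ(w_rest − w_note) over weak-note/strong-rest
  pairs, parametric syncopation families (anticipation-based), and onset
  pulse trains → analytic (Hilbert) drive signals.
* **`oscillators`** — a three-layer network of canonical Hopf oscillators
  dz/dt = z(α + iω + β₁|z|² + β₂|z|⁴/(1−|z|²)) + x, 321 log-spaced natural
  frequencies (0.375–12 Hz) per layer; an auditory layer near a Hopf
  bifurcation (α = 10⁻⁴), motor-planning and groove layers in the bistable
  double-limit-cycle regime (α = −0.8, β₁ = 4, β₂ = −3), Hebbian layer-1→2
  connections at harmonic ratios, fixed +0.8 / −0.7 convergence on layer 3.
  Numba-compiled RK4, with a run protocol that reads out each layer's 2-Hz
  mean-field amplitude per melody.
* **`acoustics`** — 32-band gammatone (ERB-spaced) cochlear envelope and the
  1–9 Hz modulation spectrum of the envelope.
* **`behavior`** — instantaneous tap frequency F(t) = 1/(m_t − m_{t−1}),
  linear and quadratic (inverted-U) fits with adjusted r².
* **`spectral`** — Morlet time–frequency decomposition (Fc = 1, 3-s FWHM),
  1/f rectification by z-scoring power across locations per frequency,
  dominant-frequency maps, 5th-order spatial-gradient polynomial fits.
* **`decoding`** — cross-validated ridge decoding w = (ZᵀZ + 2I)⁻¹ZᵀX with
  10 interleaved folds, Fisher-z coding precision, searchlight (50
  neighbours) and 20-vertex ROI variants, paired contrasts, Storey FDR.
* **`pac`** — phase–amplitude coupling ρ = |Σ a e^{iφ}|/√(N Σ a²),
  comodulograms, cluster-vs-whole-brain comparison.
* **`synth`** — synthetic study generator (29 subjects × 144 trials,
  1673-source grid, 248 sensors) planting 1/f background, a spectral
  gradient, condition-locked narrowband effects and delta→beta PAC, with
  machine-readable ground truth.
* **`pipeline` / CLI** — `groovenet run-all --seed 0` and per-stage
  subcommands (`synth-rhythms`, `simulate-model`, `synth-data`, `gradient`,
  `decode`, `pac`, `behavior`).

## Worked example

Generate a syncopation family, run the oscillator model, and relate the
beat-rate response to syncopation:

```python
import numpy as np
from groovenet import rhythms, oscillators as osc

grid = rhythms.BeatGrid()                 # 2-Hz beat, 8 s, 32 grid positions
onsets = np.zeros(grid.n_positions, bool)
onsets[::grid.subdivisions_per_beat] = True
base = rhythms.RhythmPattern(grid, onsets)
weights = rhythms.build_metric_weights(grid)

family = rhythms.generate_syncopation_family(base, [0, 6, 12], seed=42)
for p in family:
    print(rhythms.syncopation_index(p, weights).total,
          np.flatnonzero(p.onsets).tolist())
```

prints the achieved index and the onset grid positions of each variant —
the level-0 rhythm keeps every note on a beat (even positions), higher
levels anticipate beats onto off-beat positions:

```
0  [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30]
6  [2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 23, 26, 28, 30, 31]
12 [2, 4, 6, 7, 10, 12, 14, 15, 18, 20, 22, 23, 26, 28, 30, 31]
```

```python
model = osc.build_default_model()
table = osc.run_protocol(model, family, n_runs=5, base_seed=0)
print(table.groupby(["melody", "layer"])["amplitude_2hz"].mean().unstack())
```

yields the mean 2-Hz mean-field amplitude per layer (~3 s per run; layer-1
amplitude declines with the degree of syncopation, mirroring the loss of
beat-rate energy in the stimulus, while the bistable layers report whether
the pulse percept was triggered).

On the analysis side, `synth.generate_source_power` +
`spectral.fit_spatial_gradient` recover a planted 4→30 Hz dominant-frequency
gradient with adjusted r² ≈ 0.9 on the planted axis and ≈ 0 elsewhere, and
`decoding.decode_spectrum` finds a planted syncopation-linked 2-Hz effect as
a precision peak at the 2-Hz analysis bin.

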