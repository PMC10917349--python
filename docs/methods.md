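# Methods

## The model

The core of the package is a three-layer gradient-frequency network of
canonical Hopf oscillators. Each oscillator is the normal form of an
excitatory–inhibitory neural population near an Andronov–Hopf bifurcation,
written in the complex plane:

    dz/dt = z (a + b |z|² + d |z|⁴ / (1 − |z|²)) + x,
    a = α + iω,  b = β₁ + iδ₁,  d = β₂ + iδ₂,

where x collects the stimulus and coupling inputs. Every layer holds 321
oscillators with natural frequencies log-spaced from 0.375 to 12 Hz.

* **Layer 1 (auditory)**, α = 10⁻⁴, β₁ = 0, β₂ = −3: just past a
  supercritical Hopf bifurcation. Isolated, it settles at the radius solving
  α = 3r⁴/(1 − r²), r ≈ 0.0759; driven, it behaves as a compressive
  nonlinear resonator that entrains to the rhythm's onset pulses.
* **Layers 2 (motor planning) and 3 (groove)**, α = −0.8, β₁ = 4, β₂ = −3:
  the double-limit-cycle (bistable) regime, with a stable rest state, a
  stable limit cycle at r = √0.4 ≈ 0.6325, and an unstable orbit at
  r = √(2/7) between them. A resonant input exceeding ≈ 0.142 (the maximum
  of 0.8r − 4r³ + 3r⁵/(1 − r²) over the low branch) knocks an oscillator
  onto the high limit cycle, where it stays — a rhythmic-memory element.

Coupling uses mode-locking monomials c·z_source^k·conj(z_target)^(m−1),
resonant when k f_source ≈ m f_target. Layer 1→2 connections exist at the
harmonic ratios {¼, ⅓, ½, 1, 2, 3, 4} (one source per ratio, the nearest
grid oscillator) and are plastic:

    τ dc/dt = c (λ + μ₁|c|² + μ₂|c|⁴/(1 − |c|²)) + κ z_target^m conj(z_source)^k,

with λ = −1, μ₁ = 4, μ₂ = −2.2, κ = 0.2. Note this radial law is itself
bistable (stable |c| ∈ {0, 0.663}, saddle 0.606): connections seeded below
the saddle decay, connections above it self-sustain. Layer 3 receives fixed
1:1 excitation from layer 2 (w = +0.8) and 1:1 inhibition from layer 1
(w = −0.7), so its input is the difference between the pulse/meter layer and
the auditory layer — a prediction-error readout.

### Integration and run protocol

Fixed-step RK4 (default dt = 1/480 s; halving dt changes 2-Hz amplitudes by
< 0.5 %, checked in the suite), with each oscillator's right-hand side scaled
by its natural frequency (gradient-frequency convention; a flag disables
it). The RK4 midpoints read the stimulus at half steps, so drive signals are
sampled at 2/dt. The rhythm drive is a train of pulses at the onset times,
Hilbert-transformed into an analytic signal. A run integrates 16 s, drops
the first 2 s (evoked transient), computes each layer's mean field (plain
average over oscillators) and reads out the Fourier amplitude at the FFT bin
nearest 2 Hz. The run protocol repeats this 29 times per melody with random
initial conditions (oscillator states only; dynamics are deterministic).

### Calibrated working point

Several constants the model needs are not fixed by theory; they are config
fields, chosen once on mechanistic grounds and then left alone:

* **Onset pulses**: raised-cosine, width 0.12 s, amplitude 5. Weaker drives
  leave layer 1 far below the amplitude needed for its coupled input ever to
  cross the layer-2 trigger barrier, so the jump to the limit cycle — the
  regime the bistable layers exist for — would never occur.
* **Initial connections**: |c| = 0.5 (sub-saddle), zero phase, τ = 8 s, with
  connection plasticity running at the stimulus timescale (not scaled by
  oscillator frequency). Connections therefore hold long enough to trigger
  layer 2 early in the trial and then fade, leaving the triggered limit
  cycle weakly locked to the beat. Zero initial phase makes the
  excitatory/inhibitory convergence on layer 3 coherent; random connection
  phases would make the layer-3 cancellation an accident of the seed,
  because the Hebbian term exerts no restoring force on a uniform phase
  offset.
* **Beat track**: the run protocol merges an always-on beat-rate pulse train
  with the melody onsets, mirroring stimuli that combine an invariant drum
  with a syncopated bass line.
* **Mode-locking exponents**: the printed small-integer ratios (k:m) are the
  default, so every coupling term is resonant; plain 1:1 coupling at all
  ratio pairs is available by config but injects off-frequency components
  into the target layer.

With this working point the model robustly reproduces: the monotone decline
of layer-1 2-Hz amplitude with syncopation (Spearman ρ ≈ −0.95 over an
8-level family), rest-state stability of the bistable layers without input,
and beat-triggered jumps to the high limit cycle. It does **not** reproduce
an interior maximum of layer-3 2-Hz amplitude over syncopation: across the
explored configuration space the layer-3 mean-field amplitude tracks layer 1
(convex, declining). The reason is structural: a triggered layer-2
oscillator is pinned at r ≥ 0.632 while the compressive layer 1 saturates
near 0.5–0.65, so the mismatch 0.8·z₂ − 0.7·z₁ stays above the layer-3
trigger barrier whenever layer 1 is entrained, and layer 3 activates
wherever layer 1 does. The corresponding acceptance test states the interior-
maximum property as such and currently fails; the test is kept rather than
weakened. A definitive reproduction would require the original stimulus set.

## Syncopation

Metric weights follow the recursive-subdivision convention: the downbeat has
weight 0 and every subdivision level subtracts 1 (duple splits before triple
by default; both the split order and tree depth are config options). A
syncopation event is a note at weight w₁ whose following rests (scanned
cyclically up to the next onset) include a position with weight w₂ > w₁;
its value is w₂ − w₁, taking the strongest qualifying rest, and the index is
the sum over events. Cyclic scanning makes the index invariant under
rotating a periodic pattern by whole measures. A rhythm in which every beat
position carries an onset scores exactly 0.

The family generator produces variants of a base rhythm at requested index
levels, syncopating by *anticipation* — shifting an on-beat onset one
subdivision earlier, which creates a weak-accent note before a strong-accent
rest — with a seeded random swap as fallback. Anticipating a downbeat can
move one note across the bar line, so per-measure note counts match the base
within one note (total count exactly).

## Acoustic stage

The temporal envelope is the sum over a 32-channel gammatone filterbank
(centre frequencies ERB-spaced from 80 Hz to min(8 kHz, 0.9 × Nyquist); the
IIR design from scipy) of per-channel Hilbert magnitudes. The modulation
spectrum is the Fourier amplitude of the mean-removed envelope on a 1–9 Hz
grid, after low-pass decimation to 100 Hz; the amplitude at the bin nearest
2 Hz is reported in dB re 1 a.u. The filterbank family and band edges of
the front-end are not constrained by the analyses that consume the envelope,
so results involving it are qualitative (e.g., 2-Hz modulation amplitude
decreasing with syncopation).

## Time–frequency analyses

Morlet wavelets with central-frequency parameter 1 and a 3-s FWHM temporal
Gaussian at 1 Hz, scaled by 1/f (sd = FWHM/(2√(2 ln 2)); unit-energy
normalization); analysis grid 100 log-spaced frequencies, 1–100 Hz (the
synthetic studies use 40 bins, 1–45 Hz). Samples within one FWHM of a
signal edge are flagged and excluded from time averages and PAC pooling.
For the large synthetic studies, epoch-averaged power is computed in the
frequency domain via Parseval (mean |wavelet coefficient|² over the epoch
equals Σ|X(ω)|²|Ψ_f(ω)|²·4/N²); the suite checks this against the full
transform. The aperiodic 1/f component is removed by z-scoring power across
locations at each frequency; any factor common to all locations (the 1/f
decay, the global beat response) cancels exactly. Dominant frequency is the
band-restricted argmax of the z-scored spectrum (ties to the lower
frequency), and the spatial gradient is a 5th-order polynomial of dominant
frequency against each coordinate separately (internally standardized for
conditioning, coefficients reported in mm), summarized by adjusted r².

## Decoding

Ridge regression of the regressor on z-scored features, w = (ZᵀZ + 2I)⁻¹ZᵀX
(the algebraically identical dual form is used when features outnumber
rows), with 10 interleaved folds (trial i → fold i mod 10; 144 trials give
the 130/14 train/test split). Standardization statistics come from the
training partition only — the suite includes an explicit leakage test.
Coding precision is atanh(Pearson r) between cross-validated predictions
and the regressor, capped at |r| = 0.999999 to stay finite on noiseless
synthetic data. Group inference: t-tests across subjects and Storey q-values
(π₀(λ) on a 0.05…0.95 grid, cubic-polynomial smoothing, read out at
λ = 0.95). Cross-validated precision has a small negative bias under the
null, so two-tailed group significance is combined with a positive group
mean when testing for coding. Searchlight features are the spectra of a
vertex and its 50 nearest neighbours; ROIs are a contrast peak plus its 19
nearest neighbours.

## Phase–amplitude coupling

ρ = |Σ a e^{iφ}| / √(N Σ a²), with phase from the wavelet angle at the grid
frequency nearest the requested phase frequency and amplitude from the
wavelet magnitude, pooled over trials (edge samples dropped). Closed-form
anchor: a = 1 + cos φ with uniform φ gives ρ → 0.5/√1.5 ≈ 0.408.

## Synthetic data

The generator plants, per subject: (i) 1/f background (exponent 1) with
per-vertex lognormal gain heterogeneity (sd 0.3 — without it, the tiny
cross-vertex variance at low frequencies lets z-scored noise beat the true
spectral peaks); (ii) a dominant-frequency gradient 4→30 Hz along y with
1-Hz jitter (narrowband bump height 3 over the floor); (iii) a global 2-Hz
beat response (random phase per trial, removed by 1/f rectification,
anchoring the 2-Hz wavelet phase for PAC specificity); (iv) regressor-locked
band-power effects — syncopation → 2 Hz in lateral "auditory" vertices
(−0.5 per regressor sd), ratings → 1.3–1.5 Hz and 20–30 Hz in "dorsal"
vertex sets (+0.5); (v) delta-phase → beta-amplitude coupling in a 20-vertex
sensorimotor cluster, built in the time domain as a 25-Hz carrier whose
amplitude follows (1 + cos φ₁.₄)/2 plus a weak 1.4-Hz oscillation. Trial
spectra are drawn directly in the Fourier domain (circularly symmetric
complex Gaussian coefficients with the prescribed PSD), which is
distribution-equivalent to filtering white noise and ~100× cheaper; PAC
vertices go through the time domain where the cross-frequency structure
lives. Sensor data mix the effect sources through per-subject
distance-decaying (40-mm Gaussian) random lead fields over a helmet-like
248-sensor shell and add a spatially correlated (rank-40) 1/f background
directly at the sensors; mixing all 1673 background sources explicitly would
be computationally prohibitive and statistically equivalent. Ratings follow
an inverted-U quadratic link in syncopation (peak 7.5, curvature −0.08,
ordinal noise 0.7 then rounding; rounding is skipped when noise is zero so
the noise-free link is exactly quadratic).

What the generator does **not** emulate: anatomical geometry (the volume is
an ellipsoid), realistic forward fields, artifacts, non-Gaussian background,
trial-to-trial adaptation, or any coupling between the behavioral and neural
noise. Recovery tests therefore show that the analysis stack finds exactly
the structure it assumes, at realistic sizes and SNR — not that the real
data contain that structure.

## Problem sizes

The default synthetic study is full scale (29 subjects × 144 trials × 248
channels / 1673 sources, 16-s trials at 96 Hz, 40 analysis frequencies).
The heavier end-to-end checks run once each: the channel-level decoding
study (~4 min), the 8-level × 5-run oscillator protocol (~2.5 min), the
full-grid gradient recovery plus 100 reduced (300-vertex, 6-trial)
gradient-vs-control replicates (~1 min), and a 5-subject PAC study with 3
trials per subject (~1 min). The pipeline driver defaults to smaller sizes
(4 subjects, 300 sources) for interactive use.
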