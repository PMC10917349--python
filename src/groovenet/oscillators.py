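"""Three-layer gradient-frequency network of canonical Hopf oscillators.

Each layer is a bank of canonical Hopf oscillators with log-spaced natural
frequencies.  An oscillator's intrinsic flow is

    dz/dt = z (a + b|z|^2 + d|z|^4 / (1 - |z|^2)) + x,

with a = alpha + i*omega, b = beta1 + i*delta1, d = beta2 + i*delta2 and x the
sum of the stimulus and coupling inputs.  Layer 1 ("auditory") sits just past
a supercritical Hopf bifurcation (alpha = 1e-4, beta1 = 0, beta2 = -3) and is
driven by the rhythm's onset pulses; layers 2 ("motor planning") and 3
("groove") sit in the bistable double-limit-cycle regime (alpha = -0.8,
beta1 = 4, beta2 = -3) with a stable rest state and a stable limit cycle at
r = sqrt(0.4).  Layer 1 -> 2 connections are plastic (Hebbian rule below) and
seeded at harmonic frequency ratios; layer 3 receives fixed 1:1 excitation
from layer 2 (w = 0.8) and fixed 1:1 inhibition from layer 1 (w = -0.7), so it
responds to the difference between the pulse/meter and auditory layers.

Coupling between oscillators uses mode-locking terms c_ij z_j^k conj(z_i)^(m-1)
and connections evolve as

    tau * dc/dt = c (lambda + mu1|c|^2 + mu2|c|^4 / (1 - |c|^2))
                  + kappa * z_target^m * conj(z_source)^k.

Integration is fixed-step RK4; the per-oscillator right-hand side is scaled by
its natural frequency by default (gradient-frequency-network convention), a
flag disables it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "LayerParams",
    "ModelConfig",
    "NetworkModel",
    "SimulationResult",
    "make_frequency_grid",
    "oscillator_derivative",
    "coupling_input",
    "hebbian_derivative",
    "harmonic_pairs",
    "radial_equilibria",
    "simulate",
    "mean_field",
    "amplitude_at_beat",
    "run_protocol",
    "build_default_model",
    "drive_sensitivity_sweep",
]

HARMONIC_RATIOS = (0.25, 1.0 / 3.0, 0.5, 1.0, 2.0, 3.0, 4.0)


def make_frequency_grid(f_min: float = 0.375, f_max: float = 12.0, n: int = 321) -> np.ndarray:
    """Log-spaced natural-frequency grid with exact endpoints."""
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least 2 grid frequencies")
    return np.geomspace(f_min, f_max, n)


@dataclass(frozen=True)
class LayerParams:
    """Intrinsic parameters of one oscillator layer."""

    alpha: float
    beta1: float
    beta2: float
    delta1: float = 0.0
    delta2: float = 0.0


@dataclass
class ModelConfig:
    """Full model configuration (defaults are the study regime)."""

    f_min: float = 0.375
    f_max: float = 12.0
    n_oscillators: int = 321
    layer1: LayerParams = field(default_factory=lambda: LayerParams(1e-4, 0.0, -3.0))
    layer2: LayerParams = field(default_factory=lambda: LayerParams(-0.8, 4.0, -3.0))
    layer3: LayerParams = field(default_factory=lambda: LayerParams(-0.8, 4.0, -3.0))
    w_23: float = 0.8       # fixed 1:1 excitation, layer 2 -> 3
    w_13: float = -0.7      # fixed 1:1 inhibition, layer 1 -> 3
    lambda_: float = -1.0   # Hebbian rule constants, layer 1 -> 2
    mu1: float = 4.0
    mu2: float = -2.2
    kappa: float = 0.2
    tau: float = 8.0        # Hebbian time constant, seconds
    initial_c: float = 0.5
    initial_c_phase: str = "zero"  # "zero" (coherent excitatory) or "random"
    mode_locking: str = "k:m"  # "1:1" or "k:m" exponents at harmonic ratios
    neighbor_mode: str = "nearest"  # one source per ratio, or "band"
    freq_scaling: bool = True
    hebbian_freq_scaling: bool = False
    dt: float = 1.0 / 480.0
    drive_amplitude: float = 5.0
    pulse_width: float = 0.12
    pulse_shape: str = "raised-cosine"
    include_beat_track: bool = True
    init_radius_layer1: float = 0.01
    init_noise_rest: float = 1e-4

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        doc = dict(doc)
        for key in ("layer1", "layer2", "layer3"):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = LayerParams(**doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def radial_equilibria(p: LayerParams, r_max: float = 0.999, n_scan: int = 20000) -> np.ndarray:
    """Radii r > 0 solving alpha + beta1 r^2 + beta2 r^4/(1-r^2) = 0.

    Scan-and-bisect root finder on the radial amplitude equation of an
    isolated oscillator; used both by the model (documentation of regimes)
    and as the closed-form oracle tests compare trajectories against.
    """
    from scipy.optimize import brentq

    def g(r: float) -> float:
        return p.alpha + p.beta1 * r**2 + p.beta2 * r**4 / (1 - r**2)

    rs = np.linspace(1e-9, r_max, n_scan)
    vals = np.array([g(r) for r in rs])
    roots = []
    for i in range(len(rs) - 1):
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            roots.append(brentq(g, rs[i], rs[i + 1]))
    return np.array(roots)


def oscillator_derivative(z, p: LayerParams, omega, x):
    """Reference (numpy) right-hand side of one canonical Hopf oscillator."""
    z = np.asarray(z, dtype=complex)
    if np.any(np.abs(z) >= 1):
        raise ValueError("state escaped the unit disk (|z| >= 1)")
    a = p.alpha + 1j * np.asarray(omega)
    b = p.beta1 + 1j * p.delta1
    d = p.beta2 + 1j * p.delta2
    az = np.abs(z) ** 2
    return z * (a + b * az + d * az**2 / (1 - az)) + x


def coupling_input(states_source, state_target, c, ratios=((1, 1),)):
    """Mode-locked coupling input  sum_j sum_{k:m} c_j z_j^k conj(z_i)^(m-1)."""
    states_source = np.asarray(states_source, dtype=complex)
    c = np.asarray(c, dtype=complex)
    if c.shape != states_source.shape:
        raise ValueError("connection vector and source states differ in length")
    if len(ratios) == 0:
        raise ValueError("ratios must be non-empty")
    x = 0.0 + 0.0j
    for k, m in ratios:
        x += np.sum(c * states_source**k) * np.conj(state_target) ** (m - 1)
    return x


def hebbian_derivative(c, lambda_, mu1, mu2, kappa, tau, z_target, z_source, k=1, m=1):
    """Reference Hebbian connection derivative (single connection)."""
    if abs(c) >= 1:
        raise ValueError("connection escaped the unit disk (|c| >= 1)")
    ac = abs(c) ** 2
    intrinsic = c * (lambda_ + mu1 * ac + mu2 * ac**2 / (1 - ac))
    return (intrinsic + kappa * z_target**m * np.conj(z_source) ** k) / tau


def harmonic_pairs(freqs: np.ndarray, ratios=HARMONIC_RATIOS,
                   mode_locking: str = "1:1", neighbor_mode: str = "nearest"):
    """Index pairs (target, source) whose frequency ratio sits at a harmonic.

    With ``neighbor_mode='nearest'`` each target oscillator connects to the
    single source whose frequency is closest to ratio * f_target (provided it
    lies within one grid step); ``'band'`` admits every source within one grid
    step.  Returns (targets, sources, k, m) integer arrays; exponents are 1:1
    by default, or the printed small-integer ratios when
    ``mode_locking='k:m'``.
    """
    logf = np.log(freqs)
    step = logf[1] - logf[0]
    tgt, src, ks, ms = [], [], [], []
    # resonance condition k*f_source ~= m*f_target, rho = f_source/f_target
    ratio_km = {0.25: (4, 1), 1.0 / 3.0: (3, 1), 0.5: (2, 1), 1.0: (1, 1),
                2.0: (1, 2), 3.0: (1, 3), 4.0: (1, 4)}
    for rho in ratios:
        d = logf[None, :] - logf[:, None] - np.log(rho)  # [target, source]
        if neighbor_mode == "nearest":
            jj = np.argmin(np.abs(d), axis=1)
            ii = np.arange(len(freqs))
            keep = np.abs(d[ii, jj]) <= step * (1 + 1e-9)
            ii, jj = ii[keep], jj[keep]
        else:
            ii, jj = np.nonzero(np.abs(d) <= step * (1 + 1e-9))
        k, m = ratio_km.get(rho, (1, 1)) if mode_locking == "k:m" else (1, 1)
        tgt.append(ii)
        src.append(jj)
        ks.append(np.full(ii.size, k))
        ms.append(np.full(ii.size, m))
    return (np.concatenate(tgt), np.concatenate(src),
            np.concatenate(ks), np.concatenate(ms))


@dataclass
class NetworkModel:
    """Configured three-layer network ready to integrate."""

    config: ModelConfig
    freqs: np.ndarray
    conn_targets: np.ndarray
    conn_sources: np.ndarray
    conn_k: np.ndarray
    conn_m: np.ndarray

    @property
    def n(self) -> int:
        return self.freqs.size


def build_default_model(config: ModelConfig | None = None) -> NetworkModel:
    config = config or ModelConfig()
    freqs = make_frequency_grid(config.f_min, config.f_max, config.n_oscillators)
    tgt, src, k, m = harmonic_pairs(
        freqs, mode_locking=config.mode_locking, neighbor_mode=config.neighbor_mode
    )
    return NetworkModel(config, freqs, tgt, src, k, m)


@dataclass
class SimulationResult:
    """Mean fields (and optionally decimated trajectories) of one run."""

    mean_fields: np.ndarray      # [3, n_steps+1] complex
    sample_rate: float
    seed: int
    final_states: np.ndarray     # [3, n_osc] complex
    final_connections: np.ndarray
    trajectories: np.ndarray | None = None  # [3, n_osc, n_kept] complex
    trajectory_times: np.ndarray | None = None


def _initial_state(model: NetworkModel, rng: np.random.Generator) -> np.ndarray:
    cfg = model.config
    n = model.n
    z = np.empty((3, n), dtype=complex)
    r = cfg.init_radius_layer1 * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    z[0] = r * np.exp(1j * th)
    for layer in (1, 2):
        z[layer] = cfg.init_noise_rest * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return z


def _initial_connections(model: NetworkModel, rng: np.random.Generator) -> np.ndarray:
    if model.config.initial_c_phase == "random":
        phases = rng.random(model.conn_targets.size) * 2 * np.pi
        return model.config.initial_c * np.exp(1j * phases)
    return np.full(model.conn_targets.size, model.config.initial_c, dtype=complex)


def simulate(
    model: NetworkModel,
    stimulus: np.ndarray,
    duration: float = 16.0,
    dt: float | None = None,
    seed: int = 0,
    keep_trajectories: bool = False,
    trajectory_stride: int = 48,
) -> SimulationResult:
    """Integrate the network with fixed-step RK4.

    ``stimulus`` must be complex-valued, sampled at 2/dt (the integrator
    reads half-step values for the RK4 midpoints) with at least
    ``2*duration/dt + 1`` samples.  Dynamics are deterministic; only the
    initial conditions depend on ``seed``.
    """
    from ._oscillator_kernel import rk4_network

    cfg = model.config
    dt = dt or cfg.dt
    n_steps = int(round(duration / dt))
    stimulus = np.asarray(stimulus, dtype=complex)
    if stimulus.size < 2 * n_steps + 1:
        raise ValueError(
            f"stimulus must provide {2 * n_steps + 1} half-step samples, got {stimulus.size}"
        )
    rng = np.random.default_rng(seed)
    z0 = _initial_state(model, rng)
    c0 = _initial_connections(model, rng)
    lp = np.array(
        [
            [p.alpha, p.beta1, p.beta2, p.delta1, p.delta2]
            for p in (cfg.layer1, cfg.layer2, cfg.layer3)
        ]
    )
    stride = trajectory_stride if keep_trajectories else 0
    mf, zf, cf, traj, status, t_fail = rk4_network(
        z0,
        c0,
        model.conn_targets.astype(np.int64),
        model.conn_sources.astype(np.int64),
        model.conn_k.astype(np.int64),
        model.conn_m.astype(np.int64),
        model.freqs,
        lp,
        cfg.w_23,
        cfg.w_13,
        cfg.lambda_,
        cfg.mu1,
        cfg.mu2,
        cfg.kappa,
        cfg.tau,
        stimulus,
        dt,
        n_steps,
        cfg.freq_scaling,
        cfg.hebbian_freq_scaling,
        stride,
    )
    if status != 0:
        kinds = {1: "oscillator state escaped the unit disk",
                 2: "connection escaped the unit disk",
                 3: "non-finite state"}
        raise FloatingPointError(f"{kinds[int(status)]} at t = {t_fail * dt:.4f} s")
    times = None
    if keep_trajectories:
        times = np.arange(traj.shape[2]) * stride * dt
    return SimulationResult(
        mean_fields=mf,
        sample_rate=1.0 / dt,
        seed=seed,
        final_states=zf,
        final_connections=cf,
        trajectories=traj if keep_trajectories else None,
        trajectory_times=times,
    )


def mean_field(result: SimulationResult, layer: int) -> np.ndarray:
    """Mean-field time series of one layer (0-based layer index)."""
    return result.mean_fields[layer]


def amplitude_at_beat(
    mf: np.ndarray,
    sample_rate: float,
    f: float = 2.0,
    window: tuple[float, float] = (2.0, 16.0),
) -> float:
    """Fourier amplitude of the windowed mean field at (the nearest bin to) f.

    The first part of the signal (default 2 s) is dropped to discard the
    evoked transient, mirroring the run protocol the model emulates.
    """
    i0, i1 = int(round(window[0] * sample_rate)), int(round(window[1] * sample_rate))
    if i1 > mf.size:
        raise ValueError("analysis window extends beyond the simulation")
    seg = mf[i0:i1]
    spec = np.fft.fft(seg)
    freqs = np.fft.fftfreq(seg.size, 1.0 / sample_rate)
    k = np.argmin(np.abs(freqs - f))
    # single-sided amplitude: a real sinusoid splits its energy over +-f
    scale = 2.0 if np.isrealobj(mf) else 1.0
    return float(np.abs(spec[k]) / seg.size * scale)


def _melody_stimulus(pattern, cfg: ModelConfig, duration: float) -> np.ndarray:
    """Render a rhythm as the complex half-step-sampled drive signal.

    When ``include_beat_track`` is set (the default, mirroring stimuli that
    combine a strictly periodic drum with a syncopated bass line), the onsets
    are merged with an always-on beat-rate pulse train before rendering.
    """
    from .rhythms import RhythmPattern, analytic_input, onsets_to_pulse_signal

    if cfg.include_beat_track:
        beat = np.zeros(pattern.grid.n_positions, dtype=bool)
        beat[:: pattern.grid.subdivisions_per_beat] = True
        pattern = RhythmPattern(pattern.grid, pattern.onsets | beat)
    sr = 2.0 / cfg.dt
    sig = onsets_to_pulse_signal(
        pattern, sr, pulse_shape=cfg.pulse_shape,
        pulse_width=cfg.pulse_width, amplitude=cfg.drive_amplitude,
    )
    n_needed = 2 * int(round(duration / cfg.dt)) + 1
    if sig.size < n_needed:
        reps = int(np.ceil(n_needed / sig.size))
        sig = np.tile(sig, reps)
    return analytic_input(sig[:n_needed])


def run_protocol(
    model: NetworkModel,
    melodies,
    n_runs: int = 29,
    base_seed: int = 0,
    duration: float = 16.0,
    beat_freq: float = 2.0,
):
    """Simulate every melody x run and tabulate per-layer 2-Hz amplitudes.

    Returns a pandas DataFrame with columns (melody, run, layer, amplitude_2hz).
    Runs differ only in their random initial conditions; seeds derive
    deterministically from ``base_seed``.  A failed integration skips that
    run with a logged diagnostic instead of aborting the table.
    """
    import logging

    import pandas as pd

    if len(melodies) == 0:
        raise ValueError("melodies must be non-empty")
    log = logging.getLogger(__name__)
    ss = np.random.SeedSequence(base_seed)
    seeds = ss.generate_state(len(melodies) * n_runs) % (2**31)
    rows = []
    for mi, mel in enumerate(melodies):
        stim = _melody_stimulus(mel, model.config, duration)
        for run in range(n_runs):
            seed = int(seeds[mi * n_runs + run])
            try:
                res = simulate(model, stim, duration=duration, seed=seed)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                log.warning("melody %d run %d failed: %s", mi, run, exc)
                continue
            for layer in range(3):
                rows.append(
                    {
                        "melody": mi,
                        "run": run,
                        "layer": layer + 1,
                        "amplitude_2hz": amplitude_at_beat(
                            res.mean_fields[layer], res.sample_rate, f=beat_freq,
                            window=(2.0, duration),
                        ),
                    }
                )
    return pd.DataFrame(rows)


def drive_sensitivity_sweep(
    melodies, amplitudes, base_seed: int = 0, n_runs: int = 2,
    config: ModelConfig | None = None,
):
    """Per-layer 2-Hz amplitude as a function of the onset-pulse drive level."""
    import pandas as pd

    frames = []
    base = (config or ModelConfig()).to_dict()
    for amp in amplitudes:
        cfg = ModelConfig.from_dict({**base, "drive_amplitude": amp})
        model = build_default_model(cfg)
        tab = run_protocol(model, melodies, n_runs=n_runs, base_seed=base_seed)
        tab["drive_amplitude"] = amp
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
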