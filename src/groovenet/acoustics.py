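"""Cochlear-style envelope extraction and low-frequency modulation spectra.

The acoustic characterization stage: a 32-band gammatone filterbank
(ERB-spaced centre frequencies), per-band Hilbert envelopes summed into a
broadband temporal envelope, and the Fourier amplitude of that envelope on a
1-9 Hz analysis grid.  The modulation amplitude at the 2-Hz beat rate is the
acoustic predictor that declines with the degree of syncopation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import gammatone, hilbert, sosfiltfilt, butter, tf2sos

__all__ = [
    "EnvelopeSignal",
    "ModulationSpectrum",
    "erb_space",
    "cochlear_envelope",
    "modulation_spectrum",
    "read_wav_mono",
]


@dataclass(frozen=True)
class EnvelopeSignal:
    """Non-negative broadband temporal envelope."""

    samples: np.ndarray
    sample_rate: float
    band_count: int = 32

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size == 0:
            raise ValueError("empty envelope")
        if (s < -1e-12).any():
            raise ValueError("envelope samples must be non-negative")
        object.__setattr__(self, "samples", np.maximum(s, 0.0))

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class ModulationSpectrum:
    """Amplitude of envelope fluctuations on a low-frequency grid."""

    frequencies: np.ndarray
    amplitude: np.ndarray
    amplitude_db_at_beat: float

    def to_csv(self) -> str:
        lines = ["frequency_hz,amplitude"]
        lines += [f"{f:.6g},{a:.6g}" for f, a in zip(self.frequencies, self.amplitude)]
        return "\n".join(lines) + "\n"


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Centre frequencies equally spaced on the ERB-rate scale (Glasberg-Moore)."""
    def hz_to_erb(f):
        return 21.4 * np.log10(1 + 0.00437 * f)

    def erb_to_hz(e):
        return (10 ** (e / 21.4) - 1) / 0.00437

    return erb_to_hz(np.linspace(hz_to_erb(f_lo), hz_to_erb(f_hi), n))


def cochlear_envelope(
    audio: np.ndarray,
    sample_rate: float,
    n_bands: int = 32,
    f_lo: float = 80.0,
    f_hi: float | None = None,
) -> EnvelopeSignal:
    """Broadband temporal envelope from a gammatone filterbank.

    The signal is split into ``n_bands`` gammatone channels with ERB-spaced
    centre frequencies from ``f_lo`` up to min(8 kHz, 0.9 x Nyquist), the
    magnitude of each channel's analytic signal is taken, and the magnitudes
    are summed across channels.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    audio = np.asarray(audio, dtype=float)
    if audio.size < sample_rate:
        raise ValueError("need at least 1 s of audio")
    top = min(8000.0, 0.45 * sample_rate) if f_hi is None else f_hi
    if sample_rate < 2 * top:
        raise ValueError("sample_rate too low for the requested filterbank")
    centers = erb_space(f_lo, top, n_bands)
    env = np.zeros_like(audio)
    for fc in centers:
        b, a = gammatone(fc, "iir", fs=sample_rate)
        sos = tf2sos(b, a)
        band = sosfiltfilt(sos, audio)
        env += np.abs(hilbert(band))
    return EnvelopeSignal(env, sample_rate, n_bands)


def modulation_spectrum(
    envelope: EnvelopeSignal,
    f_lo: float = 1.0,
    f_hi: float = 9.0,
    beat_freq: float = 2.0,
    decimate_to: float = 100.0,
) -> ModulationSpectrum:
    """Fourier amplitude of the mean-removed envelope between f_lo and f_hi.

    The envelope is low-pass decimated (default 100 Hz) before the FFT;
    ``amplitude_db_at_beat`` is 20*log10 of the amplitude at the analysis
    frequency nearest ``beat_freq`` (dB re 1 arbitrary unit).
    """
    if envelope.duration < 2.0 / f_lo:
        raise ValueError("envelope too short to resolve f_lo")
    x = envelope.samples
    sr = envelope.sample_rate
    if decimate_to and sr > decimate_to:
        step = int(round(sr / decimate_to))
        sos = butter(4, 0.8 * (sr / step) / 2, fs=sr, output="sos")
        x = sosfiltfilt(sos, x)[::step]
        sr = sr / step
    x = x - x.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / sr)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    amp = np.abs(spec[sel]) * 2.0 / x.size
    f_sel = freqs[sel]
    a_beat = amp[np.argmin(np.abs(f_sel - beat_freq))]
    db = 20.0 * np.log10(max(a_beat, np.finfo(float).tiny))
    return ModulationSpectrum(f_sel, amp, float(db))


def read_wav_mono(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file, averaging stereo to mono, scaled to [-1, 1]."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(sr)
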