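"""Time-frequency decomposition, 1/f rectification, and spectral-gradient fits.

Neural (or synthetic) signals are decomposed with Morlet wavelets — central
frequency parameter Fc = 1 and temporal-resolution parameter FwhmTc = 3 s,
i.e. the mother wavelet has a 3-s FWHM Gaussian envelope at 1 Hz, scaled by
1/f at frequency f.  Power spectra are "1/f rectified" by z-scoring power
across locations at each frequency, turning the per-frequency distribution
over locations into zero-mean unit-sd maps.  The dominant frequency per
location and its 5th-order polynomial trend along each spatial coordinate
quantify the anatomo-spectral gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialTFCube",
    "SourceGrid",
    "DominantFrequencyMap",
    "meg_frequency_grid",
    "morlet_kernels",
    "morlet_tfr",
    "wavelet_power_features",
    "time_avg_power",
    "rectify_1f",
    "dominant_frequency",
    "fit_spatial_gradient",
]

FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def meg_frequency_grid(f_lo: float = 1.0, f_hi: float = 100.0, n: int = 100) -> np.ndarray:
    """Log-spaced analysis frequencies (default 100 values, 1-100 Hz)."""
    return np.geomspace(f_lo, f_hi, n)


@dataclass
class TrialTFCube:
    """Wavelet power (and optionally phase) per trial, location, frequency, time."""

    power: np.ndarray                 # [trial, location, freq, time]
    freqs: np.ndarray
    times: np.ndarray
    phase: np.ndarray | None = None   # same shape as power
    edge_mask: np.ndarray | None = None  # [freq, time] True where edge-contaminated

    def __post_init__(self) -> None:
        if self.power.ndim != 4:
            raise ValueError("power must be [trial, location, freq, time]")
        if self.power.shape[2] != self.freqs.size or self.power.shape[3] != self.times.size:
            raise ValueError("axis lengths do not match power shape")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_locations(self) -> int:
        return self.power.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("power", data=self.power)
            fh.create_dataset("freqs", data=self.freqs)
            fh.create_dataset("times", data=self.times)
            if self.phase is not None:
                fh.create_dataset("phase", data=self.phase)

    @classmethod
    def from_hdf5(cls, path) -> "TrialTFCube":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                power=fh["power"][()],
                freqs=fh["freqs"][()],
                times=fh["times"][()],
                phase=fh["phase"][()] if "phase" in fh else None,
            )


@dataclass
class SourceGrid:
    """Volumetric vertex coordinates (mm) with nearest-neighbour queries."""

    coords: np.ndarray  # [n_vertices, 3]
    _tree: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be [n, 3]")
        if np.unique(c, axis=0).shape[0] != c.shape[0]:
            raise ValueError("vertex coordinates must be pairwise distinct")
        object.__setattr__(self, "coords", c)

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def _kdtree(self):
        if self._tree is None:
            from scipy.spatial import cKDTree

            object.__setattr__(self, "_tree", cKDTree(self.coords))
        return self._tree

    def neighbors(self, vertex: int, k: int) -> np.ndarray:
        """The ``k`` nearest vertices to ``vertex`` (excluding itself)."""
        if k >= self.n_vertices:
            raise ValueError("requested more neighbours than vertices")
        _, idx = self._kdtree().query(self.coords[vertex], k=k + 1)
        return np.asarray(idx[1:], dtype=int)

    def min_spacing(self) -> float:
        d, _ = self._kdtree().query(self.coords, k=2)
        return float(d[:, 1].min())


@dataclass(frozen=True)
class DominantFrequencyMap:
    """Per-vertex frequency of maximal 1/f-rectified power."""

    frequencies_hz: np.ndarray
    band: tuple = (1.0, 45.0)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        lo, hi = self.band
        if ((f < lo) | (f > hi)).any():
            raise ValueError("dominant frequencies outside the stated band")
        object.__setattr__(self, "frequencies_hz", f)


def morlet_kernels(freqs, sample_rate, n_samples, fc: float = 1.0, fwhm_tc: float = 3.0):
    """Frequency responses of unit-energy Morlet wavelets on an FFT grid.

    At analysis frequency f the Gaussian envelope sd is
    ``fwhm_tc * FWHM_TO_SD * fc / f`` seconds; in the frequency domain the
    (analytic) wavelet is a Gaussian centred on f.  Returns [n_freqs, n_rfft].
    """
    freqs = np.asarray(freqs, dtype=float)
    grid = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    sd_t = fwhm_tc * FWHM_TO_SD * fc / freqs
    sd_f = 1.0 / (2.0 * np.pi * sd_t)
    # unit-energy normalization: |Psi(w)|^2 integrates to 1 over the rfft grid
    kern = np.exp(-0.5 * ((grid[None, :] - freqs[:, None]) / sd_f[:, None]) ** 2)
    df = sample_rate / n_samples
    energy = (kern**2).sum(axis=1) * df
    return kern / np.sqrt(energy[:, None])


def morlet_tfr(
    signal: np.ndarray,
    sample_rate: float,
    freqs,
    fc: float = 1.0,
    fwhm_tc: float = 3.0,
    return_complex: bool = False,
):
    """Morlet wavelet transform of one or more signals.

    ``signal`` may be [time] or [channel, time].  Returns (power, phase) each
    [channel, freq, time] (the channel axis squeezed for 1-D input), or the
    complex coefficients when ``return_complex``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n = signal.shape[1]
    freqs = np.asarray(freqs, dtype=float)
    if (freqs >= sample_rate / 2).any():
        raise ValueError("analysis frequency above Nyquist")
    if n / sample_rate < 2.0 * fwhm_tc * fc / freqs.min():
        raise ValueError("signal shorter than twice the wavelet FWHM at the lowest frequency")
    kern = morlet_kernels(freqs, sample_rate, n, fc, fwhm_tc)
    spec = np.fft.rfft(signal, axis=1)
    # analytic-signal convention: one-sided spectrum doubled
    coeffs = np.fft.ifft(
        np.concatenate(
            [2.0 * spec[:, None, :] * kern[None, :, :],
             np.zeros((signal.shape[0], freqs.size, n - spec.shape[1]))],
            axis=2,
        ),
        axis=2,
    )
    if return_complex:
        return np.squeeze(coeffs)
    power = np.abs(coeffs) ** 2
    phase = np.angle(coeffs)
    return np.squeeze(power), np.squeeze(phase)


def edge_mask(freqs, times, sample_rate, fc: float = 1.0, fwhm_tc: float = 3.0) -> np.ndarray:
    """True where a time sample is within one FWHM of either signal edge."""
    freqs = np.asarray(freqs, dtype=float)
    fwhm = fwhm_tc * fc / freqs
    t0, t1 = times[0], times[-1]
    return (times[None, :] < t0 + fwhm[:, None]) | (times[None, :] > t1 - fwhm[:, None])


def wavelet_power_features(
    signals: np.ndarray,
    sample_rate: float,
    freqs,
    fc: float = 1.0,
    fwhm_tc: float = 3.0,
) -> np.ndarray:
    """Epoch-averaged wavelet power computed in the frequency domain.

    By Parseval, the time-mean of |wavelet coefficient|^2 over the whole
    epoch equals sum_w |X(w)|^2 |Psi_f(w)|^2 / N^2 (one-sided, doubled).
    Used for the large synthetic studies where only time-averaged power is
    needed; agrees with averaging the full transform over the epoch.
    ``signals``: [..., time]; returns [..., freq].
    """
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[-1]
    kern = morlet_kernels(np.asarray(freqs, float), sample_rate, n, fc, fwhm_tc)
    spec = np.fft.rfft(signals, axis=-1)
    pw = np.abs(spec) ** 2
    return (4.0 * pw) @ (kern**2).T / n**2


def time_avg_power(cube: TrialTFCube, window: tuple = (0.5, 16.0), drop_edges: bool = True):
    """Mean power over a time window per trial, location and frequency."""
    t = cube.times
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError("empty averaging window")
    if drop_edges and cube.edge_mask is not None:
        keep = sel[None, :] & ~cube.edge_mask
        w = keep.astype(float)
        denom = w.sum(axis=1)
        denom[denom == 0] = np.nan
        return np.einsum("tlfs,fs->tlf", cube.power, w) / denom[None, None, :]
    return cube.power[..., sel].mean(axis=-1)


def rectify_1f(power: np.ndarray) -> np.ndarray:
    """Remove the aperiodic 1/f component by z-scoring across locations.

    ``power``: [location, freq] (or [trial, location, freq], z-scored per
    trial).  For each frequency the cross-location distribution of the output
    has mean 0 and sd 1; a frequency with zero cross-location variance is an
    error (named in the message).
    """
    power = np.asarray(power, dtype=float)
    if power.ndim == 3:
        return np.stack([rectify_1f(p) for p in power])
    if power.ndim != 2:
        raise ValueError("power must be [location, freq]")
    if power.shape[0] < 2:
        raise ValueError("need at least 2 locations to z-score across locations")
    mu = power.mean(axis=0)
    sd = power.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero cross-location variance at frequency index {bad[0]}")
    return (power - mu) / sd


def dominant_frequency(
    z_spectra: np.ndarray,
    freqs: np.ndarray,
    band: tuple = (1.0, 45.0),
) -> DominantFrequencyMap:
    """Per-location frequency of maximal z-scored power within ``band``.

    Ties resolve to the lower frequency (argmax of the first maximum).
    """
    freqs = np.asarray(freqs, dtype=float)
    sel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if sel.size == 0:
        raise ValueError("band contains no grid frequencies")
    sub = np.asarray(z_spectra, dtype=float)[:, sel]
    return DominantFrequencyMap(freqs[sel[np.argmax(sub, axis=1)]], band)


def _poly_fit_1d(coord: np.ndarray, y: np.ndarray, order: int):
    """Degree-``order`` polynomial fit with internal standardization."""
    mu, sd = coord.mean(), coord.std()
    if sd == 0:
        raise ValueError("rank-deficient design: coordinate has zero variance")
    xs = (coord - mu) / sd
    coef_s = np.polyfit(xs, y, order)
    yhat = np.polyval(coef_s, xs)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n, p = y.size, order + 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    # map standardized coefficients back to mm units
    comp = np.polynomial.polynomial.Polynomial(coef_s[::-1])(
        np.polynomial.polynomial.Polynomial([-mu / sd, 1.0 / sd])
    )
    coef_mm = comp.coef[::-1]
    return coef_mm, r2, adj


def fit_spatial_gradient(dfm: DominantFrequencyMap, grid: SourceGrid, order: int = 5):
    """Polynomial trend of dominant frequency along each spatial dimension.

    Fits a degree-5 polynomial of dominant frequency against x, y and z
    separately and reports the adjusted r-squared per dimension.  Returns a
    dict keyed 'x'/'y'/'z' of :class:`groovenet.behavior.FitResult`.
    """
    from .behavior import FitResult

    y = dfm.frequencies_hz
    if y.size < order + 2:
        raise ValueError("need at least order + 2 vertices")
    out = {}
    for d, name in enumerate("xyz"):
        coef, r2, adj = _poly_fit_1d(grid.coords[:, d], y, order)
        out[name] = FitResult(tuple(coef), r2, adj)
    return out
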