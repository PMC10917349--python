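"""Behavioral analyses: tapping dynamics and rating-vs-syncopation fits.

Instantaneous tap frequency is the reciprocal inter-tap interval
F(t) = 1 / (m_t - m_{t-1}); groove ratings are related to the degree of
syncopation with a quadratic fit (the inverted-U profile) and acoustic or
model readouts with a linear fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TapRecord",
    "FitResult",
    "instantaneous_tap_frequency",
    "fit_quadratic",
    "fit_linear",
    "tap_frequency_histogram",
    "load_tap_records",
    "load_rating_table",
]


@dataclass(frozen=True)
class TapRecord:
    """Finger-tap times (seconds, strictly increasing) for one trial."""

    tap_times: np.ndarray
    stimulus: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.tap_times, dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("tap times must be non-decreasing")
        object.__setattr__(self, "tap_times", t)


@dataclass(frozen=True)
class FitResult:
    """Polynomial fit summary with explained-variance diagnostics."""

    coefficients: tuple        # highest order first (numpy convention)
    r_squared: float
    adjusted_r_squared: float
    vertex: float | None = None
    curvature_sign: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": list(self.coefficients),
                "r_squared": self.r_squared,
                "adjusted_r_squared": self.adjusted_r_squared,
                "vertex": self.vertex,
                "curvature_sign": self.curvature_sign,
            }
        )


def instantaneous_tap_frequency(rec: TapRecord) -> np.ndarray:
    """Per-interval tap frequency in Hz; length is n_taps - 1."""
    t = rec.tap_times
    if t.size < 2:
        return np.empty(0)
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("duplicate tap events (zero inter-tap interval)")
    return 1.0 / dt


def tap_frequency_histogram(records, bin_width: float = 0.1, f_max: float = 8.0):
    """Pooled histogram of instantaneous tap frequencies (0.1-Hz bins)."""
    freqs = np.concatenate([instantaneous_tap_frequency(r) for r in records] or [np.empty(0)])
    edges = np.arange(0.0, f_max + bin_width, bin_width)
    counts, _ = np.histogram(freqs, bins=edges)
    return counts, edges


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_quadratic(x, y) -> FitResult:
    """Least-squares quadratic fit with adjusted r-squared and vertex.

    The adjusted r-squared penalises for the three estimated coefficients;
    the vertex abscissa -b/2a and the curvature sign summarise the
    inverted-U diagnosis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct x values for a quadratic fit")
    coef = np.polyfit(x, y, 2)
    yhat = np.polyval(coef, x)
    r2 = _r2(y, yhat)
    n, p = x.size, 3
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan
    a, b = coef[0], coef[1]
    vertex = float(-b / (2 * a)) if a != 0 else None
    return FitResult(tuple(coef), r2, float(adj), vertex, int(np.sign(a)) if a else 0)


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares line; r-squared is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    coef = np.polyfit(x, y, 1)
    sy = np.std(y)
    r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    r2 = r * r
    n, p = x.size, 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan
    return FitResult(tuple(coef), r2, float(adj))


def load_tap_records(path) -> list[TapRecord]:
    """Read tap records from CSV with columns participant,stimulus,tap_time."""
    import pandas as pd

    df = pd.read_csv(path)
    recs = []
    for (part, stim), grp in df.groupby(["participant", "stimulus"]):
        recs.append(TapRecord(np.sort(grp["tap_time"].to_numpy()), str(stim), str(part)))
    return recs


def load_rating_table(path):
    """Read a ratings table (participant, melody, condition, rating) from CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    lo, hi = df["rating"].min(), df["rating"].max()
    if lo < 1 or hi > 7:
        raise ValueError("ratings outside the declared 1-7 Likert bounds")
    return df
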