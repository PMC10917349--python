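"""Beat-gridded rhythm patterns and the Longuet-Higgins–Lee syncopation index.

A rhythm lives on a metrical grid: ``n_measures`` measures of
``beats_per_measure`` beats, each beat cut into ``subdivisions_per_beat``
equal subdivisions, with the beat running at ``beat_rate`` Hz (2 Hz in the
stimuli this package emulates).  Metric weights are assigned by recursive
subdivision of the measure (downbeat weight 0, one less per level), and a
syncopation event is a note on a weak position followed by silence on a
stronger one; the index is the summed weight differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeatGrid",
    "RhythmPattern",
    "MetricWeightTree",
    "SyncopationScore",
    "build_metric_weights",
    "syncopation_index",
    "generate_syncopation_family",
    "onsets_to_pulse_signal",
    "analytic_input",
    "pattern_from_json",
    "pattern_to_json",
    "pattern_from_onset_csv",
]


@dataclass(frozen=True)
class BeatGrid:
    """Metrical grid on which note onsets are placed.

    Parameters
    ----------
    beat_rate : float
        Beat frequency in Hz (2 Hz for the drum-beat stimuli).
    subdivisions_per_beat : int
        Grid resolution within one beat.
    beats_per_measure : int
    n_measures : int
    """

    beat_rate: float = 2.0
    subdivisions_per_beat: int = 2
    beats_per_measure: int = 4
    n_measures: int = 4

    def __post_init__(self) -> None:
        if self.beat_rate <= 0:
            raise ValueError("beat_rate must be positive")
        for name in ("subdivisions_per_beat", "beats_per_measure", "n_measures"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def positions_per_measure(self) -> int:
        return self.beats_per_measure * self.subdivisions_per_beat

    @property
    def n_positions(self) -> int:
        return self.n_measures * self.positions_per_measure

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_measures * self.beats_per_measure / self.beat_rate

    def position_times(self) -> np.ndarray:
        """Timestamp of each grid position (position i at i / grid rate)."""
        rate = self.beat_rate * self.subdivisions_per_beat
        return np.arange(self.n_positions) / rate


@dataclass(frozen=True)
class RhythmPattern:
    """Note onsets (boolean vector over grid positions) on a :class:`BeatGrid`."""

    grid: BeatGrid
    onsets: np.ndarray
    pitches: tuple | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=bool)
        if onsets.shape != (self.grid.n_positions,):
            raise ValueError(
                f"onsets length {onsets.shape} does not match grid "
                f"position count {self.grid.n_positions}"
            )
        object.__setattr__(self, "onsets", onsets)

    @property
    def n_onsets(self) -> int:
        return int(self.onsets.sum())

    def onset_times(self) -> np.ndarray:
        return self.grid.position_times()[self.onsets]


@dataclass(frozen=True)
class MetricWeightTree:
    """Integer metric weight per grid position (0 at the downbeat, negative below)."""

    grid: BeatGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=int)
        if w.shape != (self.grid.n_positions,):
            raise ValueError("weights length must equal grid position count")
        if w[0] != w.max():
            raise ValueError("downbeat must carry the maximum weight")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class SyncopationScore:
    """Total syncopation and the per-event (note, rest, weight-difference) detail."""

    total: int
    per_event: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.total != sum(e[2] for e in self.per_event):
            raise ValueError("total must equal the sum of per-event differences")
        if any(e[2] <= 0 for e in self.per_event):
            raise ValueError("event weight differences must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "events": [
                    {"note_position": int(n), "rest_position": int(r), "weight_difference": int(d)}
                    for n, r, d in self.per_event
                ],
            },
            indent=2,
        )


def _split_sequence(n: int, label: str, prefer_duple: bool = True) -> list[int]:
    """Factor ``n`` into an ordered sequence of 2s and 3s (metric tree splits)."""
    splits: list[int] = []
    primes = (2, 3) if prefer_duple else (3, 2)
    while n > 1:
        for p in primes:
            if n % p == 0:
                splits.append(p)
                n //= p
                break
        else:
            raise ValueError(
                f"{label} = {n} is not decomposable into a binary/ternary metric tree"
            )
    return splits


def build_metric_weights(
    grid: BeatGrid, prefer_duple: bool = True, max_depth: int | None = None
) -> MetricWeightTree:
    """Assign Longuet-Higgins–Lee metric weights by recursive subdivision.

    The measure level has weight 0; each subdivision level subtracts 1.  The
    split order factors ``beats_per_measure`` first, then
    ``subdivisions_per_beat``, into 2s and 3s (duple splits preferred by
    default).  Weights repeat identically across measures.
    """
    splits = _split_sequence(grid.beats_per_measure, "beats_per_measure", prefer_duple)
    splits += _split_sequence(grid.subdivisions_per_beat, "subdivisions_per_beat", prefer_duple)
    if max_depth is not None:
        splits = splits[:max_depth]

    weights = np.zeros(1, dtype=int)
    for depth, p in enumerate(splits, start=1):
        tiled = np.repeat(weights, p).reshape(-1, p).copy()
        # only the first position of each group keeps the parent weight
        tiled[:, 1:] = -depth
        weights = tiled.ravel()
    # pad to full resolution if max_depth truncated the tree
    reps = grid.positions_per_measure // weights.size
    if reps * weights.size != grid.positions_per_measure:
        raise ValueError("truncated tree does not tile the measure")
    weights = np.repeat(weights, reps)
    return MetricWeightTree(grid, np.tile(weights, grid.n_measures))


def syncopation_index(
    pattern: RhythmPattern, weights: MetricWeightTree, cyclic: bool = True
) -> SyncopationScore:
    """Longuet-Higgins–Lee degree of syncopation of a rhythm pattern.

    For each note onset at metric weight ``w1``, silent positions up to the
    next onset are scanned (wrapping around the pattern when ``cyclic``); if
    the strongest such rest has weight ``w2 > w1`` a syncopation of value
    ``w2 - w1`` is recorded.  The total is the sum over events; a rhythm with
    every onset on a beat scores 0.
    """
    if pattern.grid.n_positions == 0:
        raise ValueError("empty grid")
    if weights.grid != pattern.grid:
        raise ValueError("pattern and weights must share a grid")
    onset_idx = np.flatnonzero(pattern.onsets)
    if onset_idx.size == 0:
        return SyncopationScore(0, ())

    n = pattern.grid.n_positions
    w = weights.weights
    events = []
    for k, p in enumerate(onset_idx):
        if cyclic:
            nxt = onset_idx[(k + 1) % onset_idx.size]
            gap = (nxt - p - 1) % n if onset_idx.size > 1 else n - 1
            rest_pos = (p + 1 + np.arange(gap)) % n
        else:
            nxt = onset_idx[k + 1] if k + 1 < onset_idx.size else n
            rest_pos = np.arange(p + 1, nxt)
        if rest_pos.size == 0:
            continue
        best = rest_pos[np.argmax(w[rest_pos])]
        diff = int(w[best] - w[p])
        if diff > 0:
            events.append((int(p), int(best), diff))
    return SyncopationScore(sum(e[2] for e in events), tuple(events))


def _beat_aligned(base: RhythmPattern, weights: MetricWeightTree) -> RhythmPattern:
    """Move every onset in each measure onto that measure's strongest free positions."""
    grid = base.grid
    ppm = grid.positions_per_measure
    new = np.zeros_like(base.onsets)
    w_measure = weights.weights[:ppm]
    order = np.argsort(-w_measure, kind="stable")  # strongest first
    for m in range(grid.n_measures):
        count = int(base.onsets[m * ppm : (m + 1) * ppm].sum())
        new[m * ppm + order[:count]] = True
    return RhythmPattern(grid, new)


def generate_syncopation_family(
    base: RhythmPattern,
    levels: list[int],
    seed: int,
    max_iter: int = 20000,
) -> list[RhythmPattern]:
    """Generate variants of ``base`` with requested syncopation index totals.

    Note counts per measure are preserved (as in the melody variants the
    stimuli emulate).  A seeded stochastic local search moves one onset at a
    time within its measure; the first pattern whose index equals the target
    is returned.  Raises if a level is unreachable, reporting the best value
    achieved.
    """
    if sorted(levels) != list(levels):
        raise ValueError("levels must be sorted ascending")
    weights = build_metric_weights(base.grid)
    rng = np.random.default_rng(seed)
    grid = base.grid
    ppm = grid.positions_per_measure
    sub = grid.subdivisions_per_beat
    out = []
    for level in levels:
        current = _beat_aligned(base, weights).onsets.copy()
        if level == 0:
            cand = RhythmPattern(grid, current)
            if syncopation_index(cand, weights).total != 0:
                raise ValueError("no beat-aligned variant reaches index 0")
            out.append(cand)
            continue
        # anticipation moves first: shift an on-beat onset one subdivision
        # earlier, creating a weak-accent note before a strong-accent rest
        best_total = 0
        for it in range(max_iter):
            total = syncopation_index(RhythmPattern(grid, current), weights).total
            best_total = max(best_total, total)
            if total == level:
                break
            need = level - total
            moved = False
            if need > 0:
                beats = np.flatnonzero(current[::sub] if sub > 1 else current)
                cand_moves = []
                for b in (beats * sub if sub > 1 else beats):
                    j = (b - 1) % current.size
                    if current[j] or not current[b]:
                        continue
                    trial = current.copy()
                    trial[b], trial[j] = False, True
                    t2 = syncopation_index(RhythmPattern(grid, trial), weights).total
                    if total < t2 <= level:
                        cand_moves.append((t2, b, j))
                if cand_moves:
                    t2s = np.array([c[0] for c in cand_moves])
                    top = np.flatnonzero(t2s == t2s.max())
                    _, b, j = cand_moves[top[rng.integers(top.size)]]
                    current[b], current[j] = False, True
                    moved = True
            if not moved:
                # fallback: random within-measure swap accepted if it helps
                m = int(rng.integers(grid.n_measures))
                seg = slice(m * ppm, (m + 1) * ppm)
                on = np.flatnonzero(current[seg])
                off = np.flatnonzero(~current[seg])
                if on.size == 0 or off.size == 0:
                    continue
                i = m * ppm + on[rng.integers(on.size)]
                j = m * ppm + off[rng.integers(off.size)]
                current[i], current[j] = False, True
                new_total = syncopation_index(RhythmPattern(grid, current), weights).total
                if abs(new_total - level) > abs(total - level) and rng.random() > 0.15:
                    current[i], current[j] = True, False
        final = RhythmPattern(grid, current)
        total = syncopation_index(final, weights).total
        if total != level:
            raise ValueError(
                f"target syncopation level {level} unreachable within "
                f"{max_iter} moves; best achieved {best_total}"
            )
        out.append(final)
    return out


def onsets_to_pulse_signal(
    pattern: RhythmPattern,
    sample_rate: float,
    pulse_shape: str = "rectangular",
    pulse_width: float = 0.025,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Render onsets as a train of unit pulses centred on the onset times."""
    grid_rate = pattern.grid.beat_rate * pattern.grid.subdivisions_per_beat
    if sample_rate < 4 * grid_rate:
        raise ValueError("sample_rate must be at least 4x the grid rate")
    if pulse_width >= 1.0 / grid_rate:
        raise ValueError("pulse_width must be shorter than the inter-position interval")
    n = int(round(pattern.grid.duration * sample_rate))
    sig = np.zeros(n)
    half = pulse_width / 2.0
    t = np.arange(n) / sample_rate
    occupied = np.zeros(n, dtype=bool)
    for t0 in pattern.onset_times():
        mask = (t >= t0 - half) & (t < t0 + half)
        if (occupied & mask).any():
            raise ValueError("overlapping pulses")
        occupied |= mask
        if pulse_shape == "rectangular":
            sig[mask] = amplitude
        elif pulse_shape == "raised-cosine":
            sig[mask] = amplitude * 0.5 * (1 + np.cos(np.pi * (t[mask] - t0) / half))
        else:
            raise ValueError(f"unknown pulse_shape {pulse_shape!r}")
    return sig


def analytic_input(signal: np.ndarray) -> np.ndarray:
    """Complex analytic version of a real drive signal (Hilbert transform)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    from scipy.signal import hilbert

    return hilbert(signal)


# ---------------------------------------------------------------------------
# I/O

def pattern_to_json(pattern: RhythmPattern) -> str:
    g = pattern.grid
    return json.dumps(
        {
            "grid": {
                "beat_rate": g.beat_rate,
                "subdivisions_per_beat": g.subdivisions_per_beat,
                "beats_per_measure": g.beats_per_measure,
                "n_measures": g.n_measures,
            },
            "onsets": np.flatnonzero(pattern.onsets).tolist(),
        }
    )


def pattern_from_json(text: str) -> RhythmPattern:
    doc = json.loads(text)
    grid = BeatGrid(**doc["grid"])
    onsets = np.zeros(grid.n_positions, dtype=bool)
    onsets[np.asarray(doc["onsets"], dtype=int)] = True
    return RhythmPattern(grid, onsets)


def pattern_from_onset_csv(text: str, grid: BeatGrid) -> RhythmPattern:
    """Read one onset time (seconds) per row and quantize to the grid."""
    times = np.array([float(line) for line in text.strip().splitlines() if line.strip()])
    rate = grid.beat_rate * grid.subdivisions_per_beat
    idx = np.round(times * rate).astype(int)
    err = np.abs(times * rate - idx)
    if (err > 0.5).any():  # cannot happen with round, kept as guard for NaN
        raise ValueError("onset time does not quantize onto the grid")
    import warnings

    if (err > 0.25).any():
        warnings.warn("onset quantization error exceeds half a subdivision interval")
    onsets = np.zeros(grid.n_positions, dtype=bool)
    onsets[idx % grid.n_positions] = True
    return RhythmPattern(grid, onsets)
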