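import numpy as np
import pytest

from groovenet.rhythms import BeatGrid, RhythmPattern, build_metric_weights


@pytest.fixture(scope="session")
def grid8s() -> BeatGrid:
    """The study grid: 2-Hz beat, 2 subdivisions, 4 beats/measure, 8 s."""
    return BeatGrid(beat_rate=2.0, subdivisions_per_beat=2, beats_per_measure=4, n_measures=4)


@pytest.fixture(scope="session")
def on_beat_pattern(grid8s) -> RhythmPattern:
    onsets = np.zeros(grid8s.n_positions, dtype=bool)
    onsets[:: grid8s.subdivisions_per_beat] = True
    return RhythmPattern(grid8s, onsets)


@pytest.fixture(scope="session")
def weights8s(grid8s):
    return build_metric_weights(grid8s)


def brute_force_syncopation(onsets: np.ndarray, weights: np.ndarray) -> int:
    """Independent oracle: scan every (note, following-rest) pair cyclically."""
    n = len(onsets)
    idx = [i for i in range(n) if onsets[i]]
    if not idx:
        return 0
    total = 0
    for k, p in enumerate(idx):
        nxt = idx[(k + 1) % len(idx)]
        gap = (nxt - p - 1) % n if len(idx) > 1 else n - 1
        rests = [(p + 1 + j) % n for j in range(gap)]
        if not rests:
            continue
        best = max(weights[r] for r in rests)
        if best > weights[p]:
            total += best - weights[p]
    return total
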