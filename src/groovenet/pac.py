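"""Phase-amplitude coupling via the normalized-resultant rho statistic.

rho = |sum_t a_t exp(i phi_t)| / sqrt(N * sum_t a_t^2)

with phi the phase of a slow rhythm (delta 1.4 Hz or the 2-Hz beat) and a
the amplitude envelope of a faster one (3-45 Hz).  Cauchy-Schwarz bounds rho
in [0, 1]; a flat phase distribution with constant amplitude gives 0, and
amplitude concentrated at a single phase gives 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PACEstimate",
    "pac_rho",
    "pac_comodulogram",
    "cluster_vs_wholebrain",
]


@dataclass(frozen=True)
class PACEstimate:
    rho: float
    phase_frequency: float
    amplitude_frequency: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho outside [0, 1]")


def pac_rho(
    phase: np.ndarray,
    amplitude: np.ndarray,
    phase_frequency: float = np.nan,
    amplitude_frequency: float = np.nan,
    min_samples: int = 100,
) -> PACEstimate:
    """Normalized resultant of amplitude-weighted phases."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude lengths differ")
    if phase.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if (amplitude < 0).any():
        raise ValueError("amplitudes must be non-negative")
    denom = np.sqrt(phase.size * np.sum(amplitude**2))
    if denom == 0:
        raise ValueError("all-zero amplitude")
    rho = float(np.abs(np.sum(amplitude * np.exp(1j * phase))) / denom)
    return PACEstimate(min(rho, 1.0), phase_frequency, amplitude_frequency, phase.size)


def pac_comodulogram(
    cube,
    locations,
    phase_freqs=(1.4, 2.0),
    amp_band=(3.0, 45.0),
    window=(0.5, 16.0),
    drop_edges: bool = True,
):
    """rho for each (phase frequency, amplitude frequency, location).

    Phases and amplitudes come from the cube's wavelet decomposition at the
    nearest grid frequencies (a warning is issued for off-grid requests);
    samples are concatenated over trials within the analysis window,
    dropping edge-flagged samples.  Returns (rho[n_phase, n_amp, n_loc],
    phase grid freqs, amplitude grid freqs).
    """
    import warnings

    if cube.phase is None:
        raise ValueError("cube must carry phase information for PAC")
    freqs = cube.freqs
    t = cube.times
    tsel = (t >= window[0]) & (t <= window[1])
    p_idx = []
    for f in phase_freqs:
        k = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[k] - f) / f > 0.05:
            warnings.warn(f"phase frequency {f} Hz off-grid; using {freqs[k]:.3f} Hz")
        p_idx.append(k)
    a_idx = np.flatnonzero((freqs >= amp_band[0]) & (freqs <= amp_band[1]))
    locations = np.asarray(locations, dtype=int)
    rho = np.zeros((len(p_idx), a_idx.size, locations.size))
    for li, loc in enumerate(locations):
        for pi, pk in enumerate(p_idx):
            keep = tsel.copy()
            if drop_edges and cube.edge_mask is not None:
                keep &= ~cube.edge_mask[pk]
            ph = cube.phase[:, loc, pk, :][:, keep].ravel()
            for ai, ak in enumerate(a_idx):
                amp = np.sqrt(cube.power[:, loc, ak, :][:, keep]).ravel()
                rho[pi, ai, li] = pac_rho(ph, amp, freqs[pk], freqs[ak]).rho
    return rho, freqs[p_idx], freqs[a_idx]


def cluster_vs_wholebrain(rho_maps: np.ndarray, cluster, q: float = 0.05):
    """Cluster-mean vs whole-brain-mean rho with paired group inference.

    ``rho_maps``: [subject, amp_freq, location]; ``cluster``: vertex indices.
    Returns dict with cluster/global mean curves, per-frequency paired
    t-tests and the Storey-FDR significance mask of the cluster excess.
    """
    from scipy import stats

    from .decoding import storey_fdr

    rho_maps = np.asarray(rho_maps, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("empty cluster")
    n_loc = rho_maps.shape[2]
    if cluster.max() >= n_loc:
        raise ValueError("cluster indices outside the grid")
    in_cluster = rho_maps[:, :, cluster].mean(axis=2)
    global_mean = rho_maps.mean(axis=2)
    if cluster.size == n_loc:
        t = np.zeros(rho_maps.shape[1])
        p = np.ones(rho_maps.shape[1])
    else:
        t, p = stats.ttest_rel(in_cluster, global_mean, axis=0)
    qv, mask = storey_fdr(np.where(np.isfinite(p), p, 1.0), q=q)
    return {
        "cluster_mean": in_cluster.mean(axis=0),
        "global_mean": global_mean.mean(axis=0),
        "t": t,
        "p": p,
        "q_values": qv,
        "mask": mask & (in_cluster.mean(axis=0) > global_mean.mean(axis=0)),
    }
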