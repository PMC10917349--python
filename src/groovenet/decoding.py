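"""Cross-validated ridge decoding of stimulus/experience regressors.

The decoder regresses a stimulus characteristic X on z-scored multichannel
power features Z in a ridge sense, w = (Z'Z + aI)^-1 Z'X with a = 2, using
10 interleaved cross-validation folds (trial i -> fold i mod 10).  Decoding
quality is the "coding precision": the Fisher z-transform atanh(r) of the
Pearson correlation between cross-validated predictions and the true
regressor.  Searchlight (a vertex and its 50 nearest neighbours) and ROI
(20-vertex) variants operate on source-level features; group-level inference
uses t-tests with Storey's FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CodingPrecisionMap",
    "ridge_weights",
    "crossval_decode",
    "coding_precision",
    "searchlight_decode",
    "roi_decode",
    "contrast_precision",
    "storey_fdr",
    "group_test",
]

R_CAP = 0.999999


@dataclass
class CodingPrecisionMap:
    """Fisher-z coding precision per analysis unit per subject."""

    precision: np.ndarray     # [subject, unit]
    units: np.ndarray         # unit labels (frequencies, vertex ids, ...)
    q_values: np.ndarray | None = None
    mask: np.ndarray | None = None

    @property
    def group_mean(self) -> np.ndarray:
        return self.precision.mean(axis=0)


def ridge_weights(Z_train: np.ndarray, X_train: np.ndarray, alpha: float = 2.0) -> np.ndarray:
    """Ridge normal-equations solution w = (Z'Z + alpha*I)^-1 Z'X.

    For p > n the algebraically identical dual form
    w = Z'(ZZ' + alpha*I_n)^-1 X is solved instead.
    """
    Z = np.asarray(Z_train, dtype=float)
    X = np.asarray(X_train, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n, p = Z.shape
    try:
        if p <= n:
            w = np.linalg.solve(Z.T @ Z + alpha * np.eye(p), Z.T @ X)
        else:
            w = Z.T @ np.linalg.solve(Z @ Z.T + alpha * np.eye(n), X)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular ridge system; use alpha > 0 with collinear features"
        ) from exc
    return w


def _interleaved_folds(n_rows: int, n_folds: int) -> list[np.ndarray]:
    return [np.arange(f, n_rows, n_folds) for f in range(n_folds)]


def crossval_decode(
    Z: np.ndarray,
    X: np.ndarray,
    n_folds: int = 10,
    alpha: float = 2.0,
) -> np.ndarray:
    """Interleaved k-fold ridge decoding; every row predicted exactly once.

    Feature standardization statistics (mean, sd) are estimated on each
    training partition only and applied to the held-out rows, preventing
    train/test leakage.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    if Z.ndim != 2 or X.shape[0] != Z.shape[0]:
        raise ValueError("Z must be [rows, features] matching X")
    if Z.shape[0] < n_folds:
        raise ValueError("fewer rows than folds")
    pred = np.empty(Z.shape[0])
    for test_idx in _interleaved_folds(Z.shape[0], n_folds):
        train_idx = np.setdiff1d(np.arange(Z.shape[0]), test_idx)
        if train_idx.size < 2:
            raise ValueError("fold with fewer than 2 training rows")
        mu = Z[train_idx].mean(axis=0)
        sd = Z[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        w = ridge_weights((Z[train_idx] - mu) / sd, X[train_idx], alpha)
        pred[test_idx] = (Z[test_idx] - mu) / sd @ w
    return pred


def coding_precision(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fisher z-transform of the Pearson correlation, capped near |r| = 1."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 exemplars")
    if np.ptp(truth) == 0:
        raise ValueError("constant truth regressor")
    if np.std(pred) == 0:
        return 0.0
    r = float(np.corrcoef(pred, truth)[0, 1])
    r = np.clip(r, -R_CAP, R_CAP)
    return float(np.arctanh(r))


def decode_spectrum(
    power: np.ndarray,
    regressor: np.ndarray,
    n_folds: int = 10,
    alpha: float = 2.0,
) -> np.ndarray:
    """Per-frequency coding precision from [trial, channel, freq] power."""
    n_freq = power.shape[2]
    return np.array(
        [
            coding_precision(crossval_decode(power[:, :, k], regressor, n_folds, alpha), regressor)
            for k in range(n_freq)
        ]
    )


def searchlight_decode(
    power: np.ndarray,
    grid,
    regressor: np.ndarray,
    freqs: np.ndarray,
    n_neighbors: int = 50,
    band: tuple | None = None,
    n_folds: int = 10,
    alpha: float = 2.0,
) -> np.ndarray:
    """Per-vertex coding precision from local neighbourhood power spectra.

    ``power``: [trial, vertex, freq].  Features for vertex v are the (band-
    restricted) spectra of v and its ``n_neighbors`` nearest neighbours.
    """
    if grid.n_vertices < n_neighbors + 1:
        raise ValueError("fewer vertices than the searchlight requires")
    if power.shape[1] != grid.n_vertices:
        raise ValueError("power location axis does not match the source grid")
    fsel = np.arange(freqs.size)
    if band is not None:
        fsel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
        if fsel.size == 0:
            raise ValueError("band excludes every analysis frequency")
    out = np.empty(grid.n_vertices)
    for v in range(grid.n_vertices):
        hood = np.concatenate([[v], grid.neighbors(v, n_neighbors)])
        feats = power[:, hood][:, :, fsel].reshape(power.shape[0], -1)
        out[v] = coding_precision(
            crossval_decode(feats, regressor, n_folds, alpha), regressor
        )
    return out


def roi_decode(
    contrast_map: np.ndarray,
    grid,
    power: np.ndarray,
    regressor: np.ndarray,
    freqs: np.ndarray,
    n_rois: int = 5,
    n_vertices: int = 20,
    n_folds: int = 10,
    alpha: float = 2.0,
):
    """Per-frequency decoding within ROIs centred on contrast-map peaks.

    Each ROI is a peak vertex of |contrast_map| plus its ``n_vertices - 1``
    nearest neighbours; successive peaks exclude vertices already assigned.
    Returns (rois, spectra) with ``spectra`` [roi, freq] coding precision.
    """
    if n_rois * n_vertices > grid.n_vertices:
        raise ValueError("requested ROIs exceed the available vertex count")
    taken = np.zeros(grid.n_vertices, dtype=bool)
    score = np.abs(np.asarray(contrast_map, dtype=float))
    rois = []
    for _ in range(n_rois):
        order = np.argsort(-score)
        peak = next(v for v in order if not taken[v])
        hood = np.concatenate([[peak], grid.neighbors(peak, grid.n_vertices - 1)])
        hood = [v for v in hood if not taken[v]][:n_vertices]
        if len(hood) < n_vertices:
            raise ValueError("overlapping ROI request beyond vertex count")
        taken[hood] = True
        rois.append(np.asarray(hood))
    spectra = np.stack(
        [
            decode_spectrum(power[:, roi, :], regressor, n_folds, alpha)
            for roi in rois
        ]
    )
    return rois, spectra


def contrast_precision(map_a: np.ndarray, map_b: np.ndarray):
    """Paired per-unit difference of Fisher-z precisions with group t-test.

    ``map_a``/``map_b``: [subject, unit].  Returns (difference group mean,
    t-values, p-values); units where every subject difference is zero yield
    NaN p-values (flagged by the caller).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("subject/unit mismatch between the two maps")
    diff = a - b
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(a, b, axis=0)
    return diff.mean(axis=0), t, p


def group_test(precision: np.ndarray):
    """Two-tailed one-sample t-test of Fisher-z precisions against zero."""
    t, p = stats.ttest_1samp(np.asarray(precision, dtype=float), 0.0, axis=0)
    return t, p


def storey_fdr(p_values: np.ndarray, q: float = 0.05, lambdas=None):
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is evaluated on a lambda
    grid (default 0.05..0.95 step 0.05), smoothed with a cubic polynomial and
    read out at the largest lambda; q-values are the monotone step-up
    transform of pi0 * n * p_(i) / i.  Returns (q_values, mask) with
    ``mask = q_values <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    finite = np.isfinite(p)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("no finite p-values")
    pf = p[finite]
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(pf > lam).sum() / (n * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.clip(np.polyval(coef, lambdas.max()), 1.0 / n, 1.0))
    order = np.argsort(pf)
    ranked = pf[order]
    qv = pi0 * n * ranked / np.arange(1, n + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    q_full = np.full(p.shape, np.nan)
    qf = np.empty(n)
    qf[order] = np.clip(qv, 0, 1)
    q_full[finite] = qf
    mask = np.zeros(p.shape, dtype=bool)
    mask[finite] = q_full[finite] <= q
    return q_full, mask
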