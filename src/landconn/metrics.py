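"""Accuracy statistics comparing a model prediction with simulated truth.

Both surfaces are min–max normalised to [0, 1] before comparison, which
removes each model's arbitrary output scale (path counts, kernel sums,
current). Three statistics are reported: per-pixel RMSE (bounded by 1 after
normalisation), the Pearson correlation over all pixels, and the spatial
overlap of the top-q highest-connectivity areas (fraction of the K = floor(qN)
top-ranked pixels shared by truth and prediction).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class StatTriple(NamedTuple):
    rmse: float
    pearson: float
    overlap: float


def normalize01(surface: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; constant surfaces map to all zeros."""
    surface = np.asarray(surface, dtype=float)
    lo, hi = surface.min(), surface.max()
    if hi == lo:
        return np.zeros_like(surface)
    return (surface - lo) / (hi - lo)


def _top_k_indices(values: np.ndarray, k: int) -> np.ndarray:
    """Flat indices of the k highest values; ties broken by lower pixel index."""
    order = np.argsort(-values.ravel(), kind="stable")
    return order[:k]


def compare(truth: np.ndarray, pred: np.ndarray, q: float = 0.1) -> StatTriple:
    """Score a prediction against a simulated density surface.

    Returns (rmse, pearson, overlap); identical inputs give (0, 1, 1).
    ``q`` is the top fraction used for the overlap statistic.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    t = normalize01(truth)
    p = normalize01(pred)
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))

    ts, ps = t.std(), p.std()
    if ts == 0.0 or ps == 0.0:
        # correlation undefined for a constant input: 1 for an exact match
        # after normalisation, else 0
        pearson = 1.0 if np.array_equal(t, p) else 0.0
    else:
        pearson = float(np.corrcoef(t.ravel(), p.ravel())[0, 1])

    k = int(np.floor(q * truth.size))
    if k < 1:
        raise ValueError("q too small: top-K set is empty")
    top_t = _top_k_indices(t, k)
    top_p = _top_k_indices(p, k)
    overlap = float(np.intersect1d(top_t, top_p).size / k)
    return StatTriple(rmse=rmse, pearson=pearson, overlap=overlap)
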