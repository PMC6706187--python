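"""Shared covariance/correlation PCA with a deterministic sign convention."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    """Principal components of a samples x variables matrix.

    ``eigen_pct`` is the percentage of total variance per axis (non-increasing,
    summing to 100 over all returned axes); ``scores @ loadings.T + mean``
    reconstructs the input.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigen_pct: np.ndarray
    mean: pd.Series
    scale: pd.Series | None = None

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def principal_components(X: pd.DataFrame, standardize: bool = False) -> PcaResult:
    """Covariance-matrix PCA (or correlation-matrix PCA with ``standardize``).

    Columns are centered (and unit-scaled if requested), decomposed by SVD,
    and each axis is sign-fixed so that its largest-magnitude loading is
    positive, making results reproducible across platforms.
    """
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if (scale == 0).any():
            bad = scale.index[scale == 0].tolist()
            raise ValueError(f"constant variable(s): {bad}")
        Xc = Xc / scale
    U, s, Vt = np.linalg.svd(Xc.values, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per axis
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    eigen_pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    axes = [f"PC{j + 1}" for j in range(len(s))]
    scores = pd.DataFrame(U * s, index=X.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=axes)
    return PcaResult(scores=scores, loadings=loadings, eigen_pct=eigen_pct,
                     mean=mean, scale=scale)
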