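"""Distance-based statistics for compositional and spatial data.

Bray-Curtis dissimilarities, one-way PERMANOVA with seeded permutations,
the tiny-jitter fix for substance classes absent from several samples (a
PERMANOVA cannot handle pairs at exactly zero distance), Mantel tests, and
plain-degree geographic distances.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(ids=list(df.index.astype(str)), data=df.values)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(pos, pos)])


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between non-negative abundance rows.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1].
    """
    X = table.values.astype(float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    zero_rows = table.index[X.sum(axis=1) == 0].tolist()
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero rows: {zero_rows}"
        )
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(list(table.index), d)


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F with a whole-row permutation test.

    pseudo-F = ((SS_total - SS_within)/(g-1)) / (SS_within/(n-g)) on squared
    distances; p uses the add-one convention (1 + #{F* >= F}) / (n_perm + 1).
    """
    labels = pd.Series(list(groups))
    codes, uniques = pd.factorize(labels)
    g = len(uniques)
    n = d.n
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if len(labels) != n:
        raise ValueError("group labels do not match distance matrix")
    if n - g <= 0:
        raise ValueError("no residual degrees of freedom (n - g <= 0)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d.data**2

    def _f(ss_t: float, ss_w: float) -> float:
        if ss_w == 0:
            return np.inf
        return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))

    f_obs = _f(*_permanova_ss(d2, codes, g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _f(*_permanova_ss(d2, perm, g)) >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(f_obs), float(p)


def jitter_zero_classes(
    class_table: pd.DataFrame,
    classes: Sequence[str] | None = None,
    mean: float = 1e-8,
    sd: float = 1e-8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Add minute seeded Gaussian noise to classes absent from several samples.

    PERMANOVA breaks on pairs at exactly zero distance; adding N(mean, sd)
    draws (truncated at zero) to the affected class columns for all samples
    removes ties without perturbing the analysis. When ``classes`` is None,
    columns that are zero in two or more samples are jittered.
    """
    out = class_table.copy()
    if classes is None:
        classes = [c for c in out.columns if (out[c] == 0).sum() >= 2]
    if not len(classes):
        return out
    rng = np.random.default_rng(seed)
    for c in classes:
        noise = np.clip(rng.normal(mean, sd, size=len(out)), 0.0, None)
        out[c] = out[c] + noise
    return out


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of distance matrices.

    r is computed over strictly-lower-triangle entries; the one-sided
    ("greater") p permutes rows and columns of ``d2`` jointly, with the
    add-one convention.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices have mismatching ids")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    il = np.tril_indices(n, -1)
    v1 = d1.data[il]
    if v1.std() == 0 or d2.data[il].std() == 0:
        raise ValueError("zero variance in a distance matrix")
    v1 = (v1 - v1.mean()) / v1.std()

    def corr(mat: np.ndarray) -> float:
        v2 = mat[il]
        v2 = (v2 - v2.mean()) / v2.std()
        return float((v1 * v2).mean())

    r_obs = corr(d2.data)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.data[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def geo_distance(
    coords: pd.DataFrame,
    method: str = "euclidean_degrees",
) -> DistanceMatrix:
    """Distances between GPS points (columns ``lon`` and ``lat``).

    The default is the plain Euclidean distance in degree space (the
    convention used for the isolation-by-distance tests this package
    reproduces); ``method="great_circle"`` gives haversine kilometres.
    """
    if coords[["lon", "lat"]].isna().any().any():
        bad = coords.index[coords[["lon", "lat"]].isna().any(axis=1)].tolist()
        raise ValueError(f"missing coordinates for: {bad}")
    ids = list(coords.index.astype(str))
    if method == "euclidean_degrees":
        d = squareform(pdist(coords[["lon", "lat"]].values, metric="euclidean"))
    elif method == "great_circle":
        lon = np.radians(coords["lon"].values)
        lat = np.radians(coords["lat"].values)
        dlon = lon[:, None] - lon[None, :]
        dlat = lat[:, None] - lat[None, :]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
        )
        d = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(ids, d)
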