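"""Multivariate ratio analysis (MRA) of linear body measurements.

Separates isometric size (the geometric mean of an individual's
measurements) from shape: log-measurements are projected onto the
orthocomplement of the isometric direction u = (1,...,1)/sqrt(p) and a
covariance PCA of the projected data yields shape axes that are exactly
invariant to isometric rescaling of any individual. The PCA ratio spectrum
reads a shape axis as a ratio of its two extreme-loading measurements.
Reliability screening (one-way ICC over repeated measurements), a
sequential two-factor MANOVA on shape scores (Pillai's trace) and Welch t
tests on size complete the toolkit.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._pca import principal_components

__all__ = [
    "MorphTable",
    "ShapeSpace",
    "icc_reliability",
    "isometric_size",
    "shape_pca",
    "pca_ratio_spectrum",
    "two_group_manova",
    "welch_t",
]


class MorphTable:
    """Individuals x measurements, optionally with technical repeats.

    Built from a long-format table with columns ``individual``, ``repeat``,
    ``variable``, ``value`` plus per-individual ``species`` and ``location``
    labels. All values must be positive (logs are taken downstream).
    """

    def __init__(self, long: pd.DataFrame) -> None:
        required = {"individual", "repeat", "variable", "value"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (long["value"] <= 0).any():
            bad = long.loc[long["value"] <= 0].iloc[0]
            raise ValueError(
                f"non-positive measurement: individual {bad['individual']!r}, "
                f"variable {bad['variable']!r}"
            )
        self.long = long.copy()

    # ---- views -------------------------------------------------------
    def values(self) -> pd.DataFrame:
        """Individuals x variables, repeats averaged."""
        wide = self.long.pivot_table(
            index="individual", columns="variable", values="value", aggfunc="mean",
            sort=False,
        )
        return wide[sorted(wide.columns, key=list(self.variables).index)]

    @property
    def variables(self) -> list[str]:
        return list(pd.unique(self.long["variable"]))

    @property
    def n_repeats(self) -> int:
        return int(self.long.groupby(["individual", "variable"])["repeat"].count().max())

    def labels(self, column: str) -> pd.Series:
        if column not in self.long.columns:
            raise ValueError(f"no label column {column!r}")
        lab = self.long.drop_duplicates("individual").set_index("individual")[column]
        return lab.loc[self.values().index]

    def drop_variables(self, variables: Sequence[str]) -> "MorphTable":
        keep = ~self.long["variable"].isin(set(variables))
        return MorphTable(self.long.loc[keep])

    # ---- I/O ---------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.long.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "MorphTable":
        return cls(pd.read_csv(path))


def icc_reliability(
    mt: MorphTable, threshold: float = 0.85
) -> tuple[pd.DataFrame, MorphTable]:
    """One-way random-effects ICC(1,1) per variable; screen out < threshold.

    ICC = (MS_between - MS_within) / (MS_between + (k-1) MS_within) with k
    repeats per individual. Returns the per-variable report (icc, keep flag)
    and the table restricted to reliable variables (repeats then averaged by
    downstream consumers).
    """
    rows = []
    for var, sub in mt.long.groupby("variable", sort=False):
        pivot = sub.pivot_table(index="individual", columns="repeat", values="value")
        pivot = pivot.dropna()
        k = pivot.shape[1]
        n = pivot.shape[0]
        if k < 2 or n < 2:
            raise ValueError(f"variable {var!r}: need >= 2 repeats for >= 2 individuals")
        vals = pivot.values
        grand = vals.mean()
        if np.allclose(vals, grand):
            raise ValueError(f"variable {var!r} has zero total variance")
        ms_between = k * ((vals.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_within = ((vals - vals.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
        rows.append({"variable": var, "icc": icc, "keep": icc >= threshold})
    report = pd.DataFrame(rows)
    dropped = report.loc[~report["keep"], "variable"].tolist()
    return report, mt.drop_variables(dropped)


def isometric_size(values: pd.DataFrame) -> pd.Series:
    """Geometric mean of each individual's measurements."""
    if (values.values <= 0).any():
        raise ValueError("isometric size requires positive measurements")
    return pd.Series(
        np.exp(np.log(values.values).mean(axis=1)), index=values.index, name="iso_size"
    )


@dataclass
class ShapeSpace:
    """Isometric size plus the size-free shape PCA of log measurements."""

    iso_size: pd.Series
    log_iso: pd.Series
    shape_scores: pd.DataFrame
    shape_loadings: pd.DataFrame
    eigen_pct: np.ndarray
    mean_log_projected: pd.Series

    @property
    def variables(self) -> list[str]:
        return list(self.shape_loadings.index)


def shape_pca(values: pd.DataFrame) -> ShapeSpace:
    """Shape PCA: covariance PCA of logs projected off the isometric axis.

    Multiplying any individual's measurements by a positive constant moves it
    only along u = (1,...,1)/sqrt(p), so its shape scores are unchanged.
    """
    n, p = values.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 individuals")
    if p < 2:
        raise ValueError("shape PCA needs at least 2 variables")
    L = np.log(values.values.astype(float))
    u = np.ones(p) / np.sqrt(p)
    iso_coord = L @ u  # = sqrt(p) * mean(log x) per row
    Lp = L - np.outer(iso_coord, u)
    proj = pd.DataFrame(Lp, index=values.index, columns=values.columns)
    pca = principal_components(proj, standardize=False)
    return ShapeSpace(
        iso_size=pd.Series(np.exp(iso_coord / np.sqrt(p)), index=values.index,
                           name="iso_size"),
        log_iso=pd.Series(iso_coord / np.sqrt(p), index=values.index, name="log_iso"),
        shape_scores=pca.scores,
        shape_loadings=pca.loadings,
        eigen_pct=pca.eigen_pct,
        mean_log_projected=pca.mean,
    )


def pca_ratio_spectrum(
    shape: ShapeSpace,
    values: pd.DataFrame,
    axis: int = 0,
    n_boot: int = 1000,
    conf: float = 0.68,
    seed: int | None = None,
) -> pd.DataFrame:
    """Order variables by loading on a shape axis, with bootstrap CIs.

    The ratio of the two extreme variables is the axis's best single-ratio
    reading. Rows (individuals) are resampled, the shape PCA refit, and each
    replicate's loading vector sign-aligned (dot product with the original)
    before percentile intervals are taken. ``n_boot=0`` gives point
    estimates only.
    """
    if not 0 <= axis < shape.shape_loadings.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    col = shape.shape_loadings.columns[axis]
    point = shape.shape_loadings[col]
    out = pd.DataFrame({"loading": point})
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = values.shape[0]
        boots = np.empty((n_boot, values.shape[1]))
        ref = point.values
        b = 0
        attempts = 0
        while b < n_boot:
            attempts += 1
            if attempts > 20 * n_boot:  # pragma: no cover - pathological data
                raise RuntimeError("bootstrap failed to produce valid replicates")
            idx = rng.integers(0, n, size=n)
            sub = values.iloc[idx]
            if sub.shape[0] < 3 or len(np.unique(idx)) < 3:
                continue
            try:
                rep = shape_pca(sub)
            except ValueError:
                continue
            vec = rep.shape_loadings.iloc[:, axis].values
            if vec @ ref < 0:
                vec = -vec
            boots[b] = vec
            b += 1
        alpha = (1.0 - conf) / 2.0
        out["ci_low"] = np.quantile(boots, alpha, axis=0)
        out["ci_high"] = np.quantile(boots, 1 - alpha, axis=0)
    out = out.sort_values("loading", ascending=False)
    out.index.name = "variable"
    return out


def _design(labels: pd.Series) -> np.ndarray:
    codes, uniq = pd.factorize(labels)
    cols = [np.asarray(codes == lvl, dtype=float) for lvl in range(1, len(uniq))]
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def _resid_sscp(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R, int(np.linalg.matrix_rank(X))


def _pillai_f(H: np.ndarray, E: np.ndarray, q: int, df_res: int) -> tuple[float, float, int, int, float]:
    m = H.shape[0]
    eigvals = np.linalg.eigvals(np.linalg.solve(E + H, H)).real
    V = float(np.clip(eigvals, 0, 1).sum())
    s = min(q, m)
    mm = (abs(q - m) - 1) / 2.0
    nn = (df_res - m - 1) / 2.0
    df1 = int(s * (2 * mm + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    F = (df2 / df1) * (V / (s - V)) if s > V else np.inf
    p = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, df2, p


def two_group_manova(
    scores: pd.DataFrame,
    species: pd.Series | Sequence[str],
    location: pd.Series | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Additive two-factor MANOVA with sequential (type-I) sums of squares.

    Species is entered first, then sampling location. Pillai's trace with
    the standard F approximation; the residual SSCP of the full additive
    model is the error term for every factor. Returns one row per factor
    with (pillai, F, df1, df2, p).
    """
    Y = scores.values.astype(float)
    n = Y.shape[0]
    species = pd.Series(list(species))
    blocks: list[tuple[str, np.ndarray]] = [("species", _design(species))]
    if location is not None:
        blocks.append(("location", _design(pd.Series(list(location)))))
    for name, block in blocks:
        if block.shape[1] == 0:
            raise ValueError(f"factor {name!r} has a single level")
    X = np.ones((n, 1))
    E_prev, rank_prev = _resid_sscp(Y, X)
    seq: list[tuple[str, np.ndarray, int]] = []
    for name, block in blocks:
        X = np.column_stack([X, block])
        E_cur, rank_cur = _resid_sscp(Y, X)
        q = rank_cur - rank_prev
        if q == 0:
            raise ValueError(f"factor {name!r} adds no rank (confounded design)")
        seq.append((name, E_prev - E_cur, q))
        E_prev, rank_prev = E_cur, rank_cur
    E = E_prev
    df_res = n - rank_prev
    if df_res <= 0 or np.linalg.matrix_rank(E) < Y.shape[1]:
        raise ValueError("rank-deficient design or residual SSCP")
    rows = []
    for name, H, q in seq:
        V, F, df1, df2, p = _pillai_f(H, E, q, df_res)
        rows.append({"factor": name, "pillai": V, "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows).set_index("factor")


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test (Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
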