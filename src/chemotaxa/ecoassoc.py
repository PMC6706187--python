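"""Partner-association and environmental-association models.

A Yates-corrected chi-squared test for the 2x2 partner co-occurrence
table; a correlation-matrix PCA reducing the 19 climate variables to a few
gradients; binomial (logit) GLMs for species occurrence with explicit term
bookkeeping; backward stepwise reduction by AIC honouring interaction
hierarchy; and analysis-of-deviance chi-squared tests for single terms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._pca import PcaResult, principal_components

__all__ = [
    "contingency_chisq",
    "climate_pca",
    "GlmFit",
    "fit_binomial_glm",
    "stepwise_aic",
    "deviance_term_test",
]


def contingency_chisq(
    table: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame,
    correction: bool = True,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    Yates continuity correction is applied by default for 2x2 tables (the
    convention matching reported partner-association statistics). Returns
    (chi2, df, p).
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    use_corr = correction and arr.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=use_corr)
    return float(chi2), int(dof), float(p)


def climate_pca(env: pd.DataFrame, columns: Sequence[str] | None = None) -> PcaResult:
    """Correlation-matrix PCA of the climate variables.

    Variables are standardized because they mix incommensurate units (mm,
    tenths of °C). ``columns`` defaults to every column starting with
    ``bio``.
    """
    if columns is None:
        columns = [c for c in env.columns if c.startswith("bio")]
    if not columns:
        raise ValueError("no climate columns found")
    X = env[list(columns)]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in climate columns: {bad}")
    return principal_components(X, standardize=True)


def _interaction_parts(term: str) -> list[str]:
    return term.split(":")


def _build_columns(term: str, data: pd.DataFrame) -> pd.DataFrame:
    """Design columns for one term (treatment coding for categoricals)."""
    parts = _interaction_parts(term)
    pieces: list[pd.DataFrame] = []
    for p in parts:
        if p not in data.columns:
            raise ValueError(f"unknown covariate {p!r}")
        col = data[p]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=p, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).to_frame(p))
    out = pieces[0]
    for nxt in pieces[1:]:
        combined = {}
        for a in out.columns:
            for b in nxt.columns:
                combined[f"{a}:{b}"] = out[a] * nxt[b]
        out = pd.DataFrame(combined, index=data.index)
    return out


@dataclass
class GlmFit:
    """A fitted binomial GLM with term-level bookkeeping."""

    terms: list[str]
    data: pd.DataFrame
    y: pd.Series
    design: pd.DataFrame
    term_columns: dict[str, list[str]]
    result: object  # statsmodels GLMResults
    separation: bool

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    @property
    def standard_errors(self) -> pd.Series:
        return self.result.bse

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    @property
    def df_model(self) -> int:
        return int(self.design.shape[1])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.result.params, "se": self.result.bse,
             "z": self.result.tvalues, "p": self.result.pvalues}
        )


def fit_binomial_glm(
    y: pd.Series | Sequence[int],
    data: pd.DataFrame,
    terms: Sequence[str],
) -> GlmFit:
    """Binomial GLM with logit link, fitted by IRLS.

    ``terms`` name columns of ``data``; ``"a:b"`` denotes an interaction
    (categorical covariates are treatment-coded). Quasi-separation is
    detected from runaway coefficients and flagged rather than raised.
    """
    y = pd.Series(np.asarray(y), index=data.index).astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary (0/1)")
    design = pd.DataFrame(index=data.index)
    design["Intercept"] = 1.0
    term_columns: dict[str, list[str]] = {}
    for t in terms:
        block = _build_columns(t, data)
        for c in block.columns:
            design[c] = block[c]
        term_columns[t] = list(block.columns)
    if design.shape[0] <= design.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        raise ValueError("collinear design matrix")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10)
    separation = bool(
        np.any(np.abs(res.params.values) > 15.0)
        or not np.all(np.isfinite(res.bse.values))
        or res.deviance < 1e-8
    )
    return GlmFit(
        terms=list(terms),
        data=data,
        y=y,
        design=design,
        term_columns=term_columns,
        result=res,
        separation=separation,
    )


def _droppable(terms: list[str]) -> list[str]:
    """Terms not protected by a remaining higher-order interaction."""
    out = []
    for t in terms:
        protected = any(
            t != other and t in _interaction_parts(other) for other in terms
        )
        if not protected:
            out.append(t)
    return out


def stepwise_aic(fit: GlmFit, trace: list | None = None) -> GlmFit:
    """Backward stepwise reduction: drop terms while AIC decreases.

    At each step the single eligible term whose removal lowers AIC the most
    is dropped (interactions before their main effects; a main effect is
    never removed while its interaction remains). Ties break by term order.
    """
    current = fit
    while True:
        candidates = _droppable(current.terms)
        best: GlmFit | None = None
        best_term: str | None = None
        for t in candidates:
            reduced_terms = [x for x in current.terms if x != t]
            reduced = fit_binomial_glm(current.y, current.data, reduced_terms)
            if reduced.aic < current.aic - 1e-12 and (
                best is None or reduced.aic < best.aic - 1e-12
            ):
                best = reduced
                best_term = t
        if best is None:
            return current
        if trace is not None:
            trace.append(
                {"dropped": best_term, "aic_before": current.aic, "aic_after": best.aic}
            )
        current = best


def deviance_term_test(full: GlmFit, reduced: GlmFit) -> tuple[float, int, float]:
    """Analysis-of-deviance chi-squared test between nested binomial GLMs."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not in full)")
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    chi2 = reduced.deviance - full.deviance
    if df == 0:
        return float(chi2), 0, 1.0
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p
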