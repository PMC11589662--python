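"""PCA and PC-weighted divergence statistics.

Morphological and climatic divergence between two units (clades or
populations) is measured on the principal components of the trait matrix:
with x_k and y_k the unit scores on PC k, z_k the percentage of variance
that PC explains, and m the number of leading PCs cumulatively explaining
at least 99% of the variance,

    divergence = (1/m) * sum_{k=1..m} |x_k - y_k| * z_k

The per-PC differences are taken in absolute value (a signed sum would make
the statistic depend on arbitrary PC orientations), and z is kept on the
0-100 scale. PCA is covariance-based by default; pass ``scale=True`` for a
correlation-matrix analysis.

The module also houses the genotype-space ordination used for species
delimitation (mean-imputed allele counts) and its missingness diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitMatrix",
    "PCModel",
    "DivergenceValue",
    "run_pca",
    "retain_pcs",
    "pc_weighted_divergence",
    "average_climate_by_unit",
    "genotype_pca",
    "missingness_pc_correlation",
    "delimit_by_ordination",
]


@dataclass
class TraitMatrix:
    """Units (clades/populations/localities) x continuous variables."""

    units: list
    variables: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.units), len(self.variables)):
            raise ValueError("values shape inconsistent with unit/variable lists")
        if np.isnan(self.values).any():
            raise ValueError("TraitMatrix must not contain missing values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(df.index.tolist(), df.columns.tolist(), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.units, columns=self.variables)


@dataclass
class PCModel:
    units: list
    loadings: np.ndarray  # variables x components
    eigenvalues: np.ndarray  # covariance/correlation eigenvalues, descending
    explained_pct: np.ndarray  # z_k, percent, sums to 100
    scores: np.ndarray  # units x components
    n_retained: int  # PCs cumulatively explaining >= 99% variance

    def score_of(self, unit) -> np.ndarray:
        try:
            return self.scores[self.units.index(unit)]
        except ValueError as exc:
            raise KeyError(f"unknown unit {unit!r}") from exc


def run_pca(t: TraitMatrix, scale: bool = False, cum_threshold: float = 99.0) -> PCModel:
    """Principal component analysis of a trait matrix.

    Columns are centred (and scaled to unit variance when ``scale``); the
    decomposition is the SVD of the centred data, equivalent to an
    eigendecomposition of the covariance (or correlation) matrix. Variance
    percentages come from the eigenvalues; a zero-variance variable under
    ``scale=True`` is an error naming the variable.
    """
    if len(t.units) < 2:
        raise ValueError("PCA requires at least two units")
    X = t.values - t.values.mean(axis=0)
    if scale:
        sd = t.values.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [t.variables[i] for i in zero]
            raise ValueError(f"zero-variance variables cannot be scaled: {names}")
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (len(t.units) - 1)
    total = eigvals.sum()
    z = 100.0 * eigvals / total if total > 0 else np.full_like(eigvals, np.nan)
    loadings = vt.T
    scores = X @ loadings
    model = PCModel(list(t.units), loadings, eigvals, z, scores, n_retained=0)
    model.n_retained = retain_pcs(model, cum_threshold)
    return model


def retain_pcs(model: PCModel, cum_threshold: float = 99.0) -> int:
    """Smallest m whose leading PCs cumulatively explain >= ``cum_threshold``%."""
    cum = np.cumsum(model.explained_pct)
    # tolerance so an exact boundary (e.g. z = (99, 1)) is inclusive in float
    reached = cum >= cum_threshold - 1e-9
    return int(np.argmax(reached)) + 1 if reached.any() else len(cum)


@dataclass
class DivergenceValue:
    pair_id: object
    value: float
    n_pcs_used: int


def pc_weighted_divergence(
    model: PCModel, unit_a, unit_b, n_pcs: int | None = None, pair_id=None
) -> DivergenceValue:
    """Variance-weighted mean absolute PC-score difference between two units."""
    m = n_pcs if n_pcs is not None else model.n_retained
    x = model.score_of(unit_a)[:m]
    y = model.score_of(unit_b)[:m]
    z = model.explained_pct[:m]
    value = float(np.sum(np.abs(x - y) * z) / m)
    return DivergenceValue(pair_id=pair_id, value=value, n_pcs_used=m)


def average_climate_by_unit(climate: TraitMatrix, unit_of, units=None) -> TraitMatrix:
    """Average locality-level climate rows into unit-level rows.

    ``unit_of`` maps each locality (row of ``climate``) to its unit; units
    requested via ``units`` but having no localities raise an error.
    """
    unit_of = pd.Series(unit_of)
    df = climate.to_dataframe()
    assigned = unit_of.reindex(df.index)
    if assigned.isna().any():
        missing = df.index[assigned.isna()].tolist()
        raise ValueError(f"localities without a unit assignment: {missing}")
    means = df.groupby(assigned).mean()
    if units is not None:
        empty = [u for u in units if u not in means.index]
        if empty:
            raise ValueError(f"units with zero localities: {empty}")
        means = means.loc[list(units)]
    return TraitMatrix.from_dataframe(means)


def genotype_pca(g, scale: bool = False, cum_threshold: float = 99.0) -> PCModel:
    """PCA of the allele-count matrix with per-site mean imputation.

    Sites with every call missing are dropped (count logged) before
    imputation; with no missing data the result is identical to a direct
    PCA of the calls.
    """
    calls = np.asarray(g.calls, dtype=float)
    all_missing = np.isnan(calls).all(axis=0)
    if all_missing.any():
        logger.info("genotype_pca: dropped %d fully missing sites", all_missing.sum())
        calls = calls[:, ~all_missing]
    col_mean = np.nanmean(calls, axis=0)
    imputed = np.where(np.isnan(calls), col_mean[None, :], calls)
    t = TraitMatrix(list(g.samples), [f"site{j}" for j in range(imputed.shape[1])], imputed)
    return run_pca(t, scale=scale, cum_threshold=cum_threshold)


def missingness_pc_correlation(model: PCModel, missingness, n_pcs: int = 3) -> pd.DataFrame:
    """Spearman correlation of per-sample missingness with leading PC scores.

    Missing data can distort genotype ordinations, so each of the first
    ``n_pcs`` score vectors is rank-correlated against per-sample
    missingness. Degenerate (constant) inputs are flagged and reported as
    rho = 0, p = 1.
    """
    from .association import spearman

    miss = np.asarray(pd.Series(missingness).reindex(model.units)
                      if hasattr(missingness, "reindex") else missingness, dtype=float)
    if len(miss) != len(model.units):
        raise ValueError("missingness vector does not match model samples")
    rows = []
    for k in range(min(n_pcs, model.scores.shape[1])):
        res = spearman(model.scores[:, k], miss)
        rows.append((k + 1, res.rho, res.p, res.degenerate))
    return pd.DataFrame(rows, columns=["pc", "rho", "p", "degenerate"])


def delimit_by_ordination(model: PCModel, labels, group_a, group_b, n_pcs: int = 3) -> bool:
    """Ordination arm of the dual-criterion species delimitation.

    Two groups occupy distinct regions of genotype space iff every
    individual is strictly closer (Euclidean, first ``n_pcs`` PCs) to its
    own group centroid than to the other group's centroid -- a
    deterministic proxy for judging separation in a 3-PC score plot.
    """
    labels = pd.Series(labels)
    if hasattr(labels, "reindex") and not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.reindex(model.units)
    lab = np.asarray(labels)
    scores = model.scores[:, : min(n_pcs, model.scores.shape[1])]
    in_a, in_b = lab == group_a, lab == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups must be non-empty")
    cent_a = scores[in_a].mean(axis=0)
    cent_b = scores[in_b].mean(axis=0)
    for mask, own, other in ((in_a, cent_a, cent_b), (in_b, cent_b, cent_a)):
        d_own = np.linalg.norm(scores[mask] - own, axis=1)
        d_other = np.linalg.norm(scores[mask] - other, axis=1)
        if not np.all(d_own < d_other):
            return False
    return True
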