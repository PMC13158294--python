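"""Trait-gene PCA per genotype.

Assembles, for one genotype, a matrix whose rows are biological replicates
(across both treatments) and whose columns mix phenotypic traits with gene
fold changes, then runs a principal component analysis on the centred —
and by default unit-variance-scaled — matrix. Scaling defaults on because
the columns mix units (g/m2, enzyme activities, dimensionless fold
changes); with scaling the analysis is a correlation-matrix PCA.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from .design import PCA_DEFAULT_TRAITS

__all__ = ["assemble_matrix", "TraitGenePCA", "pca", "variance_explained", "PCAResult"]


def assemble_matrix(
    traits: pd.DataFrame,
    expression: pd.DataFrame,
    genotype: str,
    trait_list: tuple[str, ...] | list[str] | None = None,
    gene_list: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Observation matrix for one genotype: replicates x (traits + genes).

    Rows are (treatment, bio_rep) pairs; trait columns hold raw trait
    values and gene columns hold per-replicate fold changes. ``trait_list``
    defaults to the ten-trait multivariate panel; ``gene_list`` defaults to
    every gene in the expression table. A replicate present in one table
    but not the other raises. Zero-variance columns are dropped with a
    warning (they carry no information for correlation-based analysis).
    """
    if trait_list is None:
        trait_list = PCA_DEFAULT_TRAITS
    t = traits[traits["genotype"] == genotype]
    e = expression[expression["genotype"] == genotype]
    if t.empty and trait_list:
        raise ValueError(f"trait table does not cover genotype {genotype!r}")
    if e.empty and (gene_list is None or gene_list):
        raise ValueError(f"expression table does not cover genotype {genotype!r}")

    blocks = []
    if trait_list:
        missing = set(trait_list) - set(t["trait"].unique())
        if missing:
            raise ValueError(f"traits absent from the table: {sorted(missing)}")
        tw = t[t["trait"].isin(trait_list)].pivot_table(
            index=["treatment", "bio_rep"], columns="trait", values="value"
        )[list(trait_list)]
        blocks.append(tw)
    if gene_list is None:
        gene_list = tuple(e["gene"].unique())
    if gene_list:
        missing = set(gene_list) - set(e["gene"].unique())
        if missing:
            raise ValueError(f"genes absent from the expression table: {sorted(missing)}")
        ew = e[e["gene"].isin(gene_list)].pivot_table(
            index=["treatment", "bio_rep"], columns="gene", values="fold_change"
        )[list(gene_list)]
        blocks.append(ew)
    if not blocks:
        raise ValueError("no variables requested")
    if len(blocks) == 2 and not blocks[0].index.equals(blocks[1].index):
        only_t = set(blocks[0].index) - set(blocks[1].index)
        only_e = set(blocks[1].index) - set(blocks[0].index)
        raise ValueError(
            f"replicate mismatch between tables (traits only: {sorted(only_t)}, "
            f"expression only: {sorted(only_e)})"
        )
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing entries after assembly in columns: {bad}")
    if len(X) < 2:
        raise ValueError("need at least two observations")
    var = X.var(axis=0, ddof=1)
    dead = var[var == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        X = X.drop(columns=dead)
    return X


@dataclass
class PCAResult:
    """Loadings (variables x components), scores (observations x components)
    and per-component variance fractions in percent (summing to 100)."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_percent: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_percent)


class TraitGenePCA(BaseEstimator, TransformerMixin):
    """PCA of a replicate x (traits + genes) matrix.

    Parameters
    ----------
    center, scale : bool
        Column centring and unit-variance scaling (ddof=1). Scaling
        defaults on; without it, high-variance traits (e.g. grain yield in
        g/m2) dominate the decomposition.

    Fitted attributes: ``loadings_`` (orthonormal columns, each oriented so
    its largest-magnitude entry is positive), ``variance_percent_``
    (fractions of total variance, percent, summing to 100 over all
    components), ``mean_``, ``scale_``, ``columns_``.
    """

    def __init__(self, center: bool = True, scale: bool = True):
        self.center = center
        self.scale = scale

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        if self.center:
            A = A - self.mean_
        if self.scale:
            A = A / self.scale_
        return A

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("PCA needs at least two observations")
        A = np.asarray(X, dtype=float)
        self.columns_ = list(X.columns) if hasattr(X, "columns") else list(range(A.shape[1]))
        self.index_ = list(X.index) if hasattr(X, "index") else list(range(A.shape[0]))
        self.mean_ = A.mean(axis=0) if self.center else np.zeros(A.shape[1])
        sd = A.std(axis=0, ddof=1)
        if self.scale and np.any(sd == 0):
            dead = [self.columns_[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance columns cannot be scaled: {dead}")
        self.scale_ = sd if self.scale else np.ones(A.shape[1])
        Z = self._prepare(X)
        n_comp = min(Z.shape)
        sk = _SkPCA(n_components=n_comp, svd_solver="full")
        sk.fit(Z)
        load = sk.components_.T  # variables x components
        # deterministic orientation: largest-|entry| of each loading positive
        flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(load.shape[1])])
        flip[flip == 0] = 1.0
        load = load * flip
        self.loadings_ = pd.DataFrame(
            load, index=self.columns_, columns=[f"PC{i+1}" for i in range(load.shape[1])]
        )
        self.variance_percent_ = 100.0 * sk.explained_variance_ratio_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = self._prepare(X)
        scores = Z @ self.loadings_.to_numpy()
        idx = X.index if hasattr(X, "index") else None
        return pd.DataFrame(scores, index=idx, columns=self.loadings_.columns)

    def fit_result(self, X: pd.DataFrame) -> PCAResult:
        """Fit and package loadings, scores and variance fractions."""
        self.fit(X)
        return PCAResult(
            loadings=self.loadings_.copy(),
            scores=self.transform(X),
            variance_percent=self.variance_percent_.copy(),
        )


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """Functional wrapper over :class:`TraitGenePCA`."""
    return TraitGenePCA(center=center, scale=scale).fit_result(matrix)


def variance_explained(result: PCAResult, k: int = 2) -> float:
    """Percent of total variance carried by the first ``k`` components."""
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k must be in 1..{result.n_components}, got {k}")
    return float(result.variance_percent[:k].sum())
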