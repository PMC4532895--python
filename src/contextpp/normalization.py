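"""Removal of sRNA-independent effects from a fold-change compendium.

Perturbation compendia (one sRNA transfection per column) share strong
sRNA-independent structure — batch effects tied to e.g. 3'-UTR length and AU
content — that confounds feature discovery.  For each experiment i the
response y_i is regressed, by partial least squares, on the fold changes of
the remaining experiments and replaced by its residual:

    i.   cells of the predictor matrix belonging to genes with a canonical
         7-8 nt site to that column's sRNA are masked out, so genuine
         repression measured twice is not subtracted as if it were bias;
    ii.  genes missing in y_i, or missing in >50% of predictor columns,
         are dropped;
    iii. remaining holes are filled by k-nearest-neighbor imputation (k=20);
    iv.  y_i <- y_i - y_i_hat from a PLSR whose component count is chosen by
         10-fold cross-validation.

Each normalized column is then centered on the median of its 'no-site'
mRNAs.  Diagnostics carry the inter-experiment Spearman correlation
matrices before and after.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.impute import KNNImputer
from sklearn.model_selection import KFold

from .types import FoldChangeCompendium

__all__ = [
    "mask_site_entries",
    "filter_genes",
    "knn_impute",
    "plsr_residualize",
    "normalize_compendium",
    "NormalizationResult",
    "CompendiumNormalizer",
]


def mask_site_entries(X: pd.DataFrame, T_slice: pd.DataFrame) -> pd.DataFrame:
    """Set to missing every cell whose mask entry is 1; others untouched."""
    if X.shape != T_slice.shape:
        raise ValueError("X and T slices must share shape")
    return X.mask(T_slice.to_numpy() == 1)


def filter_genes(y: pd.Series, X: pd.DataFrame) -> pd.Index:
    """Genes retained for residualization: y defined and at most 50% of the
    predictor columns missing (strictly more than 50% missing drops the gene)."""
    frac_missing = X.isna().mean(axis=1)
    keep = (~y.isna()) & (frac_missing <= 0.5)
    return y.index[keep]


def knn_impute(X: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Fill missing cells with the mean over the k nearest genes, distance
    being Euclidean over jointly observed columns rescaled by
    sqrt(shared / total) (the nan-Euclidean convention)."""
    if X.isna().all(axis=1).any():
        bad = X.index[X.isna().all(axis=1)].tolist()
        raise ValueError(f"gene(s) with no observed values: {bad}")
    imputer = KNNImputer(n_neighbors=min(k, max(len(X) - 1, 1)), weights="uniform")
    filled = imputer.fit_transform(X.to_numpy())
    return pd.DataFrame(filled, index=X.index, columns=X.columns)


def plsr_residualize(
    y: np.ndarray,
    X: np.ndarray,
    max_components: int = 10,
    cv_folds: int = 10,
    random_state: int | None = 0,
) -> tuple[np.ndarray, int]:
    """Residual of y after a PLSR fit on X, with the component count chosen
    as the smallest within one standard error of the minimum cross-validated
    RMSEP.  Returns (residual, n_components)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < 2 * cv_folds:
        raise ValueError(f"{n} rows is too few for {cv_folds}-fold cross-validation")
    kmax = int(min(max_components, X.shape[1], n - 1))
    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    press = np.zeros((kmax, cv_folds))  # squared-error means per fold
    for f, (tr, te) in enumerate(folds.split(X)):
        for ncomp in range(1, kmax + 1):
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
            press[ncomp - 1, f] = np.mean((y[te] - pred) ** 2)
    rmsep = np.sqrt(press.mean(axis=1))
    se = np.sqrt(press.var(axis=1, ddof=1) / cv_folds) / (2 * np.maximum(rmsep, 1e-12))
    best = int(np.argmin(rmsep))
    threshold = rmsep[best] + se[best]
    ncomp = int(np.argmax(rmsep <= threshold)) + 1  # smallest within one SE
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X, y)
    residual = y - pls.predict(X).ravel()
    return residual, ncomp


@dataclass
class NormalizationResult:
    Z_norm: pd.DataFrame
    n_components: dict[str, int]
    spearman_before: pd.DataFrame
    spearman_after: pd.DataFrame

    def mean_offdiag_abs(self, which: str = "after") -> float:
        m = (self.spearman_after if which == "after" else self.spearman_before).to_numpy()
        off = m[~np.eye(m.shape[0], dtype=bool)]
        return float(np.nanmean(np.abs(off)))


def _spearman_matrix(Z: pd.DataFrame) -> pd.DataFrame:
    corr, _ = spearmanr(Z.to_numpy(), nan_policy="omit")
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=Z.columns, columns=Z.columns)


def normalize_compendium(
    compendium: FoldChangeCompendium,
    *,
    k_neighbors: int = 20,
    max_components: int = 10,
    cv_folds: int = 10,
    center_no_site: bool = True,
    random_state: int | None = 0,
) -> NormalizationResult:
    """Leave-one-out PLSR residualization of every experiment (steps i-iv),
    followed by centering each column on the median fold change of its
    no-site mRNAs."""
    Z, T = compendium.Z, compendium.T
    if Z.shape[1] < 3:
        raise ValueError("need at least 3 experiments")
    Z_norm = pd.DataFrame(np.nan, index=Z.index, columns=Z.columns)
    ncomps: dict[str, int] = {}
    for exp in Z.columns:
        y = Z[exp]
        others = [c for c in Z.columns if c != exp]
        X = mask_site_entries(Z[others], T[others])  # step i
        kept = filter_genes(y, X)  # step ii
        X_imp = knn_impute(X.loc[kept], k=k_neighbors)  # step iii
        resid, ncomp = plsr_residualize(  # step iv
            y.loc[kept].to_numpy(),
            X_imp.to_numpy(),
            max_components=max_components,
            cv_folds=cv_folds,
            random_state=random_state,
        )
        Z_norm.loc[kept, exp] = resid
        ncomps[exp] = ncomp
    if center_no_site:
        for exp in Z_norm.columns:
            no_site = (T[exp] == 0) & Z_norm[exp].notna()
            med = Z_norm.loc[no_site, exp].median()
            Z_norm[exp] = Z_norm[exp] - med
    return NormalizationResult(
        Z_norm=Z_norm,
        n_components=ncomps,
        spearman_before=_spearman_matrix(Z),
        spearman_after=_spearman_matrix(Z_norm),
    )


class CompendiumNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`normalize_compendium`.

    ``fit_transform(compendium)`` returns the normalized genes x experiments
    DataFrame; the full :class:`NormalizationResult` (chosen component
    counts, Spearman diagnostics) is kept on ``result_``.
    """

    def __init__(
        self,
        k_neighbors: int = 20,
        max_components: int = 10,
        cv_folds: int = 10,
        center_no_site: bool = True,
        random_state: int | None = 0,
    ):
        self.k_neighbors = k_neighbors
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.center_no_site = center_no_site
        self.random_state = random_state

    def fit(self, compendium: FoldChangeCompendium, y=None):
        self.result_ = normalize_compendium(
            compendium,
            k_neighbors=self.k_neighbors,
            max_components=self.max_components,
            cv_folds=self.cv_folds,
            center_no_site=self.center_no_site,
            random_state=self.random_state,
        )
        return self

    def transform(self, compendium: FoldChangeCompendium) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("CompendiumNormalizer is not fitted")
        return self.result_.Z_norm

    def fit_transform(self, compendium: FoldChangeCompendium, y=None) -> pd.DataFrame:
        return self.fit(compendium).transform(compendium)
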