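"""PCA on the cross-species log2 matrix and contribution-based gene selection.

Samples are the observations (six columns in the default design: three host,
three graft) and orthologues the variables. Variables are mean-centered but
not scaled. Each variable's *contribution* to a component is its share of
that component's squared loading mass, in percent:

    contrib_g = 100 * loading_g^2 / sum_g loading_g^2

so contributions sum to 100 per component and the expected average under a
uniform spread is 100/p for p variables. Genes contributing strictly more
than 100/p to a component are "selected" for downstream pathway analysis.

Also provides the hierarchical leaf ordering (1 - Pearson correlation,
average linkage) used for heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


@dataclass
class PcaResult:
    """Scores, loadings, eigenvalues and variance fractions of a fitted PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components, unit-norm columns
    eigenvalues: np.ndarray  # non-increasing
    variance_fractions: np.ndarray  # sums to 1 over retained components

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


class OrthologPCA(BaseEstimator, TransformerMixin):
    """Scikit-learn-style PCA with deterministic signs and contributions.

    Parameters
    ----------
    scale : bool, default False
        If True, scale variables to unit variance after centering
        (zero-variance variables stay zero). The default matches centering-
        only behavior.

    Attributes
    ----------
    result_ : PcaResult
    contributions_ : pandas.DataFrame
        genes x components, percent per component (columns sum to 100).
    """

    def __init__(self, scale: bool = False):
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a samples x genes matrix (rows = observations)."""
        X = pd.DataFrame(X)
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 samples")
        values = X.to_numpy(dtype=float)
        centered = values - values.mean(axis=0)
        if not np.any(centered):
            raise ValueError("matrix is constant across samples; nothing to decompose")
        if self.scale:
            sd = values.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            centered = centered / sd

        n_comp = min(n, p)
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(centered)
        loadings = pca.components_.T  # p x n_comp, unit-norm columns

        # fix SVD sign ambiguity: largest-|loading| entry of each component positive
        for j in range(n_comp):
            lead = np.argmax(np.abs(loadings[:, j]))
            if loadings[lead, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1

        comps = [f"PC{j + 1}" for j in range(n_comp)]
        self.result_ = PcaResult(
            scores=pd.DataFrame(scores, index=X.index, columns=comps),
            loadings=pd.DataFrame(loadings, index=X.columns, columns=comps),
            eigenvalues=pca.explained_variance_.copy(),
            variance_fractions=pca.explained_variance_ratio_.copy(),
        )
        sq = loadings**2
        denom = sq.sum(axis=0)
        denom[denom == 0] = 1.0
        self.contributions_ = pd.DataFrame(100.0 * sq / denom, index=X.columns, columns=comps)
        self.n_variables_ = p
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        loadings = self.result_.loadings
        X = pd.DataFrame(X)[loadings.index]
        centered = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
        return pd.DataFrame(centered @ loadings.to_numpy(), index=X.index, columns=loadings.columns)


def run_pca(ortho_matrix: pd.DataFrame, scale: bool = False) -> PcaResult:
    """PCA of an orthologue x sample matrix (transposed internally)."""
    est = OrthologPCA(scale=scale).fit(ortho_matrix.T)
    return est.result_


def gene_contributions(pca: PcaResult, component: int) -> pd.Series:
    """Percent contribution of every gene to one component (1-based index)."""
    if not (1 <= component <= len(pca.components)):
        raise ValueError(f"component must lie in [1, {len(pca.components)}]")
    loading = pca.loadings[f"PC{component}"].to_numpy()
    sq = loading**2
    total = sq.sum()
    if total == 0:
        return pd.Series(0.0, index=pca.loadings.index, name=f"PC{component}_contrib")
    return pd.Series(100.0 * sq / total, index=pca.loadings.index, name=f"PC{component}_contrib")


def select_contributing_genes(contribs: pd.Series, p: int | None = None) -> list:
    """Genes strictly above the expected average contribution 100/p percent."""
    if p is None:
        p = len(contribs)
    if p <= 0:
        raise ValueError("p must be positive")
    threshold = 100.0 / p
    return list(contribs.index[contribs > threshold])


def _correlation_linkage(rows: np.ndarray, labels) -> list:
    """Average-linkage leaf order under distance 1 - Pearson r."""
    if len(labels) < 2:
        return list(labels)
    sd = rows.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant rows: correlation undefined, distance set to max (2.0)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    dist = np.clip(dist, 0.0, None)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return [labels[i] for i in order]


def hierarchical_order(
    ortho_matrix: pd.DataFrame, max_genes: int = 5000
) -> tuple[list, list | None]:
    """Heatmap leaf orders: (sample order, gene order or None above cap).

    Samples and genes are clustered with distance 1 - Pearson correlation
    and average linkage. The gene dendrogram is skipped (None) when the
    matrix holds more than ``max_genes`` genes.
    """
    if ortho_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    values = ortho_matrix.to_numpy(dtype=float)
    sample_order = _correlation_linkage(values.T, list(ortho_matrix.columns))
    gene_order = None
    if ortho_matrix.shape[0] <= max_genes and ortho_matrix.shape[0] >= 2:
        gene_order = _correlation_linkage(values, list(ortho_matrix.index))
    elif ortho_matrix.shape[0] < 2:
        gene_order = list(ortho_matrix.index)
    return sample_order, gene_order
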