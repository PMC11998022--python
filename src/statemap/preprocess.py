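"""Count-matrix QC, median-scaling normalization, HVG selection, and PCA.

The normalization is the classic library-size correction: counts divided by
the cell total, multiplied by the median total across cells, then
ln(x + pseudo) with pseudo-count 0.1. Variable genes are ranked by dispersion
(variance/mean) z-scored within 20 equal-occupancy mean bins, and PCA keeps
the smallest number of components explaining 85% of the variance.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from ._types import CellTable, NormalizedMatrix


def filter_cells(ct: CellTable, mito_fraction_max: float = 0.20) -> CellTable:
    """Drop cells whose mitochondrial molecule fraction exceeds the threshold."""
    if ct.mito is None:
        raise ValueError("CellTable carries no mitochondrial gene flags")
    totals = np.asarray(ct.counts.sum(axis=1)).ravel()
    mito_totals = np.asarray(ct.counts[:, ct.mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    keep = np.flatnonzero(frac <= mito_fraction_max)
    return ct.subset_cells(keep)


def normalize_expression(ct: CellTable, pseudo: float = 0.1) -> NormalizedMatrix:
    """Median-of-totals scaling followed by ln(x + pseudo)."""
    totals = np.asarray(ct.counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {zero[:10].tolist()}")
    median_total = float(np.median(totals))
    scaled = ct.counts.multiply((median_total / totals)[:, None]).toarray()
    values = np.log(scaled + pseudo)
    return NormalizedMatrix(values, scale_factor=median_total, pseudo_count=pseudo,
                            gene_names=ct.gene_names)


def _binned_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion (var/mean) z-scored within equal-occupancy bins of gene mean.

    Genes with non-positive mean or zero within-bin spread get -inf so they
    are never selected ahead of genuinely variable genes.
    """
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean != 0, var / np.abs(mean), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(mean)) * n_bins) // max(len(mean), 1), n_bins - 1
    )
    z = np.full(len(mean), -np.inf)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std()
        if sd > 0:
            z[m] = (disp[m] - mu) / sd
        else:
            z[m] = 0.0
    z[var == 0] = -np.inf
    return z


def select_hvg(nm: NormalizedMatrix, n: int = 1500) -> np.ndarray:
    """Top-n genes by normalized dispersion; ties broken by gene name.

    Dispersion (variance/mean) is computed on the de-logged median-scaled
    counts, then z-scored within 20 equal-occupancy bins of gene mean, so
    highly expressed genes do not dominate the ranking.
    """
    n_genes = nm.values.shape[1]
    if n > n_genes:
        raise ValueError(f"requested {n} genes but matrix has {n_genes}")
    scaled = np.exp(nm.values) - nm.pseudo_count
    z = _binned_dispersion(scaled)
    names = (nm.gene_names if nm.gene_names is not None
             else np.array([f"g{i}" for i in range(n_genes)], dtype=object))
    # sort by (-z, name) for a deterministic ranking
    order = np.lexsort((names.astype(str), -z))
    return np.sort(order[:n])


def standard_embedding(ct: CellTable, n_hvg: int | None = None,
                       var_frac: float = 0.85, pseudo: float = 0.1) -> np.ndarray:
    """Normalize, select variable genes, and PCA-embed in one call.

    ``n_hvg=None`` selects two thirds of the panel (capped at 1500), scaling
    the HVG-count convention to small synthetic panels.
    """
    nm = normalize_expression(ct, pseudo=pseudo)
    if n_hvg is None:
        n_hvg = min(1500, max(2, (2 * ct.n_genes) // 3))
    hvg = select_hvg(nm, n=min(n_hvg, ct.n_genes))
    nm_sel = NormalizedMatrix(nm.values[:, hvg], nm.scale_factor,
                              nm.pseudo_count, nm.gene_names[hvg])
    return pca_retain(nm_sel, var_frac=var_frac)


def pca_retain(nm: NormalizedMatrix, var_frac: float = 0.85,
               random_state: int = 0) -> np.ndarray:
    """Centered PCA keeping the fewest components reaching ``var_frac``."""
    if not 0.0 < var_frac <= 1.0:
        raise ValueError("var_frac must lie in (0, 1]")
    X = nm.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells for PCA")
    n_max = min(X.shape) - 1 if min(X.shape) > 1 else 1
    pca = PCA(n_components=n_max, svd_solver="full", random_state=random_state)
    coords = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    n_keep = min(n_keep, coords.shape[1])
    return coords[:, :n_keep]
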