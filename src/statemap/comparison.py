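"""Cross-trajectory machinery: pseudotime binning, bin-to-bin multi-scale
distance matrices, nearest-bin mapping of one trajectory onto another, joint
layout, clustering, rank-sum differential expression, and signature scoring.

Two trajectories embedded in a joint diffusion space are compared through
equal pseudotime bins (20 by default): every pair of bins gets the mean
multi-scale distance over its cell pairs, and each bin of the query
trajectory maps to its closest reference bin. Reference bins may be
stratified by lineage label, which is what lets the mapping say *which*
in-vivo state an in-vitro bin resembles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._types import AffinityGraph, BinDistance, BinPartition, DiffusionSpace, NormalizedMatrix
from .diffusion import multiscale_distance


def pseudotime_bins(pt: np.ndarray, n_bins: int = 20,
                    stratify_by=None) -> BinPartition:
    """Equal-width pseudotime intervals on [0, 1], optionally split by label.

    Empty (interval, label) bins are dropped with a warning; the last
    interval is closed so pt = 1 is binned.
    """
    pt = np.asarray(pt, float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if pt.min() < -1e-12 or pt.max() > 1 + 1e-12:
        raise ValueError("pseudotime must lie in [0, 1]")
    interval = np.minimum((pt * n_bins).astype(int), n_bins - 1)
    labels = (np.asarray(stratify_by, dtype=object) if stratify_by is not None
              else np.full(len(pt), "", dtype=object))
    keys = sorted({(int(i), str(l)) for i, l in zip(interval, labels)})
    key_to_bin = {k: b for b, k in enumerate(keys)}
    n_possible = n_bins * len(set(labels))
    if len(keys) < n_possible:
        warnings.warn(f"dropped {n_possible - len(keys)} empty pseudotime bins")
    bin_ids = np.array([key_to_bin[(int(i), str(l))]
                        for i, l in zip(interval, labels)])
    meta = pd.DataFrame({
        "bin": np.arange(len(keys)),
        "pt_lo": [i / n_bins for i, _ in keys],
        "pt_hi": [(i + 1) / n_bins for i, _ in keys],
        "label": [l for _, l in keys],
        "n_cells": np.bincount(bin_ids, minlength=len(keys)),
    })
    return BinPartition(bin_ids=bin_ids, bin_meta=meta, n_bins=n_bins)


def bin_distance_matrix(ds: DiffusionSpace, pa: BinPartition, pb: BinPartition,
                        idx_a=None, idx_b=None, max_pairs: int = 250_000,
                        seed: int = 0) -> BinDistance:
    """Mean multi-scale distance for every pair of bins.

    ``idx_a``/``idx_b`` translate the partitions' cell positions into rows of
    the (joint) diffusion space; identity when omitted. Bin pairs exceeding
    ``max_pairs`` cell pairs are estimated from a uniform subsample.
    """
    idx_a = np.arange(len(pa.bin_ids)) if idx_a is None else np.asarray(idx_a)
    idx_b = np.arange(len(pb.bin_ids)) if idx_b is None else np.asarray(idx_b)
    rng = np.random.default_rng(seed)
    na, nb = len(pa.bin_meta), len(pb.bin_meta)
    out = np.zeros((na, nb))
    cells_a = [idx_a[pa.bin_ids == i] for i in range(na)]
    cells_b = [idx_b[pb.bin_ids == j] for j in range(nb)]
    for i in range(na):
        for j in range(nb):
            ca, cb = cells_a[i], cells_b[j]
            if len(ca) * len(cb) > max_pairs:
                m = int(np.sqrt(max_pairs))
                ca = rng.choice(ca, size=min(len(ca), m), replace=False)
                cb = rng.choice(cb, size=min(len(cb), m), replace=False)
            d = multiscale_distance(ds, ca, cb)
            if ca is cells_a[i] and cb is cells_b[j] and i == j and np.array_equal(ca, cb):
                out[i, j] = d[np.triu_indices(len(ca), k=1)].mean() if len(ca) > 1 else 0.0
            else:
                out[i, j] = d.mean()
    return BinDistance(matrix=out, rows=pa.bin_meta, cols=pb.bin_meta)


def map_bins(bd: BinDistance) -> pd.DataFrame:
    """Map each bin of A to its closest bin of B (argmin per row).

    Ties break toward the lower bin index. The mapped bin's label and
    pseudotime interval are carried along for interpretation.
    """
    nearest = np.argmin(bd.matrix, axis=1)
    return pd.DataFrame({
        "bin_a": bd.rows["bin"].to_numpy(),
        "label_a": bd.rows["label"].to_numpy(),
        "mapped_bin_b": bd.cols["bin"].to_numpy()[nearest],
        "mapped_label_b": bd.cols["label"].to_numpy()[nearest],
        "mapped_pt_lo": bd.cols["pt_lo"].to_numpy()[nearest],
        "mapped_pt_hi": bd.cols["pt_hi"].to_numpy()[nearest],
        "distance": bd.matrix[np.arange(bd.matrix.shape[0]), nearest],
    })


def coembed_layout(A: AffinityGraph | sp.spmatrix, iterations: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Force-directed 2-D layout of the (joint) affinity graph."""
    W = A.weights if isinstance(A, AffinityGraph) else sp.csr_matrix(A)
    G = nx.from_scipy_sparse_array(W)
    pos = nx.spring_layout(G, iterations=iterations, seed=seed, weight="weight")
    return np.array([pos[i] for i in range(W.shape[0])])


def layout_stress(coords: np.ndarray, A: AffinityGraph | sp.spmatrix) -> float:
    """Sum of squared deviations of edge lengths from their target lengths
    (1/weight for weighted graphs); a diagnostic for layout quality."""
    W = (A.weights if isinstance(A, AffinityGraph) else sp.csr_matrix(A)).tocoo()
    mask = W.row < W.col
    lengths = np.linalg.norm(coords[W.row[mask]] - coords[W.col[mask]], axis=1)
    target = 1.0 / np.maximum(W.data[mask], 1e-12)
    target = target / target.mean() * lengths.mean()   # scale-free comparison
    return float(np.sum((lengths - target) ** 2))


def cluster_cells(X, method: str = "community", k: int = 30,
                  resolution: float = 1.0, n_clusters: int = 30,
                  seed: int = 0) -> np.ndarray:
    """Cluster cells on an embedding.

    'community' builds a k-NN graph re-weighted by neighbor-set Jaccard
    similarity (PhenoGraph-style) and runs modularity community detection;
    'kmeans_diffusion' runs k-means with a fixed seed (the joint-space
    alternative used alongside spectral embeddings).
    """
    X = np.asarray(X, float)
    if method == "kmeans_diffusion":
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        return km.fit_predict(X)
    if method != "community":
        raise ValueError(f"unknown method '{method}'")
    n = X.shape[0]
    kk = min(k, n - 1)
    _, idx = NearestNeighbors(n_neighbors=kk + 1).fit(X).kneighbors(X)
    neigh = [set(r[1:]) for r in idx]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            if G.has_edge(i, j):
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union if union else 0.0
            if w > 0:
                G.add_edge(i, j, weight=w)
    comms = nx.community.louvain_communities(G, weight="weight",
                                             resolution=resolution, seed=seed)
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(sorted(comms, key=lambda s: -len(s))):
        labels[list(members)] = c
    return labels


def differential_genes(nm: NormalizedMatrix, labels, target_group,
                       p_max: float = 0.01, lfc_min: float = 2.0,
                       top_n: int | None = 50,
                       use_fdr: bool = True) -> pd.DataFrame:
    """Rank-sum differential expression of one group versus the rest.

    Per gene: two-sided Mann-Whitney p, Benjamini-Hochberg FDR, and the log
    fold change of group means on the normalized (natural-log) scale. Genes
    passing (FDR or raw p) < p_max and |lfc| > lfc_min are returned, ranked
    by FDR then |lfc|, optionally truncated to ``top_n``.
    """
    labels = np.asarray(labels)
    in_g = labels == target_group
    if in_g.sum() < 2 or (~in_g).sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    X = nm.values
    a, b = X[in_g], X[~in_g]
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    lfc = a.mean(axis=0) - b.mean(axis=0)
    names = (nm.gene_names if nm.gene_names is not None
             else np.array([f"g{i}" for i in range(X.shape[1])], dtype=object))
    tab = pd.DataFrame({"gene": names, "p": p, "fdr": fdr, "lfc": lfc})
    crit = tab["fdr"] if use_fdr else tab["p"]
    tab = tab[(crit < p_max) & (tab["lfc"].abs() > lfc_min)]
    tab = tab.sort_values(["fdr", "lfc"], key=lambda s: s.abs() if s.name == "lfc" else s,
                          ascending=[True, False])
    if top_n is not None:
        tab = tab.head(top_n)
    tab = tab.reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def signature_scores(nm: NormalizedMatrix, gene_sets: dict) -> pd.DataFrame:
    """Average z-scored expression of each gene set per cell."""
    X = nm.values
    names = (nm.gene_names if nm.gene_names is not None
             else np.array([f"g{i}" for i in range(X.shape[1])], dtype=object))
    pos = {g: i for i, g in enumerate(names)}
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    out = {}
    for set_name, genes in gene_sets.items():
        idx = [pos[g] for g in genes if g in pos]
        if not idx:
            raise ValueError(f"gene set '{set_name}' has no genes in the matrix")
        out[set_name] = Z[:, idx].mean(axis=1)
    return pd.DataFrame(out)
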