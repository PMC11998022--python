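"""k-NN graphs, the adaptive affinity kernel, mutual nearest neighbors, and
augmented affinity matrices joining datasets or timepoints.

Affinity kernel: a_ij = exp(-d_ij^2 / (sigma_i * sigma_j)) with sigma_i the
distance from cell i to its l-th nearest neighbor (l = round(k/3)), evaluated
on the union of the two cells' neighborhoods and symmetrized. The adaptive
bandwidth compensates for density differences along the trajectory. The
augmented affinity matrix stitches per-dataset (or per-timepoint) blocks
together with adaptive-kernel weights on mutual-nearest-neighbor cross edges.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._types import AffinityGraph, NeighborGraph


def knn_graph(X: np.ndarray, k: int = 50) -> NeighborGraph:
    """Exact k-nearest-neighbor graph by Euclidean distance.

    Ties at the k-th distance are broken by ascending index for determinism.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self (guaranteed first among zero distances only if unique; handle dupes)
    rows, cols, vals = [], [], []
    for i in range(n):
        js, ds = idx[i], dist[i]
        keep = js != i
        js, ds = js[keep][:k], ds[keep][:k]
        rows.append(np.full(len(js), i))
        cols.append(js)
        vals.append(ds)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    d = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return NeighborGraph(d, k=k)


def _bandwidths(g: NeighborGraph, l: int) -> np.ndarray:
    """sigma_i = distance from i to its l-th nearest neighbor."""
    n = g.n
    sig = np.zeros(n)
    d = g.distances
    for i in range(n):
        row = np.sort(d.data[d.indptr[i]:d.indptr[i + 1]])
        if len(row) >= l:
            sig[i] = row[l - 1]
        elif len(row):
            sig[i] = row[-1]
    pos = sig[sig > 0]
    if pos.size:
        sig[sig == 0] = pos.min()
    else:
        sig[:] = 1.0
    return sig


def adaptive_affinity(g: NeighborGraph, l: int | None = None,
                      bandwidth: str = "geometric") -> AffinityGraph:
    """Adaptive anisotropic kernel on the k-NN graph.

    ``bandwidth='geometric'`` uses exp(-d^2/(sigma_i sigma_j));
    ``'per_cell'`` uses exp(-d^2/sigma_i^2) followed by transpose-averaging.
    """
    if l is None:
        l = int(round(g.k / 3))
    if not 1 <= l < g.k:
        raise ValueError(f"l={l} must satisfy 1 <= l < k={g.k}")
    if bandwidth not in ("geometric", "per_cell"):
        raise ValueError("bandwidth must be 'geometric' or 'per_cell'")
    sig = _bandwidths(g, l)
    d = g.distances.tocoo()
    if bandwidth == "geometric":
        w = np.exp(-(d.data ** 2) / (sig[d.row] * sig[d.col]))
    else:
        w = np.exp(-(d.data ** 2) / sig[d.row] ** 2)
    a = sp.csr_matrix((w, (d.row, d.col)), shape=d.shape)
    a = (a + a.T) * 0.5
    a.setdiag(0)
    a.eliminate_zeros()
    return AffinityGraph(a, provenance=["within:knn"])


def mutual_nn(Xa: np.ndarray, Xb: np.ndarray, k: int = 50) -> np.ndarray:
    """Mutual-nearest-neighbor cross edges between two coordinate sets.

    Returns an (m, 3) array of (index_in_a, index_in_b, distance) rows where
    b is among a's k nearest in B *and* a is among b's k nearest in A.
    """
    Xa = np.atleast_2d(np.asarray(Xa, float))
    Xb = np.atleast_2d(np.asarray(Xb, float))
    if Xa.shape[0] == 0 or Xb.shape[0] == 0:
        raise ValueError("both coordinate sets must be non-empty")
    ka = min(k, Xb.shape[0])
    kb = min(k, Xa.shape[0])
    dab, iab = NearestNeighbors(n_neighbors=ka).fit(Xb).kneighbors(Xa)
    _, iba = NearestNeighbors(n_neighbors=kb).fit(Xa).kneighbors(Xb)
    nn_b_of_a = [set(r) for r in iab]
    nn_a_of_b = [set(r) for r in iba]
    edges = []
    for a in range(Xa.shape[0]):
        for b, dist in zip(iab[a], dab[a]):
            if a in nn_a_of_b[b]:
                edges.append((a, b, dist))
    return np.array(edges, dtype=float).reshape(-1, 3)


def augment_affinity(blocks: list, cross_specs: list,
                     k: int = 50, l: int | None = None) -> AffinityGraph:
    """Stitch per-group affinity blocks with MNN cross edges.

    ``blocks`` is a list of (group_name, coordinates, AffinityGraph) triples;
    coordinates are needed to search cross neighbors and to derive each
    endpoint's within-group bandwidth. ``cross_specs`` lists (group_a,
    group_b) pairs to join by mutual nearest neighbors. Provenance records
    every spec verbatim.
    """
    if l is None:
        l = int(round(k / 3))
    names = [b[0] for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    offsets, at = {}, 0
    for name, X, _aff in blocks:
        offsets[name] = at
        at += np.atleast_2d(X).shape[0]
    n_total = at

    mats = [sp.coo_matrix(aff.weights) for _n, _x, aff in blocks]
    A = sp.block_diag(mats, format="lil")

    # within-group bandwidths for cross-edge kernels
    sigma = {}
    for name, X, _aff in blocks:
        X = np.atleast_2d(np.asarray(X, float))
        kk = min(k, X.shape[0] - 1)
        g = knn_graph(X, k=kk) if X.shape[0] > 1 else None
        sigma[name] = (_bandwidths(g, min(l, max(1, kk - 1)))
                       if g is not None else np.ones(X.shape[0]))

    provenance = [f"within:{name}" for name in names]
    A = A.tocsr().tolil()
    for ga, gb in cross_specs:
        if ga not in offsets or gb not in offsets:
            missing = ga if ga not in offsets else gb
            raise ValueError(f"unknown group name '{missing}'")
        Xa = np.atleast_2d(next(b[1] for b in blocks if b[0] == ga))
        Xb = np.atleast_2d(next(b[1] for b in blocks if b[0] == gb))
        edges = mutual_nn(Xa, Xb, k=k)
        for a, b, dist in edges:
            w = np.exp(-(dist ** 2) / (sigma[ga][int(a)] * sigma[gb][int(b)]))
            i, j = offsets[ga] + int(a), offsets[gb] + int(b)
            w = max(w, A[i, j])
            A[i, j] = w
            A[j, i] = w
        provenance.append(f"mnn:{ga}<->{gb}")
    A = A.tocsr()
    A = (A + A.T) * 0.5
    A.setdiag(0)
    A.eliminate_zeros()
    return AffinityGraph(A, provenance=provenance)
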