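"""Diffusion operator, spectral decomposition with eigengap selection,
multi-scale coordinates/distances, and graph-diffusion imputation.

The row-stochastic operator T = D^-1 A is decomposed through its symmetric
conjugate D^1/2 T D^-1/2 (identical spectrum, orthogonal eigenvectors), and
the eigenvectors are mapped back. Multi-scale coordinates re-weight each
non-trivial eigenvector by lambda/(1 - lambda), so Euclidean distance in that
space integrates diffusion distances over all scales. Imputation smooths
expression by t steps of the same operator (t = 3 by default).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl
from sklearn.base import BaseEstimator

from ._types import AffinityGraph, DiffusionSpace


def markov_operator(A: AffinityGraph | sp.spmatrix) -> sp.csr_matrix:
    """Row-normalize an affinity matrix into a diffusion operator."""
    W = A.weights if isinstance(A, AffinityGraph) else sp.csr_matrix(A)
    deg = np.asarray(W.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg <= 0)
    if isolated.size:
        raise ValueError(f"isolated vertices (zero degree): {isolated[:10].tolist()}")
    return sp.diags(1.0 / deg) @ W


class DiffusionMap(BaseEstimator):
    """Spectral embedding of the diffusion operator with eigengap selection.

    Parameters
    ----------
    n_eigs : number of eigenpairs computed before selection (default 20).
    selection : 'eigengap' picks the largest consecutive eigenvalue drop
        among the non-trivial eigenvalues (at least 2 components kept);
        'fixed' keeps ``n_components`` eigenvectors.
    n_components : component count when selection='fixed'.

    Attributes (after fit)
    ----------------------
    eigenvalues_, eigenvectors_ : descending spectrum of T and the
        right eigenvectors mapped back from the symmetric conjugate.
    n_selected_ : number of informative (non-trivial) components kept.
    multiscale_ : cells x n_selected_ multi-scale coordinates.
    """

    def __init__(self, n_eigs: int = 20, selection: str = "eigengap",
                 n_components: int | None = None):
        self.n_eigs = n_eigs
        self.selection = selection
        self.n_components = n_components

    def fit(self, A: AffinityGraph | sp.spmatrix, y=None):
        if self.selection not in ("eigengap", "fixed"):
            raise ValueError("selection must be 'eigengap' or 'fixed'")
        W = A.weights if isinstance(A, AffinityGraph) else sp.csr_matrix(A)
        n = W.shape[0]
        deg = np.asarray(W.sum(axis=1)).ravel()
        if np.any(deg <= 0):
            raise ValueError("graph has isolated vertices")
        n_eigs = min(self.n_eigs, n - 1)
        d_isqrt = 1.0 / np.sqrt(deg)
        S = sp.diags(d_isqrt) @ W @ sp.diags(d_isqrt)
        S = (S + S.T) * 0.5
        if n < 200:
            vals, vecs = np.linalg.eigh(S.toarray())
            vals, vecs = vals[::-1][: n_eigs + 1], vecs[:, ::-1][:, : n_eigs + 1]
        else:
            v0 = np.full(n, 1.0 / np.sqrt(n))    # deterministic start vector
            try:
                vals, vecs = spl.eigsh(S, k=n_eigs + 1, which="LA", v0=v0)
            except spl.ArpackNoConvergence as err:
                raise RuntimeError(
                    f"eigensolver did not converge ({len(err.eigenvalues)} of "
                    f"{n_eigs + 1} eigenpairs found)"
                ) from err
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
        # map symmetric eigenvectors back to right eigenvectors of T
        psi = vecs * d_isqrt[:, None]
        # normalize and fix sign for determinism
        psi /= np.linalg.norm(psi, axis=0, keepdims=True)
        sign = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
        psi *= np.where(sign == 0, 1.0, sign)

        if self.selection == "fixed":
            if not self.n_components or self.n_components < 1:
                raise ValueError("selection='fixed' requires n_components >= 1")
            n_sel = min(self.n_components, len(vals) - 1)
        else:
            lam = vals[1:]                      # exclude trivial lambda_0
            gaps = lam[:-1] - lam[1:]
            n_sel = max(2, int(np.argmax(gaps)) + 1) if len(gaps) else 1
        lam_sel = vals[1: n_sel + 1]
        scale = lam_sel / np.maximum(1.0 - lam_sel, 1e-12)
        self.eigenvalues_ = vals
        self.eigenvectors_ = psi
        self.n_selected_ = int(n_sel)
        self.multiscale_ = psi[:, 1: n_sel + 1] * scale[None, :]
        return self

    def space(self) -> DiffusionSpace:
        return DiffusionSpace(self.eigenvalues_, self.eigenvectors_,
                              self.n_selected_, self.multiscale_)


def diffusion_maps(T_or_A, n_eigs: int = 20, select: str = "eigengap",
                   n_components: int | None = None) -> DiffusionSpace:
    """Functional wrapper over :class:`DiffusionMap`.

    Accepts either an affinity matrix/graph or a row-stochastic operator
    (the symmetrized decomposition only needs the affinities' degrees, and a
    row-stochastic matrix is treated as an affinity with unit row sums).
    """
    dm = DiffusionMap(n_eigs=n_eigs, selection=select, n_components=n_components)
    return dm.fit(T_or_A).space()


def multiscale_distance(ds: DiffusionSpace, idx_a=None, idx_b=None) -> np.ndarray:
    """Pairwise Euclidean distances in multi-scale diffusion coordinates."""
    u = ds.multiscale
    a = u if idx_a is None else u[np.asarray(idx_a)]
    b = u if idx_b is None else u[np.asarray(idx_b)]
    from scipy.spatial.distance import cdist
    return cdist(a, b)


def impute(T: sp.spmatrix, X: np.ndarray, t: int = 3) -> np.ndarray:
    """Diffusion-based (MAGIC-style) smoothing: T^t X by repeated products."""
    if t < 0:
        raise ValueError("t must be >= 0")
    Y = np.asarray(X, dtype=float)
    T = sp.csr_matrix(T)
    for _ in range(t):
        Y = T @ Y
    return Y
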