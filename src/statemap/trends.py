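"""Smoothed gene-expression trends along pseudotime and their clustering.

Trends are penalized cubic B-spline (P-spline) fits of expression on
pseudotime — second-order difference penalty, smoothing parameter chosen per
gene by generalized cross-validation over a lambda grid. The spline basis is
shared across genes, so each lambda costs one factorization for the whole
panel. Branch probabilities can weight the fit so a trend follows one
terminal's cells only.

Trend clustering follows the correlation-radius recipe: z-score each trend,
connect gene pairs with correlation distance <= 0.025, convert to an
affinity (1 - distance), run Louvain, and drop clusters of fewer than
2 genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

from ._types import TrendSet


def _bspline_basis(x: np.ndarray, n_knots: int = 8, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with equally spaced interior knots on [0,1]."""
    interior = np.linspace(0, 1, n_knots)[1:-1]
    t = np.concatenate([[0] * (degree + 1), interior, [1] * (degree + 1)])
    return BSpline.design_matrix(np.clip(x, 0, 1), t, degree).toarray()


def _second_diff_penalty(p: int) -> np.ndarray:
    D = np.diff(np.eye(p), n=2, axis=0)
    return D.T @ D


class GeneTrendSmoother(BaseEstimator):
    """P-spline smoother of many genes against a shared pseudotime axis.

    Parameters
    ----------
    grid_size : evaluation grid resolution on [0, 1] (default 500).
    n_knots : interior-knot count of the cubic basis (default 8).
    lambdas : candidate smoothing parameters searched by GCV.

    Attributes (after fit)
    ----------------------
    trends_ : genes x grid fitted means.
    stderr_ : genes x grid pointwise standard errors.
    lambda_ : per-gene GCV-selected smoothing parameter.
    """

    def __init__(self, grid_size: int = 500, n_knots: int = 8,
                 lambdas=tuple(10.0 ** np.arange(-4, 5))):
        self.grid_size = grid_size
        self.n_knots = n_knots
        self.lambdas = lambdas

    def fit(self, expr: np.ndarray, pt: np.ndarray, weights=None):
        expr = np.atleast_2d(np.asarray(expr, float))  # cells x genes
        pt = np.asarray(pt, float)
        if expr.shape[0] != pt.shape[0]:
            raise ValueError("expression rows must match pseudotime length")
        if expr.shape[0] < 10:
            raise ValueError("need at least 10 cells to fit trends")
        if pt.min() < -1e-9 or pt.max() > 1 + 1e-9:
            raise ValueError("pseudotime must lie in [0, 1]")
        w = (np.ones(len(pt)) if weights is None
             else np.asarray(weights, float))
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        B = _bspline_basis(pt, self.n_knots)
        P = _second_diff_penalty(B.shape[1])
        Bw = B * w[:, None]
        BtWB = B.T @ Bw
        BtWy = Bw.T @ expr
        n_eff = w.sum()

        grid = np.linspace(0, 1, self.grid_size)
        Bg = _bspline_basis(grid, self.n_knots)

        n_g = expr.shape[1]
        best_gcv = np.full(n_g, np.inf)
        best_coef = np.zeros((B.shape[1], n_g))
        best_lam = np.zeros(n_g)
        best_rss = np.zeros(n_g)
        best_edf = np.zeros(n_g)
        best_H = [None] * n_g
        for lam in self.lambdas:
            M = BtWB + lam * P
            Minv = np.linalg.pinv(M)
            coef = Minv @ BtWy
            fitted = B @ coef
            rss = (w[:, None] * (expr - fitted) ** 2).sum(axis=0)
            edf = np.trace(Minv @ BtWB)
            denom = max(n_eff - edf, 1e-9) ** 2
            gcv = n_eff * rss / denom
            better = gcv < best_gcv
            if np.any(better):
                best_gcv[better] = gcv[better]
                best_coef[:, better] = coef[:, better]
                best_lam[better] = lam
                best_rss[better] = rss[better]
                best_edf[better] = edf
                for g in np.flatnonzero(better):
                    best_H[g] = Minv

        self.lambda_ = best_lam
        self.trends_ = (Bg @ best_coef).T
        # pointwise SE: sigma^2_g * diag(Bg Minv (B'W^2 B) Minv Bg')
        se = np.zeros_like(self.trends_)
        BtW2B = Bw.T @ Bw
        for g in range(n_g):
            Minv = best_H[g]
            sigma2 = best_rss[g] / max(n_eff - best_edf[g], 1.0)
            cov_core = Minv @ BtW2B @ Minv
            se[g] = np.sqrt(np.maximum(sigma2 * np.einsum(
                "ij,jk,ik->i", Bg, cov_core, Bg), 0.0))
        self.stderr_ = se
        self.grid_ = grid
        return self

    def result(self) -> TrendSet:
        return TrendSet(trends=self.trends_, grid=self.grid_,
                        stderr=self.stderr_)


def fit_trends(expr: np.ndarray, pt: np.ndarray, weights=None,
               grid_size: int = 500) -> TrendSet:
    """Fit per-gene penalized-spline trends of expression on pseudotime."""
    sm = GeneTrendSmoother(grid_size=grid_size)
    return sm.fit(expr, pt, weights=weights).result()


class TrendGraphClusterer(BaseEstimator):
    """Louvain communities on the correlation-radius gene-gene graph.

    Genes whose z-scored trends have correlation distance <= ``radius`` are
    connected with affinity 1 - distance; communities smaller than
    ``min_size`` are dropped (their genes labeled -1).
    """

    def __init__(self, radius: float = 0.025, min_size: int = 2, seed: int = 0):
        self.radius = radius
        self.min_size = min_size
        self.seed = seed

    def fit_predict(self, trends: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(trends, float))
        n_genes = Z.shape[0]
        if n_genes < 2:
            raise ValueError("need at least 2 genes")
        sd = Z.std(axis=1)
        degenerate = sd < 1e-12
        if np.any(degenerate):
            warnings.warn(f"excluding {int(degenerate.sum())} zero-variance trends")
        ok = np.flatnonzero(~degenerate)
        Zn = (Z[ok] - Z[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        corr = np.corrcoef(Zn)
        dist = 1.0 - corr
        G = nx.Graph()
        G.add_nodes_from(range(len(ok)))
        ii, jj = np.where(np.triu(dist <= self.radius, k=1))
        for i, j in zip(ii, jj):
            G.add_edge(int(i), int(j), weight=max(1.0 - dist[i, j], 1e-12))
        comms = nx.community.louvain_communities(G, weight="weight", seed=self.seed)
        labels = np.full(n_genes, -1, dtype=int)
        next_id = 0
        for members in sorted(comms, key=lambda s: (-len(s), min(s))):
            if len(members) < self.min_size:
                continue
            labels[ok[list(members)]] = next_id
            next_id += 1
        self.labels_ = labels
        return labels


def cluster_trends(ts: TrendSet | np.ndarray, radius: float = 0.025,
                   min_size: int = 2, seed: int = 0) -> np.ndarray:
    """Cluster fitted trends; returns per-gene labels (-1 = unassigned)."""
    trends = ts.trends if isinstance(ts, TrendSet) else np.asarray(ts)
    return TrendGraphClusterer(radius=radius, min_size=min_size,
                               seed=seed).fit_predict(trends)
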