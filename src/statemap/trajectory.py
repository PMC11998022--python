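"""Trajectory inference on the diffusion graph: start-cell anchoring,
shortest-path pseudotime, a pseudotime-directed Markov chain, automatic
terminal-state detection, absorbing-chain fate probabilities, and the
entropy-based differentiation potential.

The model treats differentiation as a Markov chain over the cell-cell
affinity graph whose edges are oriented by pseudotime; terminal states are
absorbing, and each cell's fate probabilities are the absorption
probabilities B = (I - Q)^-1 R of the chain. The entropy of that row is the
cell's differentiation potential: ln K for a fully uncommitted cell over K
fates, 0 for a committed one.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spl
from sklearn.base import BaseEstimator

from ._types import AffinityGraph, DiffusionSpace, NeighborGraph, TrajectoryFit
from .diffusion import DiffusionMap
from .graphkit import adaptive_affinity, knn_graph


def anchor_start_cell(ds: DiffusionSpace, candidate: int) -> int:
    """Snap a user-chosen start cell to the nearest extreme of the diffusion
    component on which it loads most strongly."""
    u = ds.multiscale
    extrema = {int(np.argmin(u[:, c])) for c in range(u.shape[1])}
    extrema |= {int(np.argmax(u[:, c])) for c in range(u.shape[1])}
    extrema = np.array(sorted(extrema))
    d = np.linalg.norm(u[extrema] - u[candidate], axis=1)
    return int(extrema[np.argmin(d)])


def compute_pseudotime(g: NeighborGraph, start: int,
                       n_waypoints: int = 0, seed: int = 0) -> np.ndarray:
    """Shortest-path pseudotime from the start cell, min-max scaled to [0, 1].

    With ``n_waypoints > 0`` the ordering is refined by iteratively averaging
    waypoint-centred shortest-path perspectives weighted by proximity, until
    the maximum change drops below 1e-3.
    """
    D = g.distances.maximum(g.distances.T)
    dist = csgraph.dijkstra(D, directed=False, indices=start)
    unreachable = np.flatnonzero(~np.isfinite(dist))
    if unreachable.size:
        raise ValueError(f"{unreachable.size} cells unreachable from start cell")
    pt = dist.copy()
    if n_waypoints > 0:
        pt = _waypoint_refine(D, pt, start, n_waypoints, seed)
    rng_ = pt.max() - pt.min()
    return (pt - pt.min()) / (rng_ if rng_ > 0 else 1.0)


def _maxmin_sample(n: int, start: int, all_dist) -> np.ndarray:
    """Greedy max-min landmark selection in shortest-path distance."""
    chosen = [start]
    mind = all_dist[start].copy()
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, all_dist[nxt])
    return np.array(chosen)


def _waypoint_refine(D, pt, start, n_waypoints, seed, tol=1e-3, max_iter=25):
    n = D.shape[0]
    n_waypoints = min(n_waypoints, n)
    all_needed = csgraph.dijkstra(D, directed=False)
    wp = _maxmin_sample(n_waypoints, start, all_needed)
    Dw = all_needed[wp]
    sigma = np.std(Dw)
    W = np.exp(-Dw / max(sigma, 1e-12))
    W /= W.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        persp = np.where(pt[None, :] >= pt[wp][:, None],
                         pt[wp][:, None] + Dw, pt[wp][:, None] - Dw)
        new = (W * persp).sum(axis=0)
        new[start] = 0.0
        if np.max(np.abs(new - pt)) < tol:
            pt = new
            break
        pt = new
    return pt


def directed_markov_chain(A: AffinityGraph | sp.spmatrix,
                          pt: np.ndarray) -> sp.csr_matrix:
    """Orient the affinity graph by pseudotime and renormalize rows.

    Edge i->j survives iff pt_j >= pt_i - w_i, where w_i is the standard
    deviation of pseudotime among i's neighbors (an adaptive backward
    window). Rows losing every edge become self-absorbing.
    """
    W = (A.weights if isinstance(A, AffinityGraph) else sp.csr_matrix(A)).tocsr()
    pt = np.asarray(pt, float)
    n = W.shape[0]
    indptr, indices, data = W.indptr, W.indices, W.data
    rows, cols, vals = [], [], []
    for i in range(n):
        js = indices[indptr[i]:indptr[i + 1]]
        ws = data[indptr[i]:indptr[i + 1]]
        if len(js) == 0:
            rows.append(i); cols.append(i); vals.append(1.0)
            continue
        wi = np.std(pt[js])
        keep = pt[js] >= pt[i] - wi
        if not np.any(keep):
            rows.append(i); cols.append(i); vals.append(1.0)
            continue
        kept_w = ws[keep]
        kept_w = kept_w / kept_w.sum()
        rows.extend([i] * int(keep.sum()))
        cols.extend(js[keep].tolist())
        vals.extend(kept_w.tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _ascend_pseudotime(adj: sp.csr_matrix, pt: np.ndarray, u: np.ndarray,
                       cell: int, radius: float, max_hops: int = 5) -> int:
    """Local pseudotime hill-climb constrained to the candidate's own
    diffusion region: each step moves to the highest-pseudotime neighbor
    within ``radius`` in multi-scale coordinates, so a candidate snaps to
    its branch boundary without migrating across the trajectory."""
    for _ in range(max_hops):
        neigh = adj.indices[adj.indptr[cell]:adj.indptr[cell + 1]]
        if neigh.size == 0:
            return cell
        close = neigh[np.linalg.norm(u[neigh] - u[cell], axis=1) <= radius]
        if close.size == 0:
            return cell
        best = int(close[np.argmax(pt[close])])
        if pt[best] <= pt[cell]:
            return cell
        cell = best
    return cell


def detect_terminal_states(chain: sp.spmatrix, ds: DiffusionSpace,
                           pt: np.ndarray, user_terminals=None,
                           eps: float = 1e-3, start: int | None = None) -> np.ndarray:
    """Find absorbing boundary cells of the directed chain.

    Candidates are the extrema of the multi-scale diffusion components,
    snapped to the pseudotime boundary of their own diffusion region by a
    locally constrained hill-climb; a candidate is kept iff its outgoing
    transition mass toward higher pseudotime is below ``eps``
    (boundary-absorbing). Kept candidates are merged by superlevel-set
    connectivity: a candidate joins an earlier (higher-pseudotime) one iff
    the two are connected through cells of no lower pseudotime (minus a
    small tolerance). Boundary pockets along one branch merge into that
    branch's tip, while distinct terminal states stay separate because any
    path between them dips through the branch point.
    """
    if user_terminals is not None:
        return np.asarray(user_terminals, dtype=int)
    chain = sp.csr_matrix(chain)
    pt = np.asarray(pt, float)
    u = ds.multiscale
    span = float(np.linalg.norm(u.max(axis=0) - u.min(axis=0)))
    radius = 0.1 * span
    adj_und = chain.maximum(chain.T).tocsr()
    cands = set()
    for c in range(u.shape[1]):
        for cell in (int(np.argmax(u[:, c])), int(np.argmin(u[:, c]))):
            cands.add(_ascend_pseudotime(adj_und, pt, u, cell, radius))
    kept = []
    for c in sorted(cands):
        if start is not None and np.linalg.norm(u[c] - u[start]) <= radius:
            continue            # the start boundary is not a terminal fate
        row = chain.getrow(c)
        fwd = row.data[pt[row.indices] > pt[c]].sum()
        if fwd < eps:
            kept.append(c)
    if not kept:
        raise ValueError(
            "no terminal states detected automatically; pass user_terminals"
        )
    # superlevel-set merge, highest pseudotime first
    tol = 0.05 * (pt.max() - pt.min())
    kept = sorted(kept, key=lambda c: -pt[c])
    terminals: list[int] = []
    for c in kept:
        mask = pt >= pt[c] - tol
        idx = np.flatnonzero(mask)
        sub = adj_und[np.ix_(idx, idx)]
        _n, labels = csgraph.connected_components(sub > 0, directed=False)
        pos = {cell: i for i, cell in enumerate(idx)}
        if not any(labels[pos[c]] == labels[pos[t]] for t in terminals):
            terminals.append(int(c))
    return np.array(sorted(terminals), dtype=int)


def branch_probabilities(chain: sp.spmatrix, terminals) -> np.ndarray:
    """Absorption probabilities of the chain with the terminals absorbing.

    Returns cells x terminals; each terminal's own row is an indicator.
    """
    terminals = np.asarray(terminals, dtype=int)
    if terminals.size == 0:
        raise ValueError("terminals must be non-empty")
    chain = sp.csr_matrix(chain).astype(float)
    n = chain.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[terminals] = False
    trans = np.flatnonzero(mask)
    Q = chain[np.ix_(trans, trans)]
    R = chain[np.ix_(trans, terminals)]
    A = sp.identity(len(trans), format="csc") - Q.tocsc()
    Rd = R.toarray()
    try:
        if len(trans) < 500:
            B = np.linalg.solve(A.toarray(), Rd)
        else:
            lu = spl.splu(A)
            B = lu.solve(Rd)
    except (np.linalg.LinAlgError, RuntimeError) as err:
        raise RuntimeError(
            "absorbing-chain solve failed: the chain has a recurrent class "
            "that cannot reach any terminal state"
        ) from err
    if not np.all(np.isfinite(B)) or np.any(np.abs(B.sum(axis=1) - 1) > 1e-6):
        raise RuntimeError(
            "absorbing-chain solve failed: transient states cannot all reach "
            "a terminal state (recurrent non-terminal class)"
        )
    probs = np.zeros((n, len(terminals)))
    probs[trans] = np.clip(B, 0.0, 1.0)
    probs[terminals, np.arange(len(terminals))] = 1.0
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def differentiation_potential(branch_probs: np.ndarray) -> np.ndarray:
    """Entropy (natural log) of each cell's fate-probability row."""
    p = np.asarray(branch_probs, float)
    if np.any(p < -1e-12):
        raise ValueError("branch probabilities must be non-negative")
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=1)


def _reaches_terminal(chain: sp.csr_matrix, terminals: np.ndarray) -> np.ndarray:
    """Boolean mask of states with a directed path into the terminal set."""
    n = chain.shape[0]
    RT = sp.csr_matrix((chain.T > 0))
    reach = np.zeros(n, dtype=bool)
    reach[terminals] = True
    frontier = list(terminals)
    while frontier:
        nxt = []
        for t in frontier:
            preds = RT.indices[RT.indptr[t]:RT.indptr[t + 1]]
            new = preds[~reach[preds]]
            reach[new] = True
            nxt.extend(new.tolist())
        frontier = nxt
    return reach


def _fate_probabilities_robust(chain: sp.csr_matrix, terminals: np.ndarray,
                               ds: DiffusionSpace) -> np.ndarray:
    """Absorption probabilities tolerating stray boundary cells.

    Cells past the detected boundary that cannot reach any terminal along
    the directed chain (tiny recurrent pockets at branch tips) are treated
    as already absorbed in their nearest terminal by multi-scale distance;
    everything else follows the exact fundamental-matrix solve.
    """
    chain = sp.csr_matrix(chain)
    terminals = np.asarray(terminals, dtype=int)
    reach = _reaches_terminal(chain, terminals)
    stray = np.flatnonzero(~reach)
    if stray.size == 0:
        return branch_probabilities(chain, terminals)
    u = ds.multiscale
    nearest = np.argmin(
        np.linalg.norm(u[stray][:, None, :] - u[terminals][None, :, :], axis=2),
        axis=1)
    absorbing = np.concatenate([terminals, stray])
    probs_ext = branch_probabilities(chain, absorbing)
    probs = probs_ext[:, : len(terminals)].copy()
    # redistribute stray-absorption mass to the stray cells' nearest terminals
    for s_local, t_local in zip(range(len(stray)), nearest):
        probs[:, t_local] += probs_ext[:, len(terminals) + s_local]
    probs[stray] = 0.0
    probs[stray, nearest] = 1.0
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


class FateModel(BaseEstimator):
    """End-to-end trajectory fit on a low-dimensional embedding.

    Builds the k-NN graph and adaptive affinity kernel, the diffusion map,
    shortest-path pseudotime from an (anchored) start cell, the directed
    Markov chain, terminal states and absorption probabilities.

    Parameters
    ----------
    k : neighbors for the graph (default 50).
    n_eigs : eigenpairs computed for the diffusion map.
    n_waypoints : waypoint count for pseudotime refinement (0 = plain
        shortest-path ordering, the default).
    terminal_eps : outgoing-mass threshold for automatic terminal detection.
    """

    def __init__(self, k: int = 50, n_eigs: int = 20, n_waypoints: int = 0,
                 terminal_eps: float = 1e-3, anchor_start: bool = True,
                 random_state: int = 0):
        self.k = k
        self.n_eigs = n_eigs
        self.n_waypoints = n_waypoints
        self.terminal_eps = terminal_eps
        self.anchor_start = anchor_start
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, start_cell: int = 0,
            terminal_states=None):
        X = np.asarray(X, float)
        k = min(self.k, X.shape[0] - 1)
        g = knn_graph(X, k=k)
        aff = adaptive_affinity(g)
        dm = DiffusionMap(n_eigs=self.n_eigs).fit(aff)
        ds = dm.space()
        start = (anchor_start_cell(ds, start_cell)
                 if self.anchor_start else int(start_cell))
        # pseudotime and the directed chain live on the multi-scale embedding,
        # where noise is integrated out and branches are well separated
        g_ms = knn_graph(ds.multiscale, k=k)
        aff_ms = adaptive_affinity(g_ms)
        pt = compute_pseudotime(g_ms, start, n_waypoints=self.n_waypoints,
                                seed=self.random_state)
        chain = directed_markov_chain(aff_ms, pt)
        terms = detect_terminal_states(chain, ds, pt, user_terminals=terminal_states,
                                       eps=self.terminal_eps, start=start)
        probs = _fate_probabilities_robust(chain, terms, ds)
        self.graph_ = g
        self.affinity_ = aff
        self.diffusion_ = ds
        self.start_cell_ = start
        self.pseudotime_ = pt
        self.terminal_states_ = terms
        self.branch_probs_ = probs
        self.diff_potential_ = differentiation_potential(probs)
        return self

    def result(self) -> TrajectoryFit:
        return TrajectoryFit(
            pseudotime=self.pseudotime_,
            terminal_states=self.terminal_states_,
            terminal_labels=[f"terminal_{i}" for i in self.terminal_states_],
            branch_probs=self.branch_probs_,
            diff_potential=self.diff_potential_,
        )
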