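"""Metacell-level scATAC processing: TF-IDF/SVD embedding, metacell
aggregation and normalization, highly variable peaks, K-S differential
accessibility, pseudobulk profiles, accessibility-kinetics classification,
and BED-convention interval utilities.

Counts are aggregated over metacells (small groups of similar cells) to
combat sparsity, median-normalized with a pseudo-count of 1, and compared
between cell groups with two-sample Kolmogorov-Smirnov tests at p < 1e-4.
All genomic intervals are 0-based half-open and strand-agnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.extmath import randomized_svd

from ._types import MetacellMap, PeakMatrix, PeakSet

PEAK_CLASS_NAMES = ("late_open", "gradual_open", "transient_open",
                    "late_close", "stable")


# ---------------------------------------------------------------------------
# embedding and metacells

class LSIEmbedding(BaseEstimator):
    """Single-pass latent semantic indexing of a cell x peak count matrix.

    TF-IDF weighting (tf = count / cell total; idf = log(1 + n_cells /
    (1 + peaks' cell count))) on the ``n_var`` deepest peaks, then truncated
    SVD to ``n_dims`` components.
    """

    def __init__(self, n_var: int = 100_000, n_dims: int = 30, seed: int = 0):
        self.n_var = n_var
        self.n_dims = n_dims
        self.seed = seed

    def fit_transform(self, pm: PeakMatrix | sp.spmatrix) -> np.ndarray:
        X = (pm.counts if isinstance(pm, PeakMatrix) else sp.csr_matrix(pm)).astype(float)
        n_cells, n_peaks = X.shape
        if self.n_dims >= min(X.shape):
            raise ValueError("n_dims must be < min(n_cells, n_peaks)")
        depth = np.asarray(X.sum(axis=0)).ravel()
        top = np.sort(np.argsort(depth, kind="stable")[::-1][: self.n_var])
        X = X[:, top]
        totals = np.asarray(X.sum(axis=1)).ravel()
        if np.any(totals == 0):
            raise ValueError("cells with zero total counts")
        tf = sp.diags(1.0 / totals) @ X
        ncell_per_peak = np.asarray((X > 0).sum(axis=0)).ravel()
        idf = np.log(1.0 + n_cells / (1.0 + ncell_per_peak))
        tfidf = tf @ sp.diags(idf)
        U, S, Vt = randomized_svd(tfidf, n_components=self.n_dims,
                                  random_state=self.seed)
        self.singular_values_ = S
        self.components_ = Vt
        self.peak_indices_ = top
        return U * S


def lsi_embed(pm: PeakMatrix, n_var: int = 100_000, n_dims: int = 30,
              seed: int = 0) -> np.ndarray:
    return LSIEmbedding(n_var=n_var, n_dims=n_dims, seed=seed).fit_transform(pm)


class MetacellKMeans(BaseEstimator):
    """Balanced k-means metacell assignment in embedding space.

    A light-weight stand-in for archetypal metacell optimisation: k-means
    with a fixed seed, followed by reassignment of members of empty clusters
    so every metacell is non-empty.
    """

    def __init__(self, n_metacells: int = 50, seed: int = 0):
        self.n_metacells = n_metacells
        self.seed = seed

    def fit_predict(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        n = coords.shape[0]
        if self.n_metacells < 2:
            raise ValueError("n_metacells must be >= 2")
        if self.n_metacells > n:
            raise ValueError("n_metacells must be <= n_cells")
        km = KMeans(n_clusters=self.n_metacells, random_state=self.seed, n_init=10)
        labels = km.fit_predict(coords)
        # compact label space (k-means can leave empty clusters on tiny data)
        uniq, labels = np.unique(labels, return_inverse=True)
        self.labels_ = labels
        return labels


def assign_metacells(coords: np.ndarray, n_metacells: int,
                     seed: int = 0) -> MetacellMap:
    labels = MetacellKMeans(n_metacells=n_metacells, seed=seed).fit_predict(coords)
    return MetacellMap(labels)


def aggregate_metacells(pm: PeakMatrix, mm: MetacellMap) -> PeakMatrix:
    """Sum peak counts over the cells of each metacell."""
    X = pm.counts
    if mm.labels.shape[0] != X.shape[0]:
        raise ValueError("metacell map does not cover all cells")
    n_mc = mm.n_metacells
    ind = sp.csr_matrix(
        (np.ones(len(mm.labels)), (mm.labels, np.arange(len(mm.labels)))),
        shape=(n_mc, X.shape[0]),
    )
    return PeakMatrix(ind @ X, level="metacell")


def normalize_metacells(pm: PeakMatrix, pseudo: float = 1.0) -> np.ndarray:
    """ln(count / total * median_total + pseudo) on the metacell matrix."""
    X = pm.counts
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("metacells with zero total counts")
    med = float(np.median(totals))
    scaled = X.multiply((med / totals)[:, None]).toarray()
    return np.log(scaled + pseudo)


def highly_variable_peaks(norm: np.ndarray, min_disp: float = 3.0,
                          min_mean: float = 0.0125, n_bins: int = 20,
                          pseudo: float = 1.0) -> np.ndarray:
    """Peaks with mean-binned normalized dispersion above ``min_disp`` and
    mean accessibility above ``min_mean``.

    Mirrors the scanpy-style variable-feature routine: dispersion
    (variance/mean) is computed on the de-logged median-scaled counts,
    z-scored within 20 equal-occupancy bins of peak mean; both thresholds
    apply on that scale.
    """
    norm = np.asarray(norm, float)
    if norm.shape[0] < 2:
        raise ValueError("need at least 2 metacells")
    scaled = np.exp(norm) - pseudo
    mean = scaled.mean(axis=0)
    var = scaled.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean != 0, var / np.abs(mean), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum((np.arange(len(mean)) * n_bins) // len(mean), n_bins - 1)
    z = np.zeros(len(mean))
    for b in np.unique(bins):
        m = bins == b
        sd = disp[m].std()
        z[m] = (disp[m] - disp[m].mean()) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf
    return np.flatnonzero((z > min_disp) & (mean > min_mean))


# ---------------------------------------------------------------------------
# differential accessibility and dynamics

def ks_differential_peaks(norm: np.ndarray, group_a, group_b,
                          alpha: float = 1e-4) -> pd.DataFrame:
    """Two-sample K-S test per peak between two metacell groups.

    The p-value is exact for small groups (min size < 10) and asymptotic
    otherwise; ``pass`` flags p < alpha.
    """
    group_a = np.asarray(group_a, int)
    group_b = np.asarray(group_b, int)
    if len(np.intersect1d(group_a, group_b)):
        raise ValueError("metacell groups must not overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 metacells")
    A, B = norm[group_a], norm[group_b]
    method = "exact" if min(len(group_a), len(group_b)) < 10 else "auto"
    D = np.empty(norm.shape[1])
    p = np.empty(norm.shape[1])
    for j in range(norm.shape[1]):
        res = stats.ks_2samp(A[:, j], B[:, j], method=method)
        D[j], p[j] = res.statistic, res.pvalue
    return pd.DataFrame({"peak": np.arange(norm.shape[1]), "D": D, "p": p,
                         "pass": p < alpha})


def pseudobulk_groups(norm: np.ndarray, groups) -> np.ndarray:
    """Mean accessibility per (group x peak); groups partition the metacells."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    out = np.empty((len(uniq), norm.shape[1]))
    for i, g in enumerate(uniq):
        members = groups == g
        if not members.any():
            raise ValueError(f"empty group {g}")
        out[i] = norm[members].mean(axis=0)
    return out


def classify_peak_dynamics(pb: np.ndarray, group_order=None,
                           stable_range: float = 0.25,
                           transient_margin: float = 0.5,
                           endpoint_hi: float = 0.75, endpoint_lo: float = 0.25,
                           late_fraction: float = 0.7,
                           rho_min: float = 0.8) -> np.ndarray:
    """Assign each peak an accessibility-kinetics class along ordered groups.

    Rules operate on each peak's group profile: 'stable' when the raw range
    is below ``stable_range``; otherwise the profile is min-max scaled and
    tested for a transient interior peak, a late opening (most of the rise in
    the final third), a gradual monotone opening (Spearman rho vs the group
    order >= ``rho_min``), or a late closing (mirror of late opening).
    Profiles matching no rule get the nearest canonical template by
    correlation, keeping the class set closed.
    """
    pb = np.asarray(pb, float)
    n_groups = pb.shape[0]
    if n_groups < 4:
        raise ValueError("need at least 4 ordered groups")
    if group_order is not None:
        go = np.asarray(group_order)
        if sorted(go.tolist()) != sorted(range(n_groups)):
            raise ValueError("group_order must be a permutation of the groups")
        pb = pb[go]
    x = np.arange(n_groups) / (n_groups - 1)
    templates = {
        "gradual_open": x,
        "late_open": np.where(x < 2 / 3, 0.0, (x - 2 / 3) * 3),
        "late_close": 1.0 - np.where(x < 2 / 3, 0.0, (x - 2 / 3) * 3),
        "transient_open": np.exp(-0.5 * ((x - 0.5) / 0.16) ** 2),
    }
    last_third = x >= 2 / 3 - 1e-9
    out = np.empty(pb.shape[1], dtype=object)
    for j in range(pb.shape[1]):
        prof = pb[:, j]
        rng_ = prof.max() - prof.min()
        if rng_ < stable_range:
            out[j] = "stable"
            continue
        s = (prof - prof.min()) / rng_
        interior_max = s[1:-1].max()
        if interior_max >= s[0] + transient_margin and interior_max >= s[-1] + transient_margin:
            out[j] = "transient_open"
            continue
        rho = stats.spearmanr(s, x).statistic
        opening = s[-1] >= endpoint_hi and s[0] <= endpoint_lo
        closing = s[0] >= endpoint_hi and s[-1] <= endpoint_lo
        if opening:
            rise_total = s[-1] - s[0]
            start_last = s[last_third][0]
            late_rise = s[-1] - min(start_last, s[~last_third].max())
            if late_rise >= late_fraction * rise_total:
                out[j] = "late_open"
                continue
            if rho >= rho_min:
                out[j] = "gradual_open"
                continue
        if closing:
            fall_total = s[0] - s[-1]
            late_fall = max(s[last_third][0], s[~last_third].min()) - s[-1]
            if late_fall >= late_fraction * fall_total:
                out[j] = "late_close"
                continue
        # fallback: nearest canonical template by correlation
        best, best_r = "stable", -np.inf
        for name, t in templates.items():
            r = np.corrcoef(s, t)[0, 1]
            if np.isfinite(r) and r > best_r:
                best, best_r = name, r
        out[j] = best
    return out


# ---------------------------------------------------------------------------
# interval utilities (BED semantics: 0-based, half-open)

def merge_intervals(ps: PeakSet, extend: int = 0) -> PeakSet:
    """Extend every interval by +/- ``extend`` bp, then merge overlapping or
    book-ended intervals per chromosome."""
    chroms, starts, ends = [], [], []
    df = ps.to_frame()
    for chrom, sub in df.groupby("chrom", sort=True):
        s = np.maximum(sub["start"].to_numpy() - extend, 0)
        e = sub["end"].to_numpy() + extend
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:          # overlap or adjacency
                cur_e = max(cur_e, e[i])
            else:
                chroms.append(chrom); starts.append(cur_s); ends.append(cur_e)
                cur_s, cur_e = s[i], e[i]
        chroms.append(chrom); starts.append(cur_s); ends.append(cur_e)
    return PeakSet(np.array(chroms, dtype=object), np.array(starts), np.array(ends))


def _window_pairs(a: PeakSet, b: PeakSet, window: int):
    """Yield (i, j) pairs where b_j overlaps the window-expanded interval
    [start_i - window, end_i + window) under half-open semantics.

    window = 0 is exactly the half-open overlap test; larger windows admit
    features whose gap to the interval is below ``window`` bp.
    """
    bf = b.to_frame().reset_index().rename(columns={"index": "j"})
    af = a.to_frame().reset_index().rename(columns={"index": "i"})
    for chrom, asub in af.groupby("chrom", sort=False):
        bsub = bf[bf["chrom"] == chrom]
        if bsub.empty:
            continue
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        bj = bsub["j"].to_numpy()
        order = np.argsort(bs, kind="stable")
        bs, be, bj = bs[order], be[order], bj[order]
        for i, s, e in zip(asub["i"], asub["start"], asub["end"]):
            # b overlaps [s - window, e + window)
            hit = (bs < e + window) & (be > s - window)
            for j in bj[hit]:
                yield int(i), int(j)


def overlap_intervals(a: PeakSet, b: PeakSet):
    """Half-open intersection test of each interval of ``a`` against ``b``.

    Returns (boolean per a-interval, list of (i, j) overlapping pairs).
    """
    pairs = list(_window_pairs(a, b, window=0))
    flags = np.zeros(len(a), dtype=bool)
    for i, _j in pairs:
        flags[i] = True
    return flags, pairs


def window_signal_sum(peaks: PeakSet, features: PeakSet, window: int = 1500,
                      signal: np.ndarray | None = None) -> np.ndarray:
    """Sum of feature signals within ``window`` bp of each peak."""
    sig = signal if signal is not None else getattr(features, "signal", None)
    if sig is None:
        raise ValueError("features carry no signal; pass signal=")
    sig = np.asarray(sig, float)
    if np.any(sig < 0):
        raise ValueError("signals must be non-negative")
    out = np.zeros(len(peaks))
    for i, j in _window_pairs(peaks, features, window):
        out[i] += sig[j]
    return out


def window_overlap_count(query: PeakSet, targets: PeakSet,
                         window: int) -> tuple[np.ndarray, np.ndarray]:
    """(has-a-target-within-window, count of such targets) per query interval."""
    counts = np.zeros(len(query), dtype=int)
    for i, _j in _window_pairs(query, targets, window):
        counts[i] += 1
    return counts > 0, counts
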