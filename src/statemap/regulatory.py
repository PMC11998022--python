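"""Regulatory-genomics layer: bias-corrected motif deviation scores with
GC/accessibility-matched backgrounds, Fisher region-set enrichment against an
atlas, and signal-window integration (CpG-island strength, TSS proximity).

The deviation score follows the chromVAR recipe: for motif m in metacell c,
the raw deviation is (observed - expected)/expected, where the expectation
distributes the metacell's total counts proportionally to each peak's share
of the dataset-wide count mass. The raw deviation is standardized against
``n_background`` resampled peak sets matched on (GC fraction, mean
accessibility) via a fixed 10 x 10 quantile grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._types import DeviationScores, MotifHits, PeakMatrix, PeakSet
from .atacmeta import overlap_intervals, window_overlap_count, window_signal_sum  # noqa: F401

__all__ = [
    "motif_deviation_scores", "regionset_enrichment",
    "window_signal_sum", "window_overlap_count",
]


def _background_bins(gc: np.ndarray, mean_acc: np.ndarray,
                     n_grid: int = 10) -> np.ndarray:
    """Assign every peak to a cell of the (GC, mean accessibility) quantile grid."""
    def qbin(v):
        order = np.argsort(v, kind="stable")
        b = np.empty(len(v), dtype=int)
        b[order] = np.minimum((np.arange(len(v)) * n_grid) // len(v), n_grid - 1)
        return b
    return qbin(gc) * n_grid + qbin(mean_acc)


def _matched_sample(peaks: np.ndarray, bins: np.ndarray,
                    members_by_bin: dict, rng) -> np.ndarray:
    """Sample one background peak per foreground peak from its grid bin,
    without replacement within a bin while possible."""
    out = np.empty(len(peaks), dtype=int)
    for b in np.unique(bins[peaks]):
        mine = peaks[bins[peaks] == b]
        pool = members_by_bin[b]
        if len(pool) >= len(mine):
            out[np.isin(peaks, mine)] = rng.choice(pool, size=len(mine), replace=False)
        else:
            out[np.isin(peaks, mine)] = rng.choice(pool, size=len(mine), replace=True)
    return out


def motif_deviation_scores(pm: PeakMatrix, mh: MotifHits, ps: PeakSet,
                           n_background: int = 50, seed: int = 0) -> "DeviationScores":
    """Bias-corrected z-scores of motif-aggregated accessibility per metacell.

    Motifs with zero hit peaks get NaN scores and are flagged in
    ``undefined_motifs``.
    """
    X = pm.counts.astype(float).toarray()
    n_mc, n_peaks = X.shape
    if mh.hits.shape[0] != n_peaks or len(ps) != n_peaks:
        raise ValueError("peak matrix, motif hits, and peak set are misaligned")
    if ps.gc is None:
        raise ValueError("peak set carries no GC fractions")
    rng = np.random.default_rng(seed)

    totals_c = X.sum(axis=1)                     # per metacell
    mass = X.sum(axis=0)                         # per peak
    frac = mass / mass.sum()
    mean_acc = X.mean(axis=0)
    bins = _background_bins(ps.gc, mean_acc)
    members_by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    def raw_dev(peak_idx: np.ndarray) -> np.ndarray:
        O = X[:, peak_idx].sum(axis=1)
        E = totals_c * frac[peak_idx].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(E > 0, (O - E) / E, 0.0)

    H = mh.hits.tocsc()
    n_motifs = H.shape[1]
    z = np.full((n_mc, n_motifs), np.nan)
    raw = np.full((n_mc, n_motifs), np.nan)
    undefined = []
    for m in range(n_motifs):
        hit_peaks = H.indices[H.indptr[m]:H.indptr[m + 1]]
        if hit_peaks.size == 0:
            undefined.append(str(mh.motif_names[m]))
            continue
        obs = raw_dev(hit_peaks)
        raw[:, m] = obs
        bg = np.empty((n_background, n_mc))
        for it in range(n_background):
            bg[it] = raw_dev(_matched_sample(hit_peaks, bins, members_by_bin, rng))
        mu, sd = bg.mean(axis=0), bg.std(axis=0)
        sd[sd == 0] = 1.0
        z[:, m] = (obs - mu) / sd
    return DeviationScores(scores=z, motif_names=mh.motif_names,
                           n_background=n_background,
                           undefined_motifs=undefined, raw=raw)


def regionset_enrichment(query: PeakSet, universe: PeakSet, sets: dict,
                         p_max: float = 1e-3) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query region set against an atlas.

    Every universe region is classified by overlap with the query and with
    each named set; the 2x2 table is tested for enrichment (greater) and
    Benjamini-Hochberg-adjusted across sets.
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    in_query, _ = overlap_intervals(universe, query)
    rows = []
    for name, regions in sets.items():
        in_set, _ = overlap_intervals(universe, regions)
        a = int(np.sum(in_query & in_set))
        b = int(np.sum(in_query & ~in_set))
        c = int(np.sum(~in_query & in_set))
        d = int(np.sum(~in_query & ~in_set))
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"set": name, "n_overlap": a, "odds_ratio": odds, "p": p})
    tab = pd.DataFrame(rows)
    if len(tab):
        from statsmodels.stats.multitest import multipletests
        tab["q"] = multipletests(tab["p"], method="fdr_bh")[1]
        tab["significant"] = tab["p"] < p_max
    return tab
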