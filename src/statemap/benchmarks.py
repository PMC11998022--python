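"""Ground-truth benchmarks exercising the pipeline end to end.

Every function here regenerates its inputs from the synthetic-data module
(or from closed-form constructions), runs the public API, and returns plain
metric dictionaries. The test suite asserts on these metrics; the
reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy import stats

from . import atacmeta as am
from . import preprocess as pp
from . import synthdata as sd
from . import trajectory as tj
from . import trends as tr
from ._types import MotifHits, PeakMatrix
from .diffusion import diffusion_maps, markov_operator
from .graphkit import adaptive_affinity, knn_graph
from .pipeline import comparison_map
from .regulatory import motif_deviation_scores
from .trajectory import FateModel


# ---------------------------------------------------------------------------
# exact Markov-chain mathematics

def gambler_chain(N: int) -> sp.csr_matrix:
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = P[N, N] = 1.0
    for i in range(1, N):
        P[i, i - 1] = P[i, i + 1] = 0.5
    return sp.csr_matrix(P)


def gambler_ruin_benchmark(Ns=(4, 10, 25)) -> dict:
    """Absorption probabilities on the symmetric ruin chain vs the i/N law."""
    worst = 0.0
    worst_rowsum = 0.0
    for N in Ns:
        bp = tj.branch_probabilities(gambler_chain(N), [0, N])
        worst = max(worst, float(np.abs(bp[:, 1] - np.arange(N + 1) / N).max()))
        worst_rowsum = max(worst_rowsum, float(np.abs(bp.sum(axis=1) - 1).max()))
    return {"max_abs_error": worst, "max_rowsum_error": worst_rowsum}


def monte_carlo_agreement(seed: int = 0, n_states: int = 20,
                          n_walks: int = 100_000) -> dict:
    """Absorption probabilities vs simulated random walks on a random chain."""
    rng = np.random.default_rng(seed)
    P = rng.random((n_states, n_states)) ** 3
    P /= P.sum(axis=1, keepdims=True)
    terminals = [0, 1]
    bp = tj.branch_probabilities(sp.csr_matrix(P), terminals)
    start = n_states // 2
    Pabs = P.copy()
    Pabs[terminals] = 0.0
    Pabs[0, 0] = Pabs[1, 1] = 1.0
    cum = np.cumsum(Pabs, axis=1)
    states = np.full(n_walks, start)
    for _ in range(600):
        u = rng.random(n_walks)
        states = (u[:, None] > cum[states]).sum(axis=1)
    emp = np.array([(states == t).mean() for t in terminals])
    se = np.sqrt(np.maximum(bp[start] * (1 - bp[start]), 1e-12) / n_walks)
    return {"max_se_units": float(np.max(np.abs(emp - bp[start]) / se)),
            "expected": bp[start].tolist(), "empirical": emp.tolist()}


def entropy_benchmark() -> dict:
    bp = np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3], [0.5, 0.5, 0.0]])
    dp = tj.differentiation_potential(bp)
    err = np.abs(dp - [0.0, np.log(3), np.log(2)]).max()
    return {"max_abs_error": float(err)}


def spectral_benchmark(seed: int = 0) -> dict:
    """Eigenpairs of small diffusion operators vs dense decompositions."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in (10, 30, 50):
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        A = sp.csr_matrix(W)
        ds = diffusion_maps(A, n_eigs=min(8, n - 2))
        T = markov_operator(A).toarray()
        dense = np.sort(np.linalg.eigvals(T).real)[::-1]
        worst = max(worst, float(np.abs(
            ds.eigenvalues - dense[: len(ds.eigenvalues)]).max()))
    # 8-ring analytic cosine spectrum
    n = 8
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
    ds = diffusion_maps(sp.csr_matrix(W), n_eigs=n - 1)
    expect = np.sort(np.cos(2 * np.pi * np.arange(n) / n))[::-1]
    ring = float(np.abs(ds.eigenvalues - expect[: len(ds.eigenvalues)]).max())
    return {"max_dense_error": worst, "ring_error": ring}


# ---------------------------------------------------------------------------
# trajectory recovery on the default branching simulation

def trajectory_recovery(n_seeds: int = 20, seed0: int = 0) -> dict:
    detected, rhos, accs = 0, [], []
    for s in range(n_seeds):
        cfg = sd.default_conversion_config(seed=seed0 + s)
        ct, gt = sd.simulate_branching_trajectory(cfg)
        fm = FateModel(k=50).fit(pp.standard_embedding(ct),
                                 start_cell=int(np.argmin(gt.true_pseudotime)))
        term_seg = gt.true_segment[fm.terminal_states_]
        detected += sorted(term_seg) == ["T1", "T2", "T3"]
        rhos.append(stats.spearmanr(fm.pseudotime_,
                                    gt.true_pseudotime).statistic)
        committed = gt.true_terminal_fate != sd.UNDETERMINED
        pred = term_seg[np.argmax(fm.branch_probs_, axis=1)]
        accs.append(float(np.mean(pred[committed] ==
                                  gt.true_terminal_fate[committed])))
    return {"terminal_detection_rate": detected / n_seeds,
            "mean_pseudotime_spearman": float(np.mean(rhos)),
            "min_pseudotime_spearman": float(np.min(rhos)),
            "mean_fate_accuracy": float(np.mean(accs)),
            "min_fate_accuracy": float(np.min(accs))}


# ---------------------------------------------------------------------------
# in-vivo / in-vitro bin mapping

def mapping_benchmark(n_seeds: int = 2, seed0: int = 0) -> dict:
    """Map linear conversions (built from the shared EPI/PrE programs, no
    progenitor program) onto embryo-like references; score how many query
    bins land on ground-truth-consistent lineages and how many on the
    progenitor (ICM) bins."""
    match, icm, total = 0, 0, 0
    for s in range(n_seeds):
        ccfg = sd.default_conversion_config(
            topology=sd.linear_topology(), seed=seed0 + 100 + s,
            n_cells_per_timepoint=200)
        ct_q, gt_q = sd.simulate_branching_trajectory(ccfg)
        ct_r, gt_r = sd.simulate_reference_embryo(
            seed=seed0 + 200 + s, n_cells_per_timepoint=250)
        res = comparison_map(
            ct_r, ct_r.cell_meta["lineage"].to_numpy(), ct_q,
            n_bins=20, k=30, seed=seed0,
            start_ref=int(np.argmin(gt_r.true_pseudotime)),
            start_query=int(np.argmin(gt_q.true_pseudotime)))
        mapping = res["mapping"]
        bins_q = res["bins_query"]
        for _, row in mapping.iterrows():
            cells = bins_q.bin_ids == row["bin_a"]
            mean_pt = gt_q.true_pseudotime[cells].mean()
            lab = row["mapped_label_b"]
            icm += lab == "ICM"
            if mean_pt < 0.4:
                match += lab in ("PrE", "VE", "ParE")
            elif mean_pt > 0.6:
                match += lab == "EPI"
            else:                       # genuinely intermediate bins
                match += lab in ("PrE", "VE", "ParE", "EPI")
            total += 1
    return {"bin_match_fraction": match / total,
            "icm_bin_fraction": icm / total, "n_bins_scored": total}


# ---------------------------------------------------------------------------
# statistical calibration

def ranksum_type1(seed: int = 0, n_genes: int = 2000, n_reps: int = 50,
                  cells_per_group: int = 100, alpha: float = 0.01) -> dict:
    """Null calibration of the rank-sum DE p-values on normalized values."""
    rng = np.random.default_rng(seed)
    hits, total = 0, 0
    for _ in range(n_reps):
        X = rng.negative_binomial(2, 2 / 7, size=(2 * cells_per_group,
                                                  n_genes)).astype(float)
        totals = X.sum(axis=1)
        V = np.log(X / totals[:, None] * np.median(totals) + 0.1)
        res = stats.mannwhitneyu(V[:cells_per_group], V[cells_per_group:],
                                 axis=0, alternative="two-sided")
        hits += int((res.pvalue < alpha).sum())
        total += n_genes
    rate = hits / total
    sd3 = 3 * np.sqrt(alpha * (1 - alpha) / total)
    return {"empirical_rate": rate, "nominal": alpha, "three_sd": sd3,
            "n_tests": total}


def ks_type1(seed: int = 0, n_peaks: int = 100_000,
             per_group: int = 50, alpha: float = 1e-4) -> dict:
    """Null calibration of the K-S differential-accessibility tail."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * per_group, n_peaks))
    tab = am.ks_differential_peaks(X, np.arange(per_group),
                                   np.arange(per_group, 2 * per_group),
                                   alpha=alpha)
    n_hits = int(tab["pass"].sum())
    lam = alpha * n_peaks
    lo, hi = stats.poisson.ppf(0.005, lam), stats.poisson.ppf(0.995, lam)
    return {"n_hits": n_hits, "expected": lam,
            "poisson99_lo": float(lo), "poisson99_hi": float(hi)}


# ---------------------------------------------------------------------------
# planted-structure recovery

def hvg_recall(n_seeds: int = 20, seed0: int = 0) -> float:
    from ._types import CellTable
    import pandas as pd
    recalls = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        n_cells, n_genes = 300, 800
        mu = rng.gamma(3, 1.5, n_genes) + 0.5
        counts = rng.negative_binomial(
            5.0, 5.0 / (5.0 + mu), size=(n_cells, n_genes)).astype(float)
        planted = rng.choice(np.flatnonzero(mu >= 2.0), 40, replace=False)
        for g in planted:
            r = mu[g] / 9
            counts[:, g] = rng.negative_binomial(r, r / (r + mu[g]), n_cells)
        ct = CellTable(sp.csr_matrix(counts),
                       pd.DataFrame({"timepoint": np.zeros(n_cells, int)}),
                       np.array([f"g{i}" for i in range(n_genes)], dtype=object))
        sel = pp.select_hvg(pp.normalize_expression(ct), n=60)
        recalls.append(len(set(sel) & set(planted)) / len(planted))
    return float(np.mean(recalls))


def hvp_recall(n_seeds: int = 10, seed0: int = 0) -> float:
    recalls = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        n_mc, n_pk = 200, 2000
        mu = rng.gamma(4, 8, n_pk)
        counts = rng.poisson(mu, size=(n_mc, n_pk)).astype(float)
        planted = rng.choice(n_pk, 50, replace=False)
        for p in planted:
            r = mu[p] / 40
            counts[:, p] = rng.negative_binomial(r, r / (r + mu[p]), n_mc)
        norm = am.normalize_metacells(
            PeakMatrix(sp.csr_matrix(counts), level="metacell"))
        sel = am.highly_variable_peaks(norm)
        recalls.append(len(set(sel) & set(planted)) / 50)
    return float(np.mean(recalls))


def trend_cluster_ari(n_seeds: int = 10, seed0: int = 0) -> float:
    from sklearn.metrics import adjusted_rand_score
    shapes = [
        lambda t: 1 / (1 + np.exp(-(t - 0.25) / 0.05)),
        lambda t: 1 / (1 + np.exp(-(t - 0.75) / 0.05)),
        lambda t: 1 - t,
    ]
    aris = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        pt = rng.uniform(0, 1, 400)
        X, truth = [], []
        for i, f in enumerate(shapes):
            for _ in range(50):
                X.append(f(pt) + rng.normal(0, 0.1, 400))
                truth.append(i)
        ts = tr.fit_trends(np.array(X).T, pt, grid_size=150)
        labels = tr.cluster_trends(ts, seed=0)
        aris.append(adjusted_rand_score(truth, labels))
    return float(np.mean(aris))


def peak_class_recall(n_seeds: int = 5, seed0: int = 0) -> dict:
    per_class = {c: [] for c in sd.PEAK_CLASSES}
    for s in range(n_seeds):
        pm, _ps, _mh, gt = sd.simulate_peak_experiment(
            sd.SimConfig(seed=seed0 + s))
        norm = am.normalize_metacells(pm)
        pb = am.pseudobulk_groups(norm, gt.group_labels)
        classes = am.classify_peak_dynamics(pb)
        for cls in sd.PEAK_CLASSES:
            m = gt.peak_class == cls
            per_class[cls].append(float(np.mean(classes[m] == cls)))
    recalls = {c: float(np.mean(v)) for c, v in per_class.items()}
    recalls["min_class_recall"] = min(recalls.values())
    return recalls


def motif_benchmark(n_seeds: int = 10, seed0: int = 0) -> dict:
    elevated = 0
    for s in range(n_seeds):
        pm, ps, mh, gt = sd.simulate_peak_experiment(
            sd.SimConfig(seed=seed0 + s, n_peaks=400, n_metacells_per_group=15))
        dev = motif_deviation_scores(pm, mh, ps, n_background=50,
                                     seed=seed0 + s)
        i = list(mh.motif_names).index("planted_late_open")
        g = gt.group_labels
        elevated += dev.scores[g == g.max(), i].mean() > \
            dev.scores[g == g.min(), i].mean()
    # permutation null calibration
    pm, ps, _mh, _gt = sd.simulate_peak_experiment(
        sd.SimConfig(seed=seed0 + 999, n_peaks=400, n_metacells_per_group=15))
    rng = np.random.default_rng(seed0)
    H = (rng.random((len(ps), 60)) < 0.2).astype(np.int8)
    hits = MotifHits(sp.csr_matrix(H),
                     np.array([f"perm{i}" for i in range(60)], dtype=object))
    dev = motif_deviation_scores(pm, hits, ps, n_background=200, seed=seed0)
    return {"planted_elevated_fraction": elevated / n_seeds,
            "permuted_mean": float(np.nanmean(dev.scores)),
            "permuted_sd": float(np.median(np.nanstd(dev.scores, axis=0)))}


# ---------------------------------------------------------------------------
# exact combinatorial oracles

def fisher_exhaustive(margins=(10, 25, 50)) -> dict:
    worst, count = 0.0, 0
    for N in margins:
        for K in range(N + 1):
            for nq in range(N + 1):
                for k in range(max(0, nq + K - N), min(nq, K) + 1):
                    table = [[k, nq - k], [K - k, N - nq - K + k]]
                    p1 = stats.fisher_exact(table, alternative="greater")[1]
                    p2 = stats.hypergeom.sf(k - 1, N, K, nq)
                    worst = max(worst, abs(p1 - p2))
                    count += 1
    return {"max_abs_diff": worst, "n_tables": count}


def interval_oracle(seed: int = 0, n: int = 10_000) -> dict:
    """Overlap and merge vs vectorized brute force on random intervals."""
    rng = np.random.default_rng(seed)
    from ._types import PeakSet
    def rand_ps(n):
        chrom = np.array([f"chr{c}" for c in rng.integers(1, 4, n)], dtype=object)
        start = rng.integers(0, 1_000_000, n)
        return PeakSet(chrom, start, start + rng.integers(1, 5_000, n))
    a, b = rand_ps(n), rand_ps(n)
    flags, _pairs = am.overlap_intervals(a, b)
    mism = 0
    for chrom in set(a.chrom):
        ia = np.flatnonzero(a.chrom == chrom)
        ib = np.flatnonzero(b.chrom == chrom)
        bs, be = b.start[ib], b.end[ib]
        for lo in range(0, len(ia), 512):
            rows = ia[lo:lo + 512]
            hit = ((bs[None, :] < a.end[rows][:, None]) &
                   (be[None, :] > a.start[rows][:, None])).any(axis=1)
            mism += int((hit != flags[rows]).sum())
    merged = am.merge_intervals(a)
    # brute-force merge via sorted sweep per chromosome
    merge_mism = 0
    for chrom in set(a.chrom):
        ia = np.flatnonzero(a.chrom == chrom)
        order = np.argsort(a.start[ia], kind="stable")
        s, e = a.start[ia][order], a.end[ia][order]
        runs = []
        cs, ce = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= ce:
                ce = max(ce, e[i])
            else:
                runs.append((cs, ce))
                cs, ce = s[i], e[i]
        runs.append((cs, ce))
        mine = sorted((int(x), int(y)) for c, x, y in
                      zip(merged.chrom, merged.start, merged.end) if c == chrom)
        merge_mism += int(mine != sorted(runs))
    # aggregation conservation
    X = sp.csr_matrix(rng.poisson(2, size=(300, 80)))
    from ._types import MetacellMap
    mm = MetacellMap(rng.integers(0, 20, 300))
    agg = am.aggregate_metacells(PeakMatrix(X), mm)
    conserved = int(agg.counts.sum() == X.sum())
    return {"overlap_mismatches": mism, "merge_mismatches": merge_mism,
            "aggregation_conserved": conserved}
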