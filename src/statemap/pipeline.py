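"""End-to-end orchestration: synthetic inputs -> preprocessing -> trajectory
-> cross-trajectory comparison -> gene trends -> scATAC metacell stack ->
regulatory scores, with a JSON run manifest recording parameters, shapes,
wall times, and output checksums. Deterministic at a fixed seed."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import atacmeta, comparison, diffusion, graphkit, preprocess, regulatory, synthdata, trends
from .io import write_bed, write_matrix
from .trajectory import FateModel

log = logging.getLogger("statemap")

DEFAULT_CONFIG = {
    "n_cells_per_timepoint": 150,
    "n_genes": 200,
    "n_timepoints": 5,
    "dispersion": 2.0,
    "dropout": 0.1,
    "n_hvg": 100,
    "pca_var_frac": 0.85,
    "knn_k": 50,
    "n_bins": 20,
    "trend_grid": 200,
    "trend_radius": 0.025,
    "n_peaks": 600,
    "n_groups": 5,
    "n_metacells_per_group": 25,
    "hvp_min_disp": 2.0,
    "ks_alpha": 1e-4,
    "n_background": 25,
}

STAGES = ("simulate", "preprocess", "trajectory", "compare", "trends",
          "atac", "regulatory")


def _validate_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key '{key}'")
        cfg[key] = val
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir="statemap_run",
                 seed: int = 0, stages=None) -> dict:
    """Run the demo pipeline on synthetic data and return the manifest."""
    cfg = _validate_config(config)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "config": cfg, "stages": {}, "checksums": {}}
    state: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, seed, out, state)
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": sorted(p.name for p in out.glob(f"{stage}*")),
        }
        log.info("stage %s finished in %.2fs", stage,
                 manifest["stages"][stage]["seconds"])

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["checksums"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(cfg, seed, out, state):
    common = dict(
        n_cells_per_timepoint=cfg["n_cells_per_timepoint"],
        n_genes=cfg["n_genes"], n_timepoints=cfg["n_timepoints"],
        dispersion=cfg["dispersion"], dropout=cfg["dropout"],
    )
    c_branch = synthdata.default_conversion_config(seed=seed, **common)
    c_linear = synthdata.default_conversion_config(
        topology=synthdata.linear_topology(), seed=seed + 1, **common)
    c_embryo = synthdata.default_embryo_config(seed=seed + 2, **common)
    state["branch"] = synthdata.simulate_branching_trajectory(c_branch)
    state["linear"] = synthdata.simulate_branching_trajectory(c_linear)
    state["embryo"] = synthdata.simulate_reference_embryo(c_embryo)
    peak_cfg = synthdata.SimConfig(
        seed=seed + 3, n_peaks=cfg["n_peaks"], n_groups=cfg["n_groups"],
        n_metacells_per_group=cfg["n_metacells_per_group"])
    state["peaks"] = synthdata.simulate_peak_experiment(peak_cfg)
    write_matrix(state["branch"][0], out / "simulate_branch")
    write_matrix(state["linear"][0], out / "simulate_linear")
    write_matrix(state["embryo"][0], out / "simulate_embryo")
    write_bed(state["peaks"][1], out / "simulate_peaks.bed")


def _stage_preprocess(cfg, seed, out, state):
    for name in ("branch", "linear", "embryo"):
        ct, gt = state[name]
        ct = preprocess.filter_cells(ct)
        nm = preprocess.normalize_expression(ct)
        hvg = preprocess.select_hvg(nm, n=min(cfg["n_hvg"], ct.n_genes))
        nm_hvg = type(nm)(nm.values[:, hvg], nm.scale_factor, nm.pseudo_count,
                          nm.gene_names[hvg])
        coords = preprocess.pca_retain(nm_hvg, var_frac=cfg["pca_var_frac"])
        state[f"{name}_nm"] = nm
        state[f"{name}_pca"] = coords
        pd.DataFrame(coords).to_csv(out / f"preprocess_{name}_pca.tsv",
                                    sep="\t", index=False)


def _stage_trajectory(cfg, seed, out, state):
    ct, gt = state["branch"]
    coords = state["branch_pca"]
    start = int(np.argmin(gt.true_pseudotime[: coords.shape[0]]))
    fm = FateModel(k=min(cfg["knn_k"], coords.shape[0] - 1)).fit(
        coords, start_cell=start)
    state["fate_model"] = fm
    fit = fm.result()
    df = pd.DataFrame({"cell": np.arange(len(fit.pseudotime)),
                       "pseudotime": fit.pseudotime,
                       "diff_potential": fit.diff_potential})
    for lbl, col in zip(fit.terminal_labels, fit.branch_probs.T):
        df[lbl] = col
    df.to_csv(out / "trajectory_fit.csv", index=False)


def _stage_compare(cfg, seed, out, state):
    # map the linear in-vitro conversion onto the embryo-like reference
    ref_ct, ref_gt = state["embryo"]
    q_ct, q_gt = state["linear"]
    res = comparison_map(ref_ct, ref_ct.cell_meta["lineage"].to_numpy(), q_ct,
                         n_bins=cfg["n_bins"], k=min(30, q_ct.n_cells - 1),
                         seed=seed,
                         start_ref=int(np.argmin(ref_gt.true_pseudotime)),
                         start_query=int(np.argmin(q_gt.true_pseudotime)))
    res["mapping"].to_csv(out / "compare_bin_mapping.csv", index=False)
    state["bin_mapping"] = res["mapping"]


def _stage_trends(cfg, seed, out, state):
    fm = state["fate_model"]
    nm = state["branch_nm"]
    T = diffusion.markov_operator(fm.affinity_)
    imputed = diffusion.impute(T, nm.values, t=3)
    n_show = min(60, imputed.shape[1])
    ts = trends.fit_trends(imputed[:, :n_show], fm.pseudotime_,
                           grid_size=cfg["trend_grid"])
    labels = trends.cluster_trends(ts, radius=cfg["trend_radius"], seed=seed)
    pd.DataFrame({"gene": nm.gene_names[:n_show], "cluster": labels}
                 ).to_csv(out / "trends_clusters.csv", index=False)


def _stage_atac(cfg, seed, out, state):
    pm, ps, mh, gt = state["peaks"]
    norm = atacmeta.normalize_metacells(pm)
    hvp = atacmeta.highly_variable_peaks(norm, min_disp=cfg["hvp_min_disp"])
    groups = gt.group_labels
    pb = atacmeta.pseudobulk_groups(norm, groups)
    classes = atacmeta.classify_peak_dynamics(pb)
    first = np.flatnonzero(groups == groups.min())
    last = np.flatnonzero(groups == groups.max())
    ks = atacmeta.ks_differential_peaks(norm[:, hvp] if len(hvp) else norm,
                                        first, last, alpha=cfg["ks_alpha"])
    pd.DataFrame({"peak": np.arange(len(classes)), "class": classes,
                  "true_class": gt.peak_class}
                 ).to_csv(out / "atac_peak_dynamics.csv", index=False)
    ks.to_csv(out / "atac_ks_differential.csv", index=False)
    state["atac_norm"], state["atac_classes"] = norm, classes


def _stage_regulatory(cfg, seed, out, state):
    pm, ps, mh, gt = state["peaks"]
    dev = regulatory.motif_deviation_scores(
        pm, mh, ps, n_background=cfg["n_background"], seed=seed)
    pd.DataFrame(dev.scores, columns=dev.motif_names
                 ).to_csv(out / "regulatory_deviations.tsv", sep="\t", index=False)


def comparison_map(ct_ref, ref_lineage, ct_query, n_bins=20, k=30, seed=0,
                   start_ref: int = 0, start_query: int = 0,
                   n_hvg: int | None = None) -> dict:
    """Map a query (in-vitro) trajectory onto a reference (in-vivo) one.

    Both count tables are embedded in a joint PCA space built from the
    reference's variable genes; the per-dataset affinity blocks are stitched
    with mutual-nearest-neighbor edges into an augmented affinity matrix,
    whose diffusion space carries the bin-to-bin multi-scale distances.
    Reference bins are stratified by lineage label, so the mapping names the
    in-vivo state each query bin resembles.
    """
    from .diffusion import DiffusionMap

    if not np.array_equal(ct_ref.gene_names, ct_query.gene_names):
        raise ValueError("reference and query must share one gene panel")
    nm_r = preprocess.normalize_expression(ct_ref)
    nm_q = preprocess.normalize_expression(ct_query)
    if n_hvg is None:
        n_hvg = min(1500, max(2, ct_ref.n_genes // 2))
    hvg = preprocess.select_hvg(nm_r, n=min(n_hvg, ct_ref.n_genes))
    joint = np.vstack([nm_r.values[:, hvg], nm_q.values[:, hvg]])
    from ._types import NormalizedMatrix
    coords = preprocess.pca_retain(
        NormalizedMatrix(joint, nm_r.scale_factor, nm_r.pseudo_count,
                         nm_r.gene_names[hvg]))
    nr, nq = ct_ref.n_cells, ct_query.n_cells
    ref_coords, q_coords = coords[:nr], coords[nr:]
    kr = min(k, nr - 1)
    kq = min(k, nq - 1)
    aff_r = graphkit.adaptive_affinity(graphkit.knn_graph(ref_coords, k=kr))
    aff_q = graphkit.adaptive_affinity(graphkit.knn_graph(q_coords, k=kq))
    aug = graphkit.augment_affinity(
        [("reference", ref_coords, aff_r), ("query", q_coords, aff_q)],
        [("reference", "query")], k=k)
    ds = DiffusionMap(n_eigs=15).fit(aug).space()

    # per-trajectory pseudotime from each dataset's own graph
    g_r = graphkit.knn_graph(ref_coords, k=kr)
    g_q = graphkit.knn_graph(q_coords, k=kq)
    from .trajectory import compute_pseudotime
    pt_r = compute_pseudotime(g_r, start=start_ref)
    pt_q = compute_pseudotime(g_q, start=start_query)
    bins_r = comparison.pseudotime_bins(pt_r, n_bins=n_bins, stratify_by=ref_lineage)
    bins_q = comparison.pseudotime_bins(pt_q, n_bins=n_bins)
    bd = comparison.bin_distance_matrix(ds, bins_q, bins_r,
                                        idx_a=np.arange(nr, nr + nq),
                                        idx_b=np.arange(nr), seed=seed)
    mapping = comparison.map_bins(bd)
    return {"mapping": mapping, "bin_distance": bd, "diffusion": ds,
            "pt_query": pt_q, "pt_reference": pt_r,
            "bins_query": bins_q, "bins_reference": bins_r}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "trajectory": _stage_trajectory,
    "compare": _stage_compare,
    "trends": _stage_trends,
    "atac": _stage_atac,
    "regulatory": _stage_regulatory,
}
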