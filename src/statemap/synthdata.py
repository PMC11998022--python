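"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study design of a bidirectional lineage-conversion
experiment profiled by scRNA-seq and scATAC-seq:

* a linear conversion (ES-to-iXEN-like) with a single terminal state,
* a heterogeneous conversion (XEN-to-iPS-like) with three terminal states,
* an embryo-like reference trajectory with a bifurcating bipotent progenitor
  (ICM -> {EPI, PrE}, PrE -> {VE, ParE}) whose progenitor expression program
  is absent from the in-vitro conversions,
* metacell peak-count matrices whose accessibility follows designed
  opening/closing kinetics classes, and
* CpG-island-like signal tracks.

Expression model: each gene's log-mean is interpolated with a cubic
smoothstep along the cell's segment between the segment-start and segment-end
program levels; counts are negative binomial around exp(log-mean) and then
zeroed by an expression-independent Bernoulli dropout. Cells are sampled in
overlapping timepoint windows to mimic asynchronous collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._types import CellTable, GroundTruth, MotifHits, PeakMatrix, PeakSet

UNDETERMINED = "undetermined"

PEAK_CLASSES = ("late_open", "gradual_open", "transient_open", "late_close", "stable")


@dataclass(frozen=True)
class Segment:
    """One branch of the trajectory tree, spanning [lo, hi] in pseudotime."""

    name: str
    parent: str | None
    lo: float
    hi: float
    terminal: bool = False


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    ``program_matrix`` holds target log-expression at each segment's END
    (genes x segments); ``start_program`` is the root segment's starting
    level. Within a segment the log-mean follows a cubic smoothstep from the
    parent's end level to the segment's end level, so expression is
    continuous across branch points.
    """

    n_cells_per_timepoint: int = 600
    n_genes: int = 300
    topology: list = field(default_factory=list)
    program_matrix: np.ndarray | None = None      # genes x segments (end levels)
    start_program: np.ndarray | None = None       # genes (root start level)
    dispersion: float = 2.0
    dropout: float = 0.1
    n_timepoints: int = 5
    timepoint_overlap: float = 0.25
    seed: int = 0
    # peak-experiment parameters
    n_peaks: int = 2000
    n_groups: int = 5
    n_metacells_per_group: int = 25
    peak_depth: float = 40.0
    n_motifs: int = 10
    # methylation-track parameters
    n_islands: int = 17000

    def __post_init__(self):
        if self.n_cells_per_timepoint <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout rate must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


# ---------------------------------------------------------------------------
# topologies

def linear_topology() -> list[Segment]:
    """Single linear segment with one terminal state (ES-to-iXEN-like)."""
    return [Segment("conversion", None, 0.0, 1.0, terminal=True)]


def three_terminal_topology(branch_at: float = 0.4) -> list[Segment]:
    """A shared trunk splitting into terminal states T1, T2 and T3
    (XEN-to-iPS-like; T3 plays the role of the successful iPS end state)."""
    return [
        Segment("trunk", None, 0.0, branch_at),
        Segment("T1", "trunk", branch_at, 1.0, terminal=True),
        Segment("T2", "trunk", branch_at, 1.0, terminal=True),
        Segment("T3", "trunk", branch_at, 1.0, terminal=True),
    ]


def embryo_topology() -> list[Segment]:
    """ICM -> {EPI, PrE}; PrE -> {VE, ParE}."""
    return [
        Segment("ICM", None, 0.0, 1 / 3),
        Segment("EPI", "ICM", 1 / 3, 1.0, terminal=True),
        Segment("PrE", "ICM", 1 / 3, 2 / 3),
        Segment("VE", "PrE", 2 / 3, 1.0, terminal=True),
        Segment("ParE", "PrE", 2 / 3, 1.0, terminal=True),
    ]


def validate_topology(topology: list[Segment]) -> dict[str, Segment]:
    """Check parental structure; raise on orphans, cycles, span mismatches."""
    by_name = {s.name: s for s in topology}
    if len(by_name) != len(topology):
        raise ValueError("duplicate segment names")
    roots = [s for s in topology if s.parent is None]
    if len(roots) != 1:
        raise ValueError("topology must have exactly one root segment")
    children: dict[str, list[Segment]] = {s.name: [] for s in topology}
    for s in topology:
        if s.parent is not None:
            if s.parent not in by_name:
                raise ValueError(f"orphan segment '{s.name}': unknown parent '{s.parent}'")
            children[s.parent].append(s)
    # cycle / reachability check by walking up from every segment
    for s in topology:
        seen = {s.name}
        cur = s
        while cur.parent is not None:
            if cur.parent in seen:
                raise ValueError(f"cycle detected at segment '{s.name}'")
            seen.add(cur.parent)
            cur = by_name[cur.parent]
    for s in topology:
        if s.parent is not None and abs(s.lo - by_name[s.parent].hi) > 1e-9:
            raise ValueError(
                f"segment '{s.name}' starts at {s.lo} but parent ends at {by_name[s.parent].hi}"
            )
        if s.hi <= s.lo:
            raise ValueError(f"segment '{s.name}' has empty pseudotime span")
        if not children[s.name] and not s.terminal:
            raise ValueError(f"leaf segment '{s.name}' must be flagged terminal")
        if children[s.name] and s.terminal:
            raise ValueError(f"terminal segment '{s.name}' must not have children")
    return by_name


# ---------------------------------------------------------------------------
# gene programs

OFF, LOW, MID, ON = np.log(0.2), np.log(0.8), np.log(2.5), np.log(20.0)


def _gene_blocks(n_genes: int) -> dict[str, np.ndarray]:
    """Fixed partition of the gene panel into expression programs.

    The EPI and PrE programs are shared between the embryo reference and the
    in-vitro conversions; the ICM progenitor program is used only by the
    reference. Dead-end blocks mark the refractory T1/T2 states.
    """
    frac = {
        "epi": 0.20, "pre": 0.20, "icm": 0.12,
        "deadend1": 0.12, "deadend2": 0.12, "ve": 0.04, "pare": 0.04,
    }
    blocks, at = {}, 0
    for name, f in frac.items():
        size = max(3, int(round(f * n_genes)))
        blocks[name] = np.arange(at, min(at + size, n_genes))
        at += size
    blocks["housekeeping"] = np.arange(at, n_genes)
    if at >= n_genes:
        raise ValueError("n_genes too small for the program blocks (need >= 80)")
    return blocks


def _base_levels(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Gene-specific baseline log-level, mildly heterogeneous."""
    base = np.full(n_genes, LOW)
    base += rng.normal(0.0, 0.15, n_genes)
    return base


def _program_vector(base: np.ndarray, blocks: dict, on=(), off=(), half=()) -> np.ndarray:
    v = base.copy()
    for b in on:
        v[blocks[b]] = ON
    for b in half:
        v[blocks[b]] = MID
    for b in off:
        v[blocks[b]] = OFF
    return v


def default_conversion_config(topology=None, seed: int = 0, **kw) -> SimConfig:
    """SimConfig for an in-vitro conversion built from the shared EPI/PrE
    programs (ICM progenitor program off everywhere).

    Default topology is the three-terminal tree; pass ``linear_topology()``
    for the deterministic conversion.
    """
    topology = three_terminal_topology() if topology is None else topology
    cfg = SimConfig(topology=topology, seed=seed, **kw)
    by_name = validate_topology(topology)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    blocks = _gene_blocks(cfg.n_genes)
    base = _base_levels(cfg.n_genes, rng)
    hk = blocks["housekeeping"]
    base[hk] = MID + rng.normal(0, 0.2, hk.size)

    start = _program_vector(base, blocks, on=("pre",), off=("icm", "epi"))
    end_epi = _program_vector(base, blocks, on=("epi",), off=("icm", "pre"))
    inter = _program_vector(base, blocks, half=("pre", "epi"), off=("icm",))
    # refractory dead-end states: an aberrant identity program switches on
    # while both lineage programs stay at the intermediate level, so every
    # terminal lies at a comparable expression distance from the trunk end
    # (comparable path lengths keep pseudotime scales aligned across branches)
    dead1 = _program_vector(base, blocks, on=("deadend1",),
                            half=("pre", "epi"), off=("icm",))
    dead2 = _program_vector(base, blocks, on=("deadend2",),
                            half=("pre", "epi"), off=("icm",))

    prog = np.empty((cfg.n_genes, len(topology)))
    for j, s in enumerate(topology):
        if s.terminal and s.name in ("T3", "conversion"):
            prog[:, j] = end_epi
        elif s.name == "T1":
            prog[:, j] = dead1
        elif s.name == "T2":
            prog[:, j] = dead2
        else:                         # shared trunk ends at the intermediate state
            prog[:, j] = inter
    cfg.program_matrix, cfg.start_program = prog, start
    cfg._blocks = blocks
    return cfg


def default_embryo_config(seed: int = 0, **kw) -> SimConfig:
    """SimConfig for the embryo-like reference (progenitor program on ICM only)."""
    topology = embryo_topology()
    cfg = SimConfig(topology=topology, seed=seed, **kw)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    blocks = _gene_blocks(cfg.n_genes)
    base = _base_levels(cfg.n_genes, rng)
    hk = blocks["housekeeping"]
    base[hk] = MID + rng.normal(0, 0.2, hk.size)

    icm = _program_vector(base, blocks, on=("icm",), half=("epi", "pre"))
    epi = _program_vector(base, blocks, on=("epi",), off=("icm", "pre"))
    pre = _program_vector(base, blocks, on=("pre",), off=("icm", "epi"))
    ve = _program_vector(base, blocks, on=("pre", "ve"), off=("icm", "epi"))
    pare = _program_vector(base, blocks, on=("pre", "pare"), off=("icm", "epi"))

    ends = {"ICM": icm, "EPI": epi, "PrE": pre, "VE": ve, "ParE": pare}
    cfg.program_matrix = np.column_stack([ends[s.name] for s in topology])
    cfg.start_program = icm
    cfg._blocks = blocks
    return cfg


def progenitor_genes(cfg: SimConfig) -> np.ndarray:
    """Indices of the ICM progenitor program genes."""
    return cfg._blocks["icm"]


# ---------------------------------------------------------------------------
# expression simulation

def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _ease_out(u: np.ndarray) -> np.ndarray:
    # switch-like onset then slow maturation: derivative 2 at u=0, 0 at u=1
    return 1.0 - (1.0 - u) ** 2


def _path_to_root(seg: Segment, by_name: dict[str, Segment]) -> list[Segment]:
    path = [seg]
    while path[-1].parent is not None:
        path.append(by_name[path[-1].parent])
    return path[::-1]


def _segment_for(pt: float, path: list[Segment]) -> Segment:
    for s in path:
        if s.lo - 1e-12 <= pt <= s.hi + 1e-12:
            # prefer the deepest segment containing pt (boundary goes to child)
            chosen = s
    return chosen


def _timepoint_windows(n_timepoints: int, overlap: float) -> list[tuple[float, float]]:
    w = 1.0 / n_timepoints
    pad = overlap * w
    return [
        (max(0.0, i * w - pad), min(1.0, (i + 1) * w + pad))
        for i in range(n_timepoints)
    ]


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    # NB with mean mu and size r: var = mu + mu^2 / r
    r = dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_branching_trajectory(cfg: SimConfig) -> tuple[CellTable, GroundTruth]:
    """Simulate one conversion experiment from its segment tree and programs.

    Each cell draws a terminal fate uniformly over the leaves, a pseudotime
    uniformly within its timepoint window, and sits on the segment of its
    root-to-fate path containing that pseudotime. The committed-fate ground
    truth is the segment name on terminal segments and "undetermined" on
    shared trunks (a progenitor's fate is not yet decided).
    """
    by_name = validate_topology(cfg.topology)
    if cfg.program_matrix is None or cfg.start_program is None:
        raise ValueError("config carries no gene programs")
    if cfg.program_matrix.shape != (cfg.n_genes, len(cfg.topology)):
        raise ValueError("program_matrix must be genes x segments")
    rng = np.random.default_rng(cfg.seed)
    leaves = [s for s in cfg.topology if s.terminal]
    seg_index = {s.name: j for j, s in enumerate(cfg.topology)}
    paths = {leaf.name: _path_to_root(leaf, by_name) for leaf in leaves}
    windows = _timepoint_windows(cfg.n_timepoints, cfg.timepoint_overlap)

    n = cfg.n_cells_per_timepoint * cfg.n_timepoints
    pt = np.empty(n)
    seg_names = np.empty(n, dtype=object)
    fates = np.empty(n, dtype=object)
    tps = np.empty(n, dtype=np.int64)
    log_mu = np.empty((n, cfg.n_genes))

    i = 0
    for t, (lo, hi) in enumerate(windows):
        for _ in range(cfg.n_cells_per_timepoint):
            leaf = leaves[rng.integers(len(leaves))]
            p = rng.uniform(lo, hi)
            seg = _segment_for(p, paths[leaf.name])
            u = (p - seg.lo) / (seg.hi - seg.lo)
            start_level = (
                cfg.start_program if seg.parent is None
                else cfg.program_matrix[:, seg_index[seg.parent]]
            )
            end_level = cfg.program_matrix[:, seg_index[seg.name]]
            # root segments mature smoothly; post-branch segments commit
            # switch-like at the branch point, then mature gradually
            curve = _smoothstep if seg.parent is None else _ease_out
            log_mu[i] = start_level + curve(np.clip(u, 0, 1)) * (end_level - start_level)
            pt[i], seg_names[i], tps[i] = p, seg.name, t
            fates[i] = seg.name if seg.terminal else UNDETERMINED
            i += 1

    counts = _nb_counts(np.exp(log_mu), cfg.dispersion, rng)
    if cfg.dropout > 0:
        counts[rng.random(counts.shape) < cfg.dropout] = 0

    gene_names = np.array([f"gene{j:04d}" for j in range(cfg.n_genes)], dtype=object)
    archetype = _gene_archetypes(cfg)
    meta = pd.DataFrame({
        "timepoint": tps,
        "batch": 0,
        "true_pseudotime": pt,
        "true_segment": seg_names,
        "true_terminal_fate": fates,
    })
    ct = CellTable(sp.csr_matrix(counts), meta, gene_names,
                   mito=np.zeros(cfg.n_genes, dtype=bool))
    gt = GroundTruth(
        true_pseudotime=pt, true_segment=seg_names, true_terminal_fate=fates,
        gene_archetype=pd.Series(archetype, index=gene_names),
    )
    return ct, gt


def _gene_archetypes(cfg: SimConfig) -> np.ndarray:
    """Label each gene by its designed dynamic along the main path."""
    main_leaf = next(s for s in cfg.topology if s.terminal)
    by_name = {s.name: s for s in cfg.topology}
    seg_index = {s.name: j for j, s in enumerate(cfg.topology)}
    end = cfg.program_matrix[:, seg_index[main_leaf.name]]
    start = cfg.start_program
    delta = end - start
    lab = np.where(delta > 0.5, "up", np.where(delta < -0.5, "down", "flat"))
    return lab.astype(object)


def simulate_reference_embryo(cfg: SimConfig | None = None, seed: int = 0,
                              **kw) -> tuple[CellTable, GroundTruth]:
    """Simulate the embryo-like reference trajectory with lineage and stage labels.

    The ICM progenitor program is expressed only on the ICM segment; the
    conversion simulators keep it off everywhere, which is the planted truth
    behind the "the in-vitro route bypasses the bipotent progenitor" mapping
    property.
    """
    if cfg is None:
        cfg = default_embryo_config(seed=seed, **kw)
    names = {s.name for s in cfg.topology}
    if names != {"ICM", "EPI", "PrE", "VE", "ParE"}:
        raise ValueError("reference config must use the fixed embryo tree")
    prog = progenitor_genes(cfg)
    seg_index = {s.name: j for j, s in enumerate(cfg.topology)}
    for name in ("EPI", "PrE", "VE", "ParE"):
        if np.any(cfg.program_matrix[prog, seg_index[name]] > MID):
            raise ValueError("progenitor gene set overlaps a branch program")
    ct, gt = simulate_branching_trajectory(cfg)
    stages = ["E3.5", "E4.5", "E5.5", "E7.5", "E8.75"]
    ct.cell_meta["lineage"] = gt.true_segment
    ct.cell_meta["stage"] = [
        stages[min(t, len(stages) - 1)] for t in ct.cell_meta["timepoint"]
    ]
    return ct, gt


# ---------------------------------------------------------------------------
# scATAC peak experiment

def _class_profile(cls: str, x: np.ndarray) -> np.ndarray:
    """Designed accessibility level (0..1 scale) across ordered groups."""
    if cls == "stable":
        return np.full_like(x, 0.55)
    if cls == "gradual_open":
        return 0.05 + 0.95 * x
    if cls == "late_open":
        return 0.05 + 0.95 * _smoothstep(np.clip((x - 0.65) / 0.35, 0, 1))
    if cls == "late_close":
        return 1.0 - 0.95 * _smoothstep(np.clip((x - 0.65) / 0.35, 0, 1))
    if cls == "transient_open":
        return 0.05 + 0.95 * np.exp(-0.5 * ((x - 0.5) / 0.16) ** 2)
    raise ValueError(f"unknown peak class '{cls}'")


def simulate_peak_experiment(
    cfg: SimConfig,
) -> tuple[PeakMatrix, PeakSet, MotifHits, GroundTruth]:
    """Metacell x peak counts with planted accessibility-kinetics classes.

    Peaks are 501 bp intervals with sampled GC fraction; counts are Poisson
    around a per-group designed mean. One motif per planted class hits only
    peaks of that class; the remaining motifs hit random peaks.
    """
    if cfg.n_groups < 2:
        raise ValueError("need at least 2 ordered groups")
    rng = np.random.default_rng(cfg.seed)
    n_peaks, n_groups, per_group = cfg.n_peaks, cfg.n_groups, cfg.n_metacells_per_group

    # stable (constitutive-promoter-like) peaks dominate the library mass, so
    # median normalization is not distorted when the dynamic classes open/close
    probs = {"stable": 0.4, "late_open": 0.15, "gradual_open": 0.15,
             "transient_open": 0.15, "late_close": 0.15}
    classes = rng.choice(np.array(PEAK_CLASSES, dtype=object), size=n_peaks,
                         p=[probs[c] for c in PEAK_CLASSES])
    x = np.arange(n_groups) / (n_groups - 1)
    level = np.empty((n_peaks, n_groups))
    for cls in PEAK_CLASSES:
        m = classes == cls
        level[m] = _class_profile(cls, x)[None, :]
    # per-peak depth heterogeneity, correlated with GC for background-matching realism
    gc = rng.beta(5, 5, size=n_peaks)
    peak_depth = cfg.peak_depth * np.exp(rng.normal(0, 0.25, n_peaks) + 0.5 * (gc - 0.5))
    peak_depth[classes == "stable"] *= 5.0

    n_cells = n_groups * per_group
    groups = np.repeat(np.arange(n_groups), per_group)
    mu = level[:, groups].T * peak_depth[None, :] + 0.25   # metacells x peaks
    # classes are planted as RELATIVE profiles: scATAC measures composition,
    # so each metacell's designed mass is rescaled to a common total before
    # sampling (sequencing depth itself varies independently)
    mu *= (n_peaks * cfg.peak_depth * 0.55) / mu.sum(axis=1, keepdims=True)
    mu *= np.exp(rng.normal(0, 0.1, size=(n_cells, 1)))    # depth wobble
    counts = rng.poisson(mu)

    start = rng.integers(1_000, 100_000_000, size=n_peaks)
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 20, size=n_peaks)], dtype=object)
    ps = PeakSet(chrom, start, start + 501, gc=gc)

    hits = np.zeros((n_peaks, cfg.n_motifs), dtype=np.int8)
    motif_names = []
    for j, cls in enumerate(PEAK_CLASSES[: min(len(PEAK_CLASSES), cfg.n_motifs)]):
        members = np.flatnonzero(classes == cls)
        chosen = rng.choice(members, size=max(5, members.size // 2), replace=False)
        hits[chosen, j] = 1
        motif_names.append(f"planted_{cls}")
    for j in range(len(motif_names), cfg.n_motifs):
        hits[rng.random(n_peaks) < 0.15, j] = 1
        motif_names.append(f"random_{j}")

    pm = PeakMatrix(sp.csr_matrix(counts), level="metacell")
    mh = MotifHits(sp.csr_matrix(hits), np.array(motif_names, dtype=object))
    gt = GroundTruth(peak_class=classes)
    gt.group_labels = groups
    return pm, ps, mh, gt


def simulate_methylation_tracks(cfg: SimConfig) -> PeakSet:
    """Non-overlapping CpG-island-like intervals with non-negative signal.

    Returns a PeakSet with an attached ``signal`` array (enrichment strength).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_islands
    per_chrom = np.bincount(rng.integers(1, 20, size=n), minlength=20)[1:]
    chroms, starts, ends = [], [], []
    for c, k in enumerate(per_chrom, start=1):
        if k == 0:
            continue
        gaps = rng.integers(2_000, 50_000, size=k)
        widths = rng.integers(300, 3_000, size=k)
        s = np.cumsum(gaps + widths) - widths
        chroms.extend([f"chr{c}"] * k)
        starts.extend(s.tolist())
        ends.extend((s + widths).tolist())
    ps = PeakSet(np.array(chroms, dtype=object), np.array(starts), np.array(ends))
    ps.signal = rng.gamma(2.0, 2.0, size=len(ps))
    return ps
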