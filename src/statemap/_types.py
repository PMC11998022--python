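"""Core in-memory containers shared across the pipeline stages.

Conventions: count matrices are cells x features (scipy CSR or dense ndarray),
genomic intervals are 0-based half-open (BED), pseudotime lives in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class CellTable:
    """Cells x genes molecule counts with aligned per-cell metadata.

    cell_meta carries at least a ``timepoint`` column; synthetic data adds
    ground-truth columns. ``mito`` flags mitochondrial genes for QC filtering.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_names: np.ndarray
    mito: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"metadata rows ({len(self.cell_meta)}) do not match matrix rows "
                f"({self.counts.shape[0]})"
            )
        if self.counts.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length does not match matrix columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.mito is not None:
            self.mito = np.asarray(self.mito, dtype=bool)
            if self.mito.shape[0] != len(self.gene_names):
                raise ValueError("mito flag length does not match gene count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx) -> "CellTable":
        idx = np.asarray(idx)
        return CellTable(
            self.counts[idx],
            self.cell_meta.iloc[idx].reset_index(drop=True),
            self.gene_names,
            self.mito,
        )


@dataclass
class NormalizedMatrix:
    """ln((count / cell_total) * median_total + pseudo) expression values."""

    values: np.ndarray
    scale_factor: float
    pseudo_count: float
    gene_names: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class NeighborGraph:
    """Sparse cells x cells Euclidean distances to each cell's k nearest neighbors."""

    distances: sp.csr_matrix
    k: int

    def __post_init__(self):
        self.distances = _as_csr(self.distances)
        if self.distances.nnz and self.distances.data.min() < 0:
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.distances.shape[0]


@dataclass
class AffinityGraph:
    """Sparse symmetric non-negative cell-cell affinities in [0, 1].

    ``provenance`` records the edge sets merged in (within-dataset blocks and
    mutual-nearest-neighbor cross specifications).
    """

    weights: sp.csr_matrix
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = _as_csr(self.weights)
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("affinity matrix must be square")
        if abs(w - w.T).max() > 1e-12 if w.nnz else False:
            raise ValueError("affinity matrix must be symmetric")
        if w.nnz and w.data.min() < 0:
            raise ValueError("affinities must be non-negative")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class DiffusionSpace:
    """Eigen-structure of the diffusion operator plus multi-scale coordinates.

    multiscale[:, i] = psi_{i+1} * lambda_{i+1} / (1 - lambda_{i+1}) for the
    ``n_selected`` informative components (the trivial constant eigenvector is
    excluded).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_selected: int
    multiscale: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class TrajectoryFit:
    """Palantir-style fit: pseudotime, terminal states, fate probabilities, entropy."""

    pseudotime: np.ndarray
    terminal_states: np.ndarray
    terminal_labels: list
    branch_probs: np.ndarray
    diff_potential: np.ndarray

    def __post_init__(self):
        rs = self.branch_probs.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise ValueError("branch probability rows must sum to 1")


@dataclass
class BinPartition:
    """Equal pseudotime intervals (optionally stratified by a lineage label)."""

    bin_ids: np.ndarray          # per-cell bin id, -1 = unbinned
    bin_meta: pd.DataFrame       # columns: bin, pt_lo, pt_hi, label, n_cells
    n_bins: int


@dataclass
class BinDistance:
    """bins-of-A x bins-of-B mean multi-scale distances."""

    matrix: np.ndarray
    rows: pd.DataFrame
    cols: pd.DataFrame

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("bin distances must be finite")
        if self.matrix.min() < 0:
            raise ValueError("bin distances must be non-negative")


@dataclass
class TrendSet:
    """genes x grid fitted expression trends along pseudotime."""

    trends: np.ndarray
    grid: np.ndarray
    stderr: np.ndarray | None = None
    branch_weights: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.trends)):
            raise ValueError("fitted trends must be finite")


@dataclass
class PeakSet:
    """Genomic intervals (0-based half-open) with per-peak GC fraction."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start >= self.end):
            bad = int(np.flatnonzero(self.start >= self.end)[0])
            raise ValueError(f"interval {bad}: start >= end")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if np.any((self.gc < 0) | (self.gc > 1)):
                raise ValueError("GC fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def width(self) -> np.ndarray:
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start, "end": self.end}
        if self.gc is not None:
            d["gc"] = self.gc
        return pd.DataFrame(d)


@dataclass
class PeakMatrix:
    """(Meta)cells x peaks accessibility counts aligned to a PeakSet."""

    counts: sp.csr_matrix
    level: str = "cell"          # "cell" | "metacell"
    normalized: bool = False

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        if self.level not in ("cell", "metacell"):
            raise ValueError("level must be 'cell' or 'metacell'")
        if not self.normalized and self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class MotifHits:
    """Binary peaks x motifs hit indicators (motif scanning is upstream)."""

    hits: sp.csr_matrix
    motif_names: np.ndarray

    def __post_init__(self):
        self.hits = _as_csr(self.hits)
        if self.hits.nnz and not np.all(np.isin(self.hits.data, [0, 1])):
            raise ValueError("motif hits must be binary")
        self.motif_names = np.asarray(self.motif_names, dtype=object)
        if self.hits.shape[1] != len(self.motif_names):
            raise ValueError("motif_names length mismatch")


@dataclass
class DeviationScores:
    """Metacells x motifs bias-corrected accessibility z-scores."""

    scores: np.ndarray
    motif_names: np.ndarray
    n_background: int
    undefined_motifs: list = field(default_factory=list)
    raw: np.ndarray | None = None        # uncorrected (O - E)/E deviations

    def __post_init__(self):
        if self.n_background < 10:
            raise ValueError("need at least 10 background iterations")


@dataclass
class MetacellMap:
    """cell -> metacell assignment."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        sizes = np.bincount(self.labels)
        if np.any(sizes == 0):
            raise ValueError("every metacell must be non-empty")

    @property
    def n_metacells(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


@dataclass
class GroundTruth:
    """Planted truth attached to synthetic data.

    ``true_terminal_fate`` is the name of the terminal segment a cell is
    committed to; cells still on a shared (non-committed) trunk carry
    "undetermined".
    """

    true_pseudotime: np.ndarray | None = None
    true_segment: np.ndarray | None = None
    true_terminal_fate: np.ndarray | None = None
    gene_archetype: pd.Series | None = None
    peak_class: np.ndarray | None = None

    def __post_init__(self):
        if self.true_pseudotime is not None:
            pt = np.asarray(self.true_pseudotime, float)
            if pt.size and (pt.min() < -1e-12 or pt.max() > 1 + 1e-12):
                raise ValueError("true pseudotime must lie in [0, 1]")
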