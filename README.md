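# statemap

Trajectory analysis for bidirectional lineage-conversion experiments:
diffusion-map pseudotime with absorbing-Markov-chain fate probabilities,
mutual-nearest-neighbor augmented affinity graphs, cross-trajectory
pseudotime-bin mapping against an embryo-like reference, gene-trend
clustering along pseudotime, and a metacell scATAC-seq
accessibility-dynamics stack — together with seeded synthetic-data
generators that make the whole pipeline testable end to end against known
ground truth.

## Who this is for

Computational biologists studying cell-state conversions (reprogramming,
transdifferentiation) profiled by time-course scRNA-seq and scATAC-seq, who
want to ask: how many terminal states does a conversion have, how committed
is each cell and to which fate, does the in-vitro route retrace the in-vivo
developmental path or bypass intermediate states, which gene programs move
together, and how does chromatin accessibility open and close along the
way.

## The model

Cells are embedded by median-scaling normalization, variable-gene selection
and PCA (components explaining 85% of variance). A k-NN graph (k = 50)
becomes an affinity matrix through the adaptive anisotropic kernel
`a_ij = exp(-d_ij² / (σ_i σ_j))` with `σ_i` the distance to the
`l = k/3`-th neighbor, and the row-normalized operator `T = D⁻¹A` yields
diffusion components (eigengap-selected) and multi-scale coordinates
`ψ_i · λ_i/(1-λ_i)`.

Differentiation is an absorbing Markov chain on that embedding: pseudotime
is shortest-path distance from a start cell anchored to a diffusion
extremum; edges are oriented by an adaptive pseudotime window; terminal
states are boundary-absorbing extrema (merged by superlevel-set
connectivity); and each cell's branch probabilities are the absorption
probabilities `B = (I - Q)⁻¹ R`. The entropy of that row, `-Σ p ln p`, is
the cell's differentiation potential.

Trajectories are compared in a joint diffusion space built from per-dataset
affinity blocks stitched with mutual-nearest-neighbor edges: cells are cut
into 20 equal pseudotime bins (reference bins stratified by lineage), every
bin pair gets the mean multi-scale distance over its cell pairs, and each
query bin maps to its closest reference bin. Gene trends are penalized
cubic-spline fits (GCV-selected smoothing, optionally weighted by branch
probabilities) clustered on a correlation-radius graph (radius 0.025,
Louvain, clusters under 2 genes dropped). The scATAC stack aggregates
cells into metacells, median-normalizes (pseudo-count 1), selects highly
variable peaks (dispersion > 3.0, mean > 0.0125), tests differential
accessibility with two-sample Kolmogorov–Smirnov at p < 1e-4, classifies
accessibility kinetics (late/gradual/transient opening, late closing,
stable), scores transcription-factor motif activity with bias-corrected
deviations against GC/accessibility-matched backgrounds, and tests region
sets for Fisher enrichment against an atlas.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import numpy as np
from statemap import synthdata as sd, preprocess as pp, FateModel

cfg = sd.default_conversion_config(seed=7)           # 3-terminal conversion
cells, truth = sd.simulate_branching_trajectory(cfg)
coords = pp.standard_embedding(cells)                # normalize + HVG + PCA
model = FateModel(k=50).fit(
    coords, start_cell=int(np.argmin(truth.true_pseudotime)))
```

printing the fitted summary:

```
cells: 3000  PCA dims: 135  diffusion components: 4
terminal states: [2272, 2516, 2683] on segments: ['T2', 'T3', 'T1']
pseudotime Spearman rho vs truth: 0.919
argmax-fate accuracy (committed cells): 0.944
mean differentiation potential, first vs last pseudotime decile: 1.093 vs 0.056
```

The model finds exactly the three planted terminal states, one per branch
of the simulated tree. Pseudotime rank-agrees with the planted ordering
(ρ = 0.92). For cells past the branch point, the highest-probability fate
matches the planted fate 94% of the time. Differentiation potential starts
near ln 3 ≈ 1.10 (three open fates) and collapses toward 0 at the
trajectory ends — cells begin uncommitted and finish determined.

The same workflow runs from a shell:

```sh
statemap all --seed 7 --out run/     # simulate -> ... -> regulatory stages
```

which writes per-stage outputs (CSV/TSV/Matrix Market/BED) and a
`manifest.json` with parameters, wall times and output checksums.

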