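# Methods

`statemap` re-implements, as a tested library, the single-cell machinery
used to compare bidirectional lineage-conversion trajectories (a
XEN-to-iPS-like conversion with multiple terminal states and an
ES-to-iXEN-like deterministic conversion) with each other and with an
embryo-like in-vivo reference. This note records the models, the defaults
and why they were chosen, what the synthetic benchmark does and does not
demonstrate, and the numerically delicate choices.

## Trajectory model

Cells are embedded by median-scaling normalization (`ln(count/total ·
median_total + 0.1)`), dispersion-ranked variable-gene selection, and
centered PCA retaining the fewest components explaining 85% of variance. A
k-nearest-neighbor graph (k = 50, Euclidean) is converted to affinities with
the adaptive anisotropic kernel

    a_ij = exp(-d_ij^2 / (sigma_i * sigma_j)),    sigma_i = d(i, l-th NN),

with l = round(k/3) = 17 at the default k. The geometric-mean bandwidth
makes symmetrization natural; a per-cell variant `exp(-d^2/sigma_i^2)` with
transpose averaging is selectable. Affinities on the union of the two
directed neighborhoods are averaged as (A + Aᵀ)/2, so an edge present in
only one direction carries half weight.

The diffusion operator T = D⁻¹A is decomposed through its symmetric
conjugate D^{1/2}TD^{-1/2} (same spectrum; stable orthogonal
eigendecomposition; eigenvectors mapped back), with a dense solver below 200
cells and ARPACK above, started from a fixed vector for bit-reproducible
output. The number of informative components is the largest consecutive
eigengap among the non-trivial eigenvalues (at least 2 kept, since one
component cannot support multi-scale distances); a fixed count can be forced
(e.g. 14 for joint-embedding clustering). Multi-scale coordinates re-weight
eigenvector i by λ_i/(1−λ_i); Euclidean distance there integrates diffusion
distances over all scales. Imputation is T^t X with t = 3.

Differentiation is modeled as an absorbing Markov chain. Pseudotime is the
min-max-scaled shortest-path distance from a start cell snapped to the
nearest extremum of the diffusion components; optional waypoint refinement
(iteratively averaged waypoint perspectives, convergence 1e-3) is off by
default. **The chain itself lives on a k-NN graph built in multi-scale
diffusion coordinates**, not on raw PCA: integrating out sampling noise
there is what keeps branches separated where raw distances are at the noise
floor. Edges i→j survive iff pt_j ≥ pt_i − w_i with w_i the standard
deviation of pseudotime over i's neighbors (a per-cell adaptive backward
window); surviving rows are renormalized and empty rows become
self-absorbing.

Terminal states: candidates are the extrema of the multi-scale components,
locally hill-climbed (≤ 5 steps, restricted to neighbors within 10% of the
embedding span so a candidate cannot migrate across the trajectory) to the
pseudotime boundary of their own region; a candidate is kept iff its
outgoing mass toward higher pseudotime is below 1e-3 (boundary-absorbing),
and candidates in the start cell's region are excluded (the origin is not a
fate). Kept candidates merge by **superlevel-set connectivity**: two
candidates are one terminal region iff they connect through cells of no
lower pseudotime (tolerance 5% of the range). Absorbing pockets along a
branch merge into that branch's tip, while genuine terminal states stay
separate because any path between them dips through the branch point. Fate
probabilities are the absorption probabilities B = (I−Q)⁻¹R (dense solve
below 500 transient states, sparse LU above). A singular system is reported
as a recurrent non-terminal class; the high-level `FateModel` additionally
treats tiny recurrent pockets beyond the detected boundary as already
absorbed in their nearest terminal, which perturbs only those cells.
Differentiation potential is the natural-log entropy of each fate row.

## Cross-trajectory comparison

Two trajectories are compared in a joint diffusion space: a joint PCA over
the shared gene panel (variable genes taken from the reference), per-dataset
affinity blocks, and mutual-nearest-neighbor (k = 50) cross edges weighted
by the same adaptive kernel; cross edges use each endpoint's within-dataset
bandwidth, a choice this package makes and records. Stage-chain augmentation (successive timepoints plus extra
lineage-specific MNN sets, e.g. parietal-endoderm bridges) is expressible as
a list of cross specifications and is recorded verbatim in the graph's
provenance. Each trajectory is cut into 20 equal-width pseudotime intervals
(equal-count quantile bins available by flag; both readings of "equal
bins" are supported, equal-width being the default), reference bins further
stratified by lineage label. Every bin pair gets the mean multi-scale
distance over its cell pairs (uniformly subsampled above 250k pairs with a
fixed seed; the estimator stays unbiased), and each query bin maps to the
arg-min reference bin, ties toward the lower index.

Differential expression is a two-sided rank-sum test with
Benjamini–Hochberg correction and log-fold-change of group means on the
normalized scale — a stand-in for the published hurdle-model test, which is
out of scope. Signature scores are per-gene z-scores averaged over the set.
Clustering is PhenoGraph-style (k-NN graph re-weighted by neighbor-set
Jaccard, Louvain at resolution 1 by default; 3 reproduces the original
scRNA run) or seeded k-means on diffusion components (n_clusters = 30).

## Gene trends

Trends are penalized cubic B-spline (P-spline) fits of (imputed) expression
on pseudotime: 8 interior knots, second-difference penalty, per-gene GCV
over a λ grid of 10^{-4..4}. The basis is shared across genes, so each λ
costs one factorization for the whole panel — functionally the same
smoother class as classic GAM backends, ~100× faster at panel scale because
the factorizations are shared. Zero-weight cells provably have no leverage (tested by
deletion equivalence), so weighting by a terminal's branch probabilities
restricts a trend to that branch. Trends are z-scored (variance guard
1e-12), genes linked when correlation distance ≤ 0.025, affinity = 1 −
distance, Louvain with seed 0, clusters under 2 genes dropped.

## Metacell scATAC stack

Single-pass TF-IDF/SVD (LSI) embedding — tf = count/cell total, idf =
log(1 + n_cells/(1 + peak cell count)), randomized SVD to 30 dims over the
100k deepest peaks; the upstream toolkit iterates, one pass suffices here
and is a documented deviation. Metacells are balanced seeded k-means groups
in LSI space — a simplified stand-in for archetypal metacell optimization
(external assignments are accepted through I/O). Counts aggregate by sum
(conservation is asserted exactly), then median normalization with
pseudo-count 1. Variable peaks mirror the scanpy-style routine: dispersion
on the de-logged median-scaled counts, z-scored in 20 equal-occupancy mean
bins, thresholds 3.0 (dispersion) and 0.0125 (mean); the relaxed 2.0
threshold for cross-trajectory peak intersection is a parameter. The mean
threshold applies on the de-logged normalized scale, matching the
convention of the scanpy routine this mirrors.

Differential accessibility is a two-sample Kolmogorov–Smirnov test per peak
at p < 1e-4, exact below 10 metacells per group and scipy's automatic
exact/asymptotic switch above. Accessibility-kinetics classes (late/gradual/
transient opening, late closing, stable) are assigned from min-max-scaled
pseudobulk profiles with rule thresholds 0.25 (stable range), 0.5 (transient
margin), 0.75/0.25 (endpoints), 70% of the rise in the final third, and
Spearman ρ ≥ 0.8 for monotone opening; profiles matching no rule take the
nearest canonical template by correlation so the class set stays closed.
The kinetics categories are conventionally defined by eye; the operational
thresholds here are this package's and are all exposed.

Genomic intervals are 0-based half-open everywhere, strand ignored. Window
queries ("within w bp") test overlap against the window-expanded interval,
so w = 0 is exactly the half-open overlap test. Motif deviations follow the
chromVAR recipe: observed motif-aggregated counts vs the expectation that
distributes each metacell's total proportionally to peak mass, standardized
against 50 background draws matched on a fixed 10×10 (GC, mean
accessibility) quantile grid, sampled without replacement within a bin
while possible. Region-set enrichment is a one-sided Fisher test per set
over the universe, BH-adjusted, significant at p < 1e-3.

## Synthetic data: what it emulates and what it does not

The generators plant every structure the pipeline is asked to recover. A
trajectory is a tree of pseudotime segments; gene programs interpolate
between segment-endpoint log-levels with a cubic smoothstep on trunk
segments and an ease-out curve (derivative 2 at the branch point) on
post-branch segments — commitment is switch-like, then maturation slows,
which both matches how lineage decisions look in real data and makes the
committed-fate ground truth recoverable in principle. Counts are negative
binomial (dispersion r = 2, variance μ + μ²/r) with expression-independent
Bernoulli dropout (rate 0.1) on top; cells are sampled in 5 overlapping
timepoint windows (25% overlap) to mimic asynchronous collection. The
shared EPI and PrE endpoint programs (20% of the panel each) appear in both
the embryo-like reference (ICM → {EPI, PrE}, PrE → {VE, ParE}) and the
conversions; the ICM progenitor program (12%) is expressed only on the
reference's ICM segment, which is the constructed truth behind the
"conversions bypass the bipotent progenitor" mapping property. The two
dead-end terminal states activate aberrant identity programs of matched
amplitude so all terminals lie at comparable expression distance from the
shared intermediate — unequal path lengths would otherwise distort
cross-branch pseudotime ranks. A cell's fate ground truth is defined only
on terminal segments ("undetermined" on shared trunks): an uncommitted
progenitor has no determined fate, and fate-accuracy metrics are evaluated
over committed cells.

Peak experiments plant the five kinetics classes as **relative** profiles
(scATAC measures composition, not absolute mass), with stable
(constitutive-promoter-like) peaks carrying ~5× depth and 40% of loci so
that median normalization is not distorted when the dynamic classes open
and close; peaks are 501 bp with Beta(5,5) GC fractions mildly coupled to
depth, counts Poisson. One motif per class hits half of that class's peaks;
the remainder hit random peaks. CpG-island-like tracks are 17,000
non-overlapping intervals with gamma-distributed signal.

Not emulated: read-level error, doublets, ambient RNA, batch chemistry,
expression-dependent dropout, fragment-level ATAC structure, and real motif
sequence content. Passing the benchmark therefore demonstrates the
correctness of the algorithms on data whose generative assumptions are
known, not robustness to every artifact of real experiments.

Benchmark problem sizes — 3,000 cells × 300 genes per conversion
(20 seeds), 2,000 peaks × 125 metacells, 10⁵ null tests per calibration
check — were chosen as the smallest at which the recovery statistics
stabilize.

## Numerical choices and degenerate inputs

Zero bandwidths (duplicate points) are replaced by the smallest positive
bandwidth in the graph. k-NN ties break by ascending index. Eigenvector
signs are fixed by the largest-magnitude entry. The ARPACK start vector is
constant, randomized SVD and k-means are seeded, and Louvain uses a fixed
seed, so the full pipeline is checksum-deterministic at a fixed seed.
Zero-total cells or metacells, isolated graph vertices, unreachable cells,
empty terminal sets, overlapping K-S groups, and malformed BED lines all
raise errors naming the offending entity. Dispersion z-scores of
zero-variance features are −∞ so they can never be selected.

## Known limitations

Terminal-state detection assumes terminal regions are pseudotime-boundary
extrema of the diffusion embedding; terminal states buried in the interior
of the embedding (e.g. cycling end states) would be missed without a user
override. The rank-sum DE stand-in loses the hurdle model's explicit
zero-inflation treatment. Single-pass LSI and k-means metacells are
simplifications of the iterative and archetypal originals. Bin mapping
reports the nearest reference bin even when all reference bins are distant;
inspecting the mapped distances is advised.
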