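# Methods

This note records the models, conventions, and numerical choices behind
the package, in the order of the pipeline.

## Distances and the penalized reciprocal k-NN graph

Five direct dissimilarities are offered between time frames: Euclidean,
city-block, Chebychev, cosine, and correlation.  Correlation is kept in
the form 1 − Pearson *r* because of its ubiquity in functional
connectivity, even though that form violates the triangle inequality (the
square root would restore it); the violation is documented with a
counterexample in the test suite, and rows of zero variance (or zero
vectors under cosine) raise a degenerate-input error naming the row.

The geodesic metric builds the **PRKNNG**: an edge (i, j) exists when j is
among the *k* nearest neighbors of i *and* vice versa.  Reciprocity prunes
asymmetric links to outliers.  Distance ties are broken by lower index so
the construction is deterministic.  The reciprocal graph may be
disconnected; components are merged greedily — repeatedly bridging the
globally closest inter-component pair — with the penalized weight

    w_bridge = d · exp(d / d̄),

where *d* is the raw inter-component distance and *d̄* the mean weight of
the reciprocal edges.  The exponential makes shortcuts across genuinely
distant clusters expensive while normalization by *d̄* keeps the penalty
scale-free.  The exact penalty is a design choice of this package
(exposed as a `penalty` hook on `build_prknng`); the exponent is capped at
500 so extreme gaps stay finite, which preserves the ordering of bridges.
Geodesic distances are Dijkstra shortest paths on this graph; `weighted`
mode (default) sums edge weights, `hops` counts edges.  All distance
matrices are dense N × N: the intended data sizes (≈ 500–1,700 rows) make
sparse or approximate paths unnecessary.

## Lenses

Classical (Torgerson) MDS is implemented natively: double-center
−½·J·D²·J, take the top-*d* eigenpairs, scale eigenvectors by the root
eigenvalue.  Non-positive eigenvalues among the top *d* (a matrix not
realizable in Euclidean *d*-space) zero-fill their axis and record a
warning on the lens.  Spectral sign/rotation ambiguity is resolved in
tests by Procrustes alignment rather than by fixing a convention.

All other reducers are delegated through a registry that declares, per
algorithm, the input form ("pairwise distances" vs. "original data") and
whether it is stochastic (then a seed is mandatory, and fixed seed + fixed
input gives byte-identical output).  PCA, factor analysis, LDA, t-SNE,
Isomap, LLE, Hessian LLE, Laplacian eigenmaps and LTSA are scikit-learn;
UMAP is umap-learn.  Sammon mapping (gradient descent on Sammon stress
with backtracking, CMDS-initialized) and diffusion maps (eigenvectors of
the Markov-normalized Gaussian kernel, bandwidth = median squared
distance unless given) are small native backends, since no installed
library provides them.  Default lens dimension is 2.

The intrinsic lens skips embedding entirely: it wraps the PRKNNG and its
geodesic matrix, preserving local structure at the cost of requiring a
graph-native cover.

## Covers

**Extrinsic:** each lens dimension is split into *R* intervals whose
centers tile [min, max] at spacing s = range/R and whose width is
w = s/(1 − g/100), making the overlap between adjacent intervals exactly
g% of the interval width — an algebraic identity of the construction, not
an approximation.  Intervals are half-open except the last (right-closed),
so every point is covered and membership is unambiguous.  Bins are the
Cartesian products of intervals (R^d bins); empty bins are kept so bin
indexing is a pure function of (R, g).  Dimensions with zero range fall
back to a single full-width interval with a warning.  Only axis-aligned
rectangles are supported; a config requesting other polygon side counts is
rejected with a clear message.

**Intrinsic:** *R* landmarks are picked by farthest-point sampling on the
geodesic matrix (deterministic start at index 0 by default; seeded random
start available; ties by lowest index).  With 2ε the minimum pairwise
landmark distance, the bin of landmark x is {x_i : d_geo(x_i, x) ≤
4ε·g/100}.  Landmarks are pairwise ≥ 2ε apart by construction and each
belongs to its own bin for any positive gain.  Coverage is *not*
guaranteed at small gain; uncovered points are counted on the cover and
propagate into the coverage criterion β rather than being patched.

## Partial clustering

Clustering always uses the pipeline's original-space distance matrix (the
geodesic matrix when the geodesic metric is selected) — never lens
coordinates.

**Single linkage** uses the classic histogram-gap cutoff: merge heights
are histogrammed into `hist_bins` equal-width bins over [0, max height],
and the dendrogram is cut at the left edge of the first empty bin *that
follows a nonempty one*.  Skipping leading empty bins matters: when every
merge height exceeds the first bin's width, a literal "first empty bin"
rule would cut at 0 and shatter every bin into singletons, although no gap
separates anything.  No qualifying gap means one cluster.  Linkage mode
therefore partitions each bin exactly.

**DBSCAN** runs on the member submatrix with `min_pts` = 3 by default
(core point: ≥ 3 members within ε including itself).  Members are sorted
into canonical index order first, which makes border-point assignment
deterministic (first cluster in index order) and the result independent of
input ordering.  Noise points are dropped; the resulting loss of coverage
is deliberately visible to β.

## Shape graph, TCM, normalized degree

One node per cluster; an undirected edge joins two nodes exactly when
their member sets intersect (full linking; adjacent-bin-only linking and
the directed temporal variant are out of scope).  The temporal
connectivity matrix is binary: TCM[i, j] = 1 iff i and j co-occur in one
node or in adjacent nodes; the diagonal is 1 for covered points and
uncovered rows are zero.  The normalized degree is the off-diagonal row
mean, min-max scaled to [0, 1] (a constant series maps to zeros with a
warning); the scaling choice is recorded in the function contract since
only the bounded range is constrained by its downstream use.

## Validation: α, β, S

* β = percent of time points in the largest connected component.
* α = percent of nodes whose member *time span* — (max − min member
  index) × TR — exceeds τ = 11 s, the canonical hemodynamic response
  peak.  Span was chosen over dwell time or maximum gap as the single
  documented predicate (the notion "describes data points over the
  autocorrelation threshold" admits several readings); the predicate is
  one function and can be swapped.
* S = Shannon entropy (base 2) of the unit-width integer histogram of
  pairwise shortest-path *hop* distances between all node pairs of the
  largest component; a single-node graph scores 0.  Hop counts, base 2 and
  unit bins are this package's convention — the criterion only needs a
  consistent degeneracy scale.

Defaults: valid ⇔ α ≥ 15 ∧ β > 70 ∧ S ≥ 2.  All three thresholds are
arguments, not constants.

## Goodness-of-fit

**Circleness** (circular-trajectory data): nodes are majority-labeled by
their members' states, ties resolved by the fixed order stable-low <
transition-up < stable-high < transition-down.  The graph minus
transition-down nodes must contain a stable-low → stable-high path whose
interior is entirely transition-up with at least one interior node, and
symmetrically for the down arc.  A direct stable-low–stable-high edge does
not by itself fail the criterion (path existence is what is tested); a
`strict` mode that additionally fails such direct edges is available and
off by default.

**Transition extraction** (paradigm-style data): changepoints of the
normalized degree under the piecewise-constant-mean model, minimizing
total within-segment squared error by exact dynamic programming (O(K·T²)
with cumulative sums) — chosen over heuristic detectors so an exhaustive-
search oracle can certify it.  The changepoint count defaults to the
number of expected transitions (7 for the 8-segment schedules).  The
**average delay** is the mean over *expected* transition times of the
absolute gap to the nearest extracted time, so a missed transition
inflates the delay; an empty extraction scores +∞.  Pass if ≤ δ = 12 s
(δ is a parameter; 20 s is a config value, not a separate code path).

## Synthetic data

The generators are pure functions of (parameters, seed).

* **Coupling schedule:** [100 s low, 200 s ramp up, 100 s high, 200 s ramp
  down] × 2 = 1,200 s; sampled at TR 0.72 s from t = 0 inclusive, giving
  1,667 samples over 8 segments.  G ranges 1.1–5.0.
* **Task paradigm:** eight 180-s blocks with 12-s instruction periods
  between consecutive blocks (1,524 s = 25 min 24 s), TR 1.5 s.
* **Network simulator:** per node, an excitatory/inhibitory rate pair with
  sigmoid transfer; long-range input G(t)·Σ C_ij·S_E,j between excitatory
  populations on a seeded modular random connectome (66 nodes by
  default); Euler–Maruyama at dt = 0.05 s; excitatory activity convolved
  with a canonical double-gamma hemodynamic response and sampled at TR.
  The parameter defaults are this package's own phenomenological choices,
  tuned only for stable bistable-looking dynamics; no published parameter
  set is claimed, and no quantitative result here depends on its exact
  trajectories.
* **Circular generator:** two orthonormal attractor patterns in feature
  space; transitions interpolate between them along two arcs bowed apart
  by `arc_separation` (default 1.0) in a third orthogonal direction —
  noiselessly a closed loop with a preferred direction.  Defaults: 66
  features and additive Gaussian noise sd 0.1 (one tenth of the unit
  pattern scale), a clean-but-noisy regime.
* **Noise injection:** per feature, an equal-variance mix of
  linear+quadratic drift, AR(1) (φ = 0.8) and white noise, scaled so
  sd(noise) = sd(signal)/SNR.  "Amplitude" is read as the per-feature
  standard deviation; at SNR 0.5 the injected noise has exactly twice the
  signal's sd.
* **Downsampling:** boxcar moving average of 4 samples (edge-truncated,
  same length), then every N-th row; TR multiplied by N
  (1,667 rows → 556 at N = 3).
* **Block-shuffle null:** consecutive 7-frame blocks permuted by a seeded
  uniform permutation, within-block order preserved; the same seed yields
  the same permutation across matrices so a cohort can be shuffled
  coherently.

What the generators do *not* emulate: spatial autocorrelation between
parcels, physiological confounds, scanner drift nonstationarity, or
subject variability.  Tests passing on these data show the pipeline's
mechanics and its parameter-band behavior, not performance on real fMRI.

## Batch runner

Grid configs expand by Cartesian product over list-valued fields in a
fixed canonical field order, so expansion order is reproducible.  Each
(input × configuration) task derives its seed from a SHA-256 of
(master seed, input id, config hash), making results independent of pool
size and rerun-idempotent.  The config hash excludes the per-task seed —
it identifies the configuration, not the run.  Output layout:
`out/<input>/<config_hash>/{graph.json, graph.graphml, membership.csv,
stats.csv}` plus a manifest; failures are recorded per task without
aborting the cohort.  Preprocessing supports per-feature z-scoring only.

## Problem sizes in tests

The end-to-end tests run the circular dataset at the downsampled 556-row
variant and 200-point trefoils; the acceptance script additionally runs
the full 1,667-row default configuration.  These sizes are the package's
own test conditions; the pipeline itself is dense-matrix exact at any N
that fits memory.

## Known limitations

* The correlation metric's triangle-inequality violation means geodesic
  constructions on it inherit no metric guarantees (the PRKNNG is built
  from ranks, which are unaffected).
* Covers in more than 3 lens dimensions are unsupported (bin count grows
  as R^d).
* DBSCAN ε has no automatic selection; sweep it via the grid runner.
* The delay-based GOF assumes the expected transitions are known; on the
  circular dataset it is used only comparatively (structured vs. shuffled),
  where its absolute value is weakly constrained by the smooth degree
  profile.
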