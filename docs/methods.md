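# Methods

## The big-small patch statistic

The method asks, for every gene, whether the spatial expression surface
observed at a fine granularity persists at a coarse granularity. Expression
is first min-max normalized per gene to [0, 1]; constant genes map to all
zeros (they carry no spatial information and receive p = 1). Coordinates are
multiplied by the density scale `s = (M / V)^(1/d)`, where V is the measure
of the axis-aligned bounding rectangle (2D) or cuboid (3D), so one unit of
distance is roughly one spot spacing regardless of the assay's physical
units. The square root applies in 2D and the cube root in 3D — the unique
exponent making the rescaling density-normalizing. A coordinate with zero
range (a single plane passed as 3D) is dropped with a warning, since it
contributes nothing to the sample's volume.

For radius D, spot i's patch is the set of spots within Euclidean distance
strictly less than D. Two granularities are used: D1 = 1 (nearest
neighbors) and D2 = 3 (a coarse neighborhood), in normalized units. The
local mean of gene j over each patch smooths the surface; σ_D(j) is the
population variance (divide by M) of the M local means. The estimator
divisor is immaterial because only the ratio of two such variances is used.
The score contrasts the granularities after putting both variance columns on
a common scale:

    r(j) = (σ_D2(j) / max_j σ_D2) / (σ_D1(j) / max_j σ_D1)

Normalizing each column by its maximum over genes removes the intrinsic
scale of each granularity (coarse smoothing shrinks every variance by a
geometry factor) without coupling the score to any single gene's expression
variance; the alternative of multiplying the raw ratio by the per-gene
weight w_j = var_j / max_j var_j is available
(`BspConfig(weighting="expression_variance")`) but measurably degrades the
ranking, because w_j injects cross-gene sampling noise into a ratio that is
already scale-invariant. The w_j weights are still computed and reported in
the results table as a per-gene variance descriptor.

### Center-spot membership

With the strict set definition a spot is not a member of its own patch. The
pipeline nevertheless includes the center by default
(`BspConfig.include_center=True`): including it makes the local mean the
average over the closed neighborhood, so when a patch grows to cover the
whole sample all local means coincide and σ_D is exactly zero — the
degenerate-granularity limit the method's logic relies on — and no patch is
ever empty. The exclusive definition remains available
(`include_center=False`; low-level `build_patch_index` defaults to it), in
which case an isolated spot's local mean falls back to its own expression.
Patch construction uses a KD-tree but is exactly equivalent to an all-pairs
scan; ties at exactly distance D are excluded.

### Significance

The score population is summarized by a two-parameter beta distribution fit
by maximum likelihood (`scipy.stats.beta.fit` with location fixed at 0).
Because raw scores are unbounded, they are divided by `max(score)·(1+1e-9)`
first; a known support can be supplied explicitly, and a free location/scale
fit is available behind a flag. Zero scores are excluded from the fit and
assigned p = 1 directly. Each gene's p-value is the fitted upper-tail
probability of its rescaled score, hence non-increasing in the score.

When a panel has fewer than 1,000 genes the fit would be unstable, so
permutation-null genes are generated (each a without-replacement shuffle of
one real gene's values across spots, sources cycled) until the pool holds
10,000 scores; real and null genes are scored as one population so the
normalization constant is shared, and the beta is fit on the null part only.
A real gene may then score beyond the null maximum; its rescaled score is
clipped just inside the support so the p-value stays positive. With 1,000 or
more genes the fit is on all genes — SVGs are assumed a minority, and the
pure-null calibration test shows the tail rate of p < α matches α within
Monte-Carlo error at this regime.

Benjamini–Hochberg adjusted p-values are always reported; the default SVG
call uses the raw p-value at α = 0.05, with a switch to call on the adjusted
values.

## Moran's I baseline

Moran's I with spot-spot weights W, computed per gene, is the comparison
statistic. Weight schemes: binary radius (symmetric, strict inequality),
k-nearest-neighbor (directed), and inverse distance (dense, O(M²)); rows can
be standardized to sum to one. p-values are one-sided (positive
autocorrelation) by a seeded permutation test (999 permutations by default;
permutations are shared across genes, which leaves each gene's p-value valid
while making large panels tractable) or by the Cliff–Ord normal
approximation under the normality assumption. The power comparisons use
row-standardized kNN (k = 6) weights with analytic p-values: a radius-1
scheme leaves a few percent of 3D cells isolated (an error by contract), and
permutation p-values at feasible permutation counts produce thousand-gene
tie blocks that degrade realized-FDR resolution for the baseline.

## 2D simulator

Emulates the classic 260-spot array benchmark. Spots are uniform in the unit
square (or a grid); pattern geometries are parametric stand-ins with an
exact marked-spot count — one hotspot, two disjoint hotspots, or a diagonal
band — at a default marked fraction of 0.2, since the original benchmark's
regions come from a real tissue array that is not shipped; user-supplied
coordinates and masks reproduce any external geometry exactly. An SVG gene
follows log λ_i = log(base) + log(FC)·[i marked] + ε_i with ε_i ~ N(0, τ²)
and a Poisson draw from λ_i (a noiseless continuous mode exists for exact
unit tests); base intensity 10 keeps counts in a realistic range. Defaults
FC = 4, τ = 0.5 are the benchmark's medium setting (FC ∈ {3,4,5},
τ ∈ {0.2,0.5,0.8}). Each of the default 9,000 nulls is a spot-permutation of
one of the 1,000 SVGs (9 each), preserving value multisets exactly.

## 3D simulator

Ten sections of 225 cells each are placed by a uniform Poisson point pattern
in a 15 × 15 window — chosen so the per-section density is 1 cell per unit
area, making the normalized nearest-neighbor spacing ≈ 1 and the sphere
radii r ∈ {1.5, 2.0, 2.5} directly interpretable — and stacked with the
section index as z. The pattern is a union of spheres around the centers of
a random walk with fixed step length 2 and 10 steps (11 centers; enough to
mark a minority of the 2,250 cells at r = 2). Direction vectors are uniform
on the sphere with sign constraints: pattern I forces positive x and z
(curved stick), II positive z only (thin plate), III is unconstrained
(irregular lump). Constrained axes start near their low bound and never
reflect, which guarantees strict monotonicity; unconstrained axes start at
the window center and reflect at the bounds so the pattern stays in-sample.

Marked cells draw expression uniformly from the pool values above the
q-quantile of a reference pool, unmarked cells from the full pool. The
bundled pool is a synthetic log-normal(0, 1) sample standing in for an
empirical single-cell distribution; any observed value vector can be passed
instead, and `quantile_for_fold_change` solves the truncated-mean equation
by bisection so a target fold change can be requested for any pool. For the
default pool, q = 0.66/0.80/0.88 give marked/unmarked mean ratios of about
2/2.5/3. All SVGs in a replicate share one walk by default (one anatomical
structure driving many genes); a per-gene-walk mode exists. Each SVG spawns
9 permutation nulls from its noiseless values, then Gaussian noise with
standard deviation σ_mult times the average per-gene standard deviation is
added to the entire matrix, so nulls and SVGs carry identical noise.

### What the simulators do not emulate

Real capture-efficiency variation, segmentation errors, section-to-section
registration artifacts, count overdispersion beyond the Poisson/log-normal
models, and correlated gene modules. Passing benchmarks here demonstrates
the statistic's behavior under idealized spatial structure, not performance
on any particular assay.

## Evaluation

Power curves rank genes by ascending p-value; each prefix yields a realized
FDR (FP/(FP+TP)) and TPR, and the curve reports the best TPR over prefixes
within each FDR budget. Tied p-values enter as one block so curves are
independent of storage order. Realized (ground-truth) FDR is the default
x-axis, as is standard for labeled benchmarks; a BH-estimated-FDR mode is
provided for real-data use.

## Numerical choices

- Local-mean variance uses the shifted-data form (subtract the first row),
  which is algebraically identical and makes the identical-local-means case
  exactly zero instead of accumulating rounding noise.
- σ_D1 = 0 (constant gene or degenerate geometry) ⇒ score 0 and p = 1.
- Every stochastic step (simulators, permutation nulls, permutation tests)
  takes an explicit integer seed; fixed seeds reproduce byte-identical
  outputs.
- Problem sizes in the test suite are scaled-down replicates (e.g. 100 SVGs
  + 900 nulls × 5 replicates for the 3D power comparison; 10,000 genes for
  calibration), chosen to exercise each property at Monte-Carlo tolerances
  appropriate to those sizes.

## Known limitations

- The beta fit on all genes assumes SVGs are a minority; on panels where
  most genes are spatially patterned the null is inflated and calls become
  conservative.
- The statistic is unsigned: it flags pattern presence, not direction or
  shape, and cannot distinguish overlapping patterns.
- Binary-radius weight construction and patch building assume coordinates
  fit a KD-tree in memory; dense inverse-distance weights are O(M²) and
  intended for small samples only.
- D1 and D2 are fixed at 1 and 3 normalized units; strongly anisotropic
  spot layouts (e.g. z-spacing much larger than in-plane spacing after
  normalization) may warrant tuning.
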