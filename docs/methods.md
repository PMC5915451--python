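# Methods

This note documents the statistical conventions the package implements and
the design of the synthetic generator, including every place where a
genuinely open choice had to be made.

## Distance constructions

All five matrices are Euclidean distances between per-region feature
vectors, indexed by one shared, ordered region set.

* **Breeds** — within each livestock group, a region's heads are converted
  to breed proportions on the [0, 1] scale; the per-group sub-vectors are
  concatenated. A region with no animals in a group contributes a zero
  sub-vector for that group rather than being dropped, which keeps all
  feature vectors commensurable (and hence the geometry Euclidean) at the
  cost of treating "no animals" as "maximally unlike any nonzero
  composition" within that group. Proportion scale (0–1 vs 0–100) is
  irrelevant downstream: Mantel and MRM statistics are invariant to
  positive affine rescaling of any one matrix.
* **Human population** — per-surname regional frequency profiles are built
  from the count table; surnames need strictly more than `min_records`
  (default 20) records to be retained. A Kohonen self-organizing map
  (default 10×10 grid, 50 epochs, learning rate 0.5, initial radius = half
  the larger grid dimension, Gaussian neighborhood, exponential decay of
  both schedules with e-folding time = a quarter of the run, seeded and
  bit-reproducible) groups profiles as marker metadata. Monophyly is
  decided by a *concentration score*: the largest single-region share of
  the profile (an optional nearest-neighbor extension exists but is off by
  default because no adjacency rule is part of the input). Surnames at or
  above the threshold (default 0.5) are monophyletic with origin = argmax
  region; the rest are polyphyletic and excluded. The human distance is
  then the Euclidean distance between the regions' *compositions* over
  retained surnames (each region's retained-surname counts normalized to
  sum 1). Relative frequencies were chosen over presence/absence or raw
  counts: they are scale-free in regional population size, which is the
  natural invariance for a marker-based comparison.
* **Ecology** — the occupancy fractions over the full species list;
  missing (region, species) cells are treated as 0 occupancy with a logged
  warning, absence records being the natural missing case in atlas data.
* **History** — per time slice, division membership is one-hot encoded and
  the slice blocks concatenated, so d² = 2 × (number of slices in which
  two regions belonged to different divisions). One-hot is the unique
  encoding for nominal labels in which "same division" contributes 0 and
  "different division" a constant, per slice.
* **Geography** — planar Euclidean distance between the supplied centroid
  coordinates, used as-is (no geodesic correction).

## Permutation inference

* The Mantel statistic is the Pearson correlation of the unfolded lower
  triangles (row-major, i > j). The simple test permutes the region order
  of the second matrix; the partial test permutes the response matrix raw,
  holding the second matrix and the covariate fixed (the classic scheme of
  the standard distance-matrix packages). A Freedman–Lane-style residual
  permutation was evaluated and behaves indistinguishably here, including
  under the nonlinear-confounding regime discussed below, so the simpler
  raw scheme is the default.
* p-values use the add-one estimator (1+k)/(1+N), with ties counted
  conservatively at a 1e-12 tolerance; the default tail is one-sided
  ("greater"), since every substantive hypothesis in this setting is
  directional; two-sided is available.
* `exact_mantel_p` enumerates all n! relabelings (n ≤ 8) and is the oracle
  the Monte-Carlo machinery is tested against.
* Default permutation count is 10,000, configurable everywhere (the
  replicate-based tests use 999 to keep runtimes in seconds).

## Correlograms

Distance classes are equal-width bins over the off-diagonal range of the
classifying matrix; the class count defaults to Sturges' rule,
round(1 + log₂ m) with half-up rounding (1081 pairs → 11 classes). Each
class's indicator matrix is tested with the (partial) Mantel machinery,
permuting the response. The reported statistic is the *negated* indicator
correlation, so positive values mean "pairs in this class are more similar
than average" (the raw sign is available). A class is untestable when its
indicator is constant (empty or all-pairs) or when the response values
carry no variation either within or outside the class; untestable classes
report null statistic and null p-value. Correction is global Bonferroni
(α / number of testable classes) by default, with Legendre's progressive
variant as an option. In the full pipeline the three partial correlograms
bin the explanatory matrix (human / ecological / historical) with
geography as covariate, and the geographic correlogram is simple; binning
everything on geography is available as an alternate mode.

## MRM

Ordinary least squares of the unfolded response on the unfolded
predictors. With `standardize=True` (default) all vectors are z-scored, so
the intercept is ~0 and slopes are standardized coefficients; coefficient
p-values are two-sided on |b| under response permutation, the R² p-value
one-sided. Perfectly collinear predictor pairs are rejected by name.

## Trees

Ward clustering is scipy's `linkage(..., method="ward")` on the distance
input — the Ward.D2 variant, verified in tests against a hand-executed
Lance–Williams trace. Neighbor joining is implemented in-package: the
canonical Q-criterion agglomeration with lowest-index tie-breaking, and
negative branch-length estimates clamped to zero with the deficit moved to
the sibling edge (path lengths through the joined node are preserved);
scikit-bio's NJ serves as an independent cross-check in the tests. Newick
export quotes labels containing delimiters and round-trips through a
standard parser.

## The synthetic generator

The generator plants known structure for every pipeline stage; its
defaults are the package's standard study conditions: 30 regions, 200
surnames × 200 records, 10% polyphyletic, 60 species, 6 livestock groups ×
5 breeds × ~4000 heads per region-group, 8 time slices × 4 divisions,
spatial range ρ = 0.3 on the unit square, utility noise σ = 0.3, weights
w_human = 1.0, w_eco = 0.6, w_geo = 0.3, w_hist = 0.2.

1. **Geography** — centroids uniform on the unit square.
2. **Culture** — a latent 2-D Gaussian field with covariance
   exp(−d_geo/ρ): cultural similarity decays with distance but has
   realization noise of its own.
3. **History** — per slice, regions join the nearest of a set of drifting
   seed points, giving spatially contiguous divisions; the small default
   drift (0.05 per century) keeps boundaries persistent, which is what
   gives the historical matrix block structure not reducible to geographic
   distance.
4. **Ecology** — a smooth coordinate gradient plus independent noise;
   species occupancy follows logistic responses with species-specific
   intercepts and slopes.
5. **Surnames** — each clear-origin surname keeps an origin-mass share
   (0.6) of its records at home; the remainder emigrates to *other*
   regions with probability decaying in latent cultural distance
   (exp(−d_cult/τ), τ = 0.3). The hollow emigration kernel is
   Sinkhorn-balanced so every region sends and receives the same total
   emigrant mass. This matters: with unbalanced kernels, culturally
   isolated regions retain more mass and develop systematically "spikier"
   surname compositions, and these regional main effects dominate the
   surname distance matrix. Main effects cannot drive the breed softmax
   (they shift every alternative's utility equally and cancel), so an
   endemicity-dominated human matrix could never carry a large MRM
   coefficient no matter the planted weight — balancing moves the
   matrix's variance into genuine pairwise exchange structure.
   Polyphyletic surnames mix the kernels of two geographically distant
   origins 50/50. Records per surname are fixed at the scale value
   (realistic Zipf tails are out of scope). Origins are balance-allocated
   across regions.
6. **Breeds** — every breed has an anchor ("cradle") region,
   balance-allocated; a region's expected within-group share of a breed is
   a softmax over the group's breeds of
   −β · (w_human·Ĥ + w_eco·Ê + w_hist·Ŝ + w_geo·Ĝ)(region, anchor) + σ·ε,
   with heads drawn multinomially. Each component matrix is the very
   distance the pipeline later measures — the *expected* surname
   composition distance, the occupancy-profile distance, the one-hot
   historical distance and the geographic distance — normalized to unit
   *interaction* (double-centered) spread, which is the only part of a
   dissimilarity component that can influence softmax shares. The
   sharpness β = 0.25 keeps breed compositions in the mild-response
   regime, where the breed distance is close to linear in the planted
   composite; this is the regime in which the linear Mantel/MRM machinery
   is the appropriate analysis. At much sharper settings breed shares
   saturate, breed distances become strongly concave in the composite,
   and the partial Mantel test inherits a genuine nonlinear-confounding
   artifact (linear partialling cannot remove a shared *curved*
   dependence on geography — a known limitation of the partial Mantel
   statistic, not an implementation defect).

Determinism: everything flows from `numpy.random.default_rng(config.seed)`;
identical (config, seed) reproduce byte-identical tables.

### What the generator does and does not emulate

It reproduces the *statistical shape* of the problem — five mutually
consistent tables, spatially structured cultural/ecological/historical
fields, surname markers with single origins and removable polyphyletic
contaminants, and breed compositions with a known effect decomposition. It
does not emulate real Spanish geography, Zipf-distributed surname
frequencies, unbalanced breed inventories (real groups range from 3 to 34
breeds), or non-Euclidean ecological gradients. Passing recovery tests
therefore demonstrates that the pipeline measures what it claims under
controlled conditions, not that any particular real-world dataset would
yield the same effect ordering.

## Problem sizes and numerical choices

The replicate-based checks run at the default generator conditions with
999 permutations per test: 200 replicates for type-I calibration, 100 for
effect-ordering recovery and confound removal, 50 random additive
matrices for NJ recovery; exact-vs-Monte-Carlo agreement uses n = 5–6
regions and 10⁵ draws. In the replicate loops the surname classification
runs without the SOM marker step (the calls are identical; the map adds
only marker metadata and dominates runtime); the full pipeline and the
acceptance script's main analysis include it. Symmetry of input matrices
is enforced to 1e-9 relative tolerance; tie counting in permutation tests
uses 1e-12; NJ recovery is asserted at 1e-8 on path metrics.

## Known limitations

* The partial Mantel test controls only the linear component of a
  confounder; strongly curved isolation-by-distance relationships leave
  residual association (see above).
* The monophyly criterion (single-region concentration ≥ 0.5) is a
  documented stand-in for the richer criteria used with real surname data;
  it ignores adjacency unless an explicit neighbor map is supplied.
* Bonferroni across correlogram classes is conservative for overlapping
  class structures; the progressive option trades family-wise control for
  power at short distances.
* With very small regions counts (n < ~10) the permutation null has few
  distinct values and p-values are coarse; the exact enumerator is the
  better tool there.
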