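# Methods

## The statistical procedure

The package decomposes the variance of (log-transformed) gridded species
richness into the unique and shared contributions of up to four predictor
sets — climatic, topographic, biotic and spatial — by commonality analysis
of ordinary least-squares models.

For every nonempty union *U* of the k sets, an OLS model of y on the
concatenated columns of *U* yields an adjusted R²,
adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1). Writing f_S for the fraction of
variance attributable to exactly the subset *S* of sets, the fractions
satisfy adjR²(U) = Σ { f_S : S ∩ U ≠ ∅ }. Defining
g(V) = adjR²(full) − adjR²(complement of V), the system inverts in closed
form by Möbius inversion over the subset lattice:
f_S = Σ_{V⊆S} (−1)^{|S|−|V|} g(V). The 15 four-set fractions are labelled
a…o in the conventional Venn order (a–d unique, e–j pairwise, k–n
three-way, o common to all); a set's **total importance** is the sum of
all fractions whose membership includes it and is identically the
adjusted R² of that set alone.

Adjusted (not raw) R² is partitioned because the sets carry unequal
numbers of predictors. Negative fractions — a routine outcome of
commonality analysis with correlated sets — are reported as computed and
flagged, never clamped.

**Degrees of freedom.** The penalty p in adjusted R² is the *effective
rank* of the design (excluding the intercept). For full-rank designs this
is simply the number of columns; for degenerate unions (e.g. a set that
duplicates another's information) the pseudo-inverse fit consumes no extra
degrees of freedom, so a purely redundant set cannot perturb the adjusted
R² of a union. This keeps the fraction system consistent: a duplicated
set's unique fractions are exactly zero.

## Predictor sets

Each raw environmental variable is standardized (sample sd), its square
appended — squaring the *centered* variable keeps linear and quadratic
terms nearly orthogonal — and the squares re-standardized. PCA runs on
the correlation matrix (variables are on incommensurate units: °C, mm, m)
and the first k = 3 component-score columns become the set's variables.
Axis signs are fixed by forcing each axis's largest-magnitude loading
positive, making outputs reproducible across platforms (up to BLAS
rounding, ~1e-14). Component scores are orthogonal, so their VIF is ≈ 1
by construction; the `vif` diagnostic (1/(1−R²_j), +∞ under perfect
collinearity) is still computed and reported.

Zonal statistics (mean, range, sample sd, cv = sd/mean) aggregate
sub-cell pixel samples to the analysis grid; a cell with zero mean has an
undefined cv and is returned as NaN with a warning. Land-cover diversity
is the Shannon index H = −Σ pᵢ ln pᵢ of class proportions (natural log,
0·ln 0 := 0).

## Spatial filters

Connectivity is binary within a truncation distance t (a 1 − d/t linear
decay is available); t defaults to the longest edge of the minimum
spanning tree over the cell centroids — the smallest threshold keeping the
graph connected — and smaller values are rejected. The doubly-centered
matrix Ω = HWH (H = I − 11ᵀ/n) is eigen-decomposed; eigenvectors with
|λ| > 1e-9 are retained, unit-normed, sign-fixed, and sorted by λ
descending. Because each eigenvector v is centered, vᵀWv = λ, so Moran's
I of v equals (n/W_tot)·λ — an identity the tests verify to 1e-6.

Filter selection is greedy forward selection over the candidate pool
(positive-λ vectors by default): at each step the candidate whose
inclusion most reduces max |I| of the refitted residuals over the checked
distance classes is accepted; ties break toward the lower eigenvector
index; selection stops below the 0.1 threshold, when no candidate
improves, or at the configured cap (60 in the pipeline default). The
acceptance rule makes the criterion non-increasing relative to the
unfiltered model.

**Distance classes.** Reported correlograms use 21 equal-width classes
over (0, d_max], the conventional presentation. The *selection criterion*,
however, is evaluated on 21 equal-count (quantile) classes: on a square
grid the farthest equal-width classes contain only a handful of pairs
(down to 10 of ~80 000 on the 20 × 20 grid) and their Moran's I is so
variable that pure white noise violates any reasonable threshold there —
|I| ≈ 0.6 is typical for the last class. Equal-count classes give every
class the same pair support, making the 0.1 threshold meaningful. Both
styles are available in `FilterSelectionConfig`.

## The synthetic generator

The generator emulates the causal structure the analysis presumes:

- **Gradients** are Gaussian random fields with exponential covariance
  exp(−d/range), drawn by Cholesky factorization over cell centroids and
  standardized exactly. Default range 550 km (5 cells) on a 20 × 20 grid
  of 110-km cells.
- **Climate**: four observed variables (temperature-like and
  precipitation-like monotone transforms) built from two shared latent
  factors (loadings √0.70 / √0.15 / √0.15). Real climate variables are
  strongly intercorrelated — that is the premise of per-set PCA — and with
  *independent* climate variables the set's correlation matrix would be
  ~identity, three axes would capture an arbitrary half of the climate
  signal, and the missing half would masquerade as biotic-unique variance
  downstream.
- **Topography**: an elevation and a roughness gradient, observed through
  zonal mean/range/cv of 16 sub-cell pixel samples whose spread follows
  the roughness field.
- **Vegetation**: continuous canopy-structure variables equal to
  coupling·(climate mix) + √(1−coupling²)·(independent gradient), unit
  variance, so corr(biotic, climate mix) = coupling (default 0.9); the
  land-cover mosaic (softmax of latent fields, 11 classes) shares the
  same coupling, and its Shannon index joins the biotic set.
- **Latent suitability** = β_clim·climate_mix + β_bio·biotic_mix +
  β_topo·topo_mix + spatially structured noise + white noise, with
  defaults 1.0 / 0.8 / 0.3 / 0.3 / 0.3. The structured noise is a random
  combination of the grid's first 15 positive-λ MEM eigenvectors — exactly
  the structure filter selection is designed to absorb.
- **Ranges**: axis-aligned boxes whose centers are drawn over cells with
  probability ∝ exp(z(driver)) (placement thinned against suitability,
  keeping ranges spatially cohesive) and whose edges are log-uniform
  between 110 and 550 km — one to five cells; larger boxes would smear
  the driver–richness link over space and shift genuinely environmental
  variance into the spatial set. Richness is the per-cell box count under
  the any-overlap rule (closed footprints; boundary touching counts; a
  centroid-in-box rule is available).

Everything derives from one integer seed through `SeedSequence` spawning;
same seed ⇒ byte-identical CSV output.

**What the generator does not emulate**: polygonal range geometry,
phylogenetic or dispersal structure, anisotropy, coastline complexity
beyond a rectangular band, measurement error in the rasters, and spherical
geometry (the frame is planar km throughout, matching an equal-area
projection). Passing tests therefore demonstrate correctness of the
machinery and recoverability of generating structure under these idealized
conditions, not robustness to the full messiness of real range maps.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; rank-deficient designs fall back to the
  pseudo-inverse with a warning. Union models are refit from scratch.
- MEM retention tolerance |λ| > 1e-9; eigenvector orthogonality and
  centering hold to 1e-8.
- The gradient covariance gets a 1e-8 diagonal jitter before Cholesky.
- Cholesky factors and distance-class pair indices are cached per grid,
  since Monte-Carlo replicates share the geometry.
- Greedy-selection ties break toward the lower eigenvector index.
- Zero-distance pairs (duplicate coordinates) fold into the first
  correlogram class.

## Known limitations

- With spatially smooth predictors and response, the adjusted R² between
  *causally unrelated* sets is substantially positive (spurious spatial
  regression): at the default 5-cell autocorrelation range a null
  topographic set still shows a total importance of several percent,
  because total importance by definition includes fractions shared with
  the spatial set. Unique environmental fractions are far less affected —
  this is precisely the motivation for partialling out spatial filters.
- Greedy max-|I| selection is a heuristic; it is not guaranteed to find
  the smallest filter subset, only a non-increasing criterion path.
- Significance tests of individual fractions or eigenvectors, SAR/CAR/GLS
  alternatives, and structural equation models are out of scope.
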