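# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `immunoarch`. It is the place to look when a default
seems arbitrary or a result needs interpreting.

## Data model and units

Coordinates are micrometers throughout; densities are reported in mm⁻²
and areas in mm² through a single conversion constant. Cell tables are
CSV (`x`, `y`, header required, UTF-8); annotations are GeoJSON
FeatureCollections whose features carry `label ∈ {tumor, normal}` with
coordinates in micrometers; outcomes are CSV with `patient_id`, `cohort`
(MSI/MSS) and `recist` (CR/PR/SD/PD). The observation window defaults to
the bounding box of the points when none is supplied; coordinate input in
pixels is converted with a user-supplied pixel size (0.49 µm/px is the
20×-equivalent scanner resolution this kind of data typically carries).
Cell positions are treated as abstract point locations; whether a
segmentation tool emits nucleus or cell centroids is immaterial at the
spatial scales analyzed (tens of micrometers and up).

## Segmentation evaluation

Detected and reference cells are matched by **mutually-greedy
nearest-neighbor pairing**: repeatedly pair the globally closest unmatched
(detected, reference) pair with distance ≤ radius. The default radius of
10 µm is about one lymphocyte diameter — generous enough to absorb
centroid jitter, tight enough to separate neighbors at typical TIL
densities. Greedy matching is deterministic and O(E log E); it coincides
with the optimal assignment whenever inter-point spacing exceeds twice
the radius (asserted by test against the Hungarian algorithm on small
instances). Recall, precision and their binomial standard errors
√(p(1−p)/n) are computed on counts pooled over sample regions; Spearman's
ρ summarizes per-sample count agreement and is reported missing when a
count vector is constant.

## Moving-window point-process analysis

Windows are 0.5 × 0.5 mm advanced in 0.25 mm steps (50% overlap), a scale
large enough to contain local density variation and small enough that
within-window stationarity is defensible. Point membership is half-open
per window; windows that would be clipped below 90% of nominal area are
dropped so that all densities are comparable. Windows with fewer than
**n_min = 10** points report density only — nearest-neighbor normal
theory and K-function fitting are not meaningful on a handful of points.

**CSR testing.** The Clark–Evans index is the observed mean
nearest-neighbor distance over its CSR expectation 1/(2√λ). The test is
one-tailed (alternative: clustered) at α = 0.05. The default p-value uses
**Donnelly's boundary-corrected** expectation and variance of the mean
nearest-neighbor distance for rectangular windows. The correction
matters: at 0.5 mm windows with n ≈ 100, the uncorrected statistic is
biased by almost one standard error (boundary cells lack neighbors beyond
the edge), which collapses the one-tailed rejection rate from the nominal
5% to well under 1%. With the correction the measured type-I error is
5% within Monte-Carlo error; the plain uncorrected variant remains
available (`correction="none"`) for comparison with textbook outputs.

**Ripley's K.** K̂(r) = (area/n²) Σ_{i≠j} w_ij 1[d_ij ≤ r] with Ripley
isotropic edge-correction weights (reciprocal of the in-window arc
fraction of the circle through j centered at i; exact for a circle
crossing at most two adjacent edges, which holds for r up to a quarter of
the shorter window side — the default fitting range). L̂ = √(K̂/π).

**Thomas process fitting.** The Thomas process has parents Poisson(κ),
offspring counts Poisson(µ), isotropic Gaussian offsets σ, and
K(r) = πr² + (1/κ)(1 − e^{−r²/4σ²}). Two fitting methods are provided:

- `method="palm"` (default): maximize the Palm-intensity likelihood of
  the edge-corrected pair distances up to r_max. The Palm intensity at
  distance r from a typical point is λ + (µ/4πσ²)e^{−r²/4σ²}; pair
  distances are treated as an inhomogeneous Poisson sample from it. After
  the unconstrained three-parameter fit, κ is re-derived from the exact
  intensity constraint κ = λ̂/µ̂ with λ̂ = n/area.
- `method="mincon"`: classical minimum contrast on K̂^q with q = 0.25
  (the conventional variance-stabilizing exponent), r from 0 to a quarter
  of the shorter side, Nelder–Mead on log-parameters from three
  deterministic starts.

Palm likelihood is the default because per-window minimum contrast on the
cumulative K is visibly biased at the operating conditions this package
targets (≈10 parents per window): in simulation at κ = 40 mm⁻², µ = 15,
σ = 25 µm, the median minimum-contrast estimates sit ≈ +22% (κ) and
−24% (µ) from the truth, while the Palm fit's medians are within ≈5% for
all three parameters. Both methods are deterministic and enforce
κ·µ = n/area exactly. A fit is flagged non-converged when the optimizer
fails or the estimates pin at the fitting range (σ̂ ≥ 0.9·r_max, µ̂ < 0.5,
or fewer than ~0.05 expected parents in the window) — the signature of
fitting a non-clustered pattern; parameters are still reported but
excluded from downstream heterogeneity summaries.

**Derived cluster statistics.** Offspring distance to the parent is
Rayleigh(σ): mean distance σ√(π/2), 95% radius r95 = σ√(2 ln 20), cluster
area πr95² (mm²). Note χ²₂(0.95) = 2 ln 20, so r95 coincides with the
major semi-axis of the 95% covariance ellipse of an isotropic cluster —
a deliberate cross-module consistency.

**Envelopes.** CSR envelopes for L(r) − r are pointwise rank envelopes
from n_sim = 99 fixed-n binomial simulations (m-th extreme with
m = ⌊(n_sim+1)(1−level)/2⌋; the min/max convention at n_sim = 39). A
global variant ranks simulations by maximum absolute deviation and takes
the pointwise extremes of the retained fraction — conservative, suitable
for fitted-model goodness-of-fit. Envelope seeds are explicit arguments.

## Cluster morphometrics

**Detection** uses HDBSCAN with min cluster size 30 and core distance at
the 4th nearest neighbor, excess-of-mass extraction. One amendment to the
raw extraction: points whose soft-membership strength is below 0.5 are
demoted to noise. Excess-of-mass extraction attaches a few remote,
last-moment border points to each cluster; because the alpha-shape must
contain *every* member, even one such straggler half a millimeter out
inflates the escalated alpha by an order of magnitude and destroys all
shape descriptors. Measured membership strengths separate cleanly
(core ≥ ~0.6, stragglers ≤ ~0.2), so the 0.5 floor is not a sensitive
tuning; it is configurable.

**Alpha-shapes** use the circumradius convention (a Delaunay triangle is
kept iff its circumradius ≤ α; boundary edges lie on circles of radius
α). Alpha escalates geometrically (×1.2) from 10 µm until the shape is a
single connected polygon covering all member points, then one bisection
step refines between the last failing and first passing value. Holes that
isolate no member point are permitted, and hole boundaries count in the
perimeter — circularity is meant to penalize non-disk topology.
Degenerate clusters (< 3 points or collinear) are excluded from
morphometrics with a logged reason but retained in counts.

**Descriptors.** Convexity A_α/A_conv; circularity 4πA_α/P_α² clipped to
(0, 1] with a warning if numerically above 1; the 95% covariance ellipse
has semi-axes √(λᵢ·χ²₂(0.95)) and eccentricity √(1 − λ₂/λ₁) (1 for
collinear clusters, flagged degenerate). All descriptors are invariant
under rigid motions; the dimensionless ones under uniform scaling
(asserted by tests).

## Heterogeneity

QCoD = (Q3 − Q1)/(Q3 + Q1), scale-free and in [0, 1) for positive
metrics. Quartiles use linear interpolation of order statistics
("type 7") by default; the convention is switchable and logged because
QCoD at small n is sensitive to it — e.g. two values {m, 3m} give 0.25
under type 7 but 0.50 under the inverted-CDF convention. Intra-tumoral
summaries use only converged-fit windows (density uses all tested
windows) and non-degenerate clusters; each patient's proxy value is the
per-metric median, and inter-tumoral QCoD is computed over those medians.

## Tissue context and outcome statistics

The invasive front is the tumor-boundary segments adjacent to non-tumor
tissue, buffered 250 µm to each side (500 µm total — "both sides of the
edge") and clipped to annotated tissue; slides without tumor/non-tumor
contact have an empty front. ROI fallback: invasive front, else tumor,
else normal — total over annotated slides. Cell labels are mutually
exclusive with front precedence; cells outside every annotation are
stromal with an out-of-annotation flag. Cluster association: any
peritumoral member → invasive front; else any intratumoral member →
tumor; else normal.

Phenotypes: circular iff e < 0.8 and f_conv > 0.8 and f_circ > 0.5;
elongated/irregular iff e > 0.9 or f_conv < 0.3 or f_circ < 0.3
(configurable; a cluster can satisfy neither). Maximum within-cluster
density per region excludes clusters under 50 cells.

Responder grouping: MSI patients respond iff RECIST ∈ {CR, PR}; for MSS
patients stable disease also counts as response (durable stability is a
meaningful outcome without mismatch-repair deficiency). Group comparison
is a two-sided Wilcoxon rank-sum, exact for combined n ≤ 20 without ties,
otherwise normal approximation with midrank ties and continuity
correction. The RECIST trend test is Jonckheere–Terpstra (ties counted
half), one-sided for an increasing trend, with an exact enumeration
p-value for total n ≤ 8 and a seeded permutation p (10,000 permutations,
add-one correction) otherwise — group sizes here are far too small for
the normal approximation.

## Virtual slides

The generator emulates what the analysis consumes, not images: an 8 × 8 mm
slide with a centered 3 × 3 mm square tumor, region-conditional point
processes, optional archetypes, and detection noise.

- Default tumor infiltrate: Thomas(κ = 40 mm⁻², µ = 15, σ = 25 µm) —
  magnitudes chosen to match what fitted clinical windows typically show
  (a few to tens of cells per cluster, cluster radii of tens of µm).
  Parents are simulated in a 4σ-expanded box so edge clusters are not
  deficient. Default normal-tissue infiltrate: Poisson 50 mm⁻².
- Follicle archetype: jittered hexagonal packing (spacing 10 µm ≈ one
  lymphocyte diameter, jitter 2 µm) in a 150 µm disk. Packing, not
  uniform sampling, is deliberate: cell centers in a dense follicle repel
  at a cell diameter, and only a hard-core arrangement yields the smooth
  alpha-shape a real follicle presents. A uniformly sampled disk at any
  physiological density has hole- and gap-dominated minimal alpha-shapes
  whose circularity never clears the phenotype threshold.
- Elongated archetype: 400 points uniform in a 1500 × 100 µm rotated
  rectangle, giving eccentricity ≈ 0.998.
- Detection noise: independent thinning at miss rate q (default 0.25)
  plus uniform false detections calibrated to a target false fraction
  (default 0.12) — the operating point of commercial IHC segmentation
  this workflow is built around. An optional density-dependent miss mode
  scales per-cell miss probability with local k-NN density, mimicking
  segmentation failure in dense sheets of cells.
- `archetype_scenario()` fixes a sparse 1 mm⁻² background so the planted
  archetypes are the only aggregates (comparable to the sparsest clinical
  slides); `detection_noise_scenario()` is a homogeneous 150 mm⁻² slide
  where matching is unambiguous and the noise model can be validated in
  isolation.

What the generator does **not** emulate: anisotropic or curved invasive
fronts, spatially varying background intensity, marker-intensity values,
segmentation displacement noise (detected cells sit exactly on true
cells), and multi-type interactions. Tests passing on virtual slides
therefore validate the estimators and the pipeline plumbing, not the
biological fidelity of any particular clinical dataset.

## Problem sizes and determinism

Simulation-backed checks use sizes chosen to make their Monte-Carlo error
small relative to the tolerance they assert: 200 windows for parameter
recovery (median estimates within 15% of truth), 1000 windows for CSR
calibration (3 binomial se around α), 99 simulations per envelope, one
8 × 8 mm slide per archetype/noise check. Every stochastic component
takes an explicit seed or Generator; the pipeline is deterministic given
inputs, config, and seeds.

## Known limitations

- The Clark–Evans correction assumes rectangular windows; non-rectangular
  tissue masks are handled only by dropping clipped windows.
- Window density uses window area, not tissue area within the window;
  windows straddling tissue edges understate local density.
- Per-window Thomas estimates remain heavy-tailed at ~10 parents per
  window even with the Palm fit — individual windows can be far off even
  though the median is nearly unbiased; downstream summaries use medians
  and IQR-based dispersion for this reason.
- Greedy matching can differ from the optimal assignment in dense
  detection fields (spacing below twice the radius).
- The K estimator's area/n² normalization is the simplest consistent
  choice; for clustered patterns it carries the usual conditional bias of
  plug-in intensity estimates, which the Palm fitting route sidesteps.
- No multiple-testing correction is applied to outcome tables; p-values
  are reported raw and should be interpreted accordingly.
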