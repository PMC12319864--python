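# Methods

This note documents the models, parameter defaults, and numerical choices
behind `thalagrad`, and what the synthetic validation does and does not show
about real data.

## Coordinate and data conventions

All coordinates are RAS in millimetres (+x lateral/right, +y anterior,
+z superior); serialized indices are 0-based. A connectivity matrix M is
seeds × vertices and moves through explicit states — raw → smoothed →
filtered → normalized → centred — each stage validating its input state, so
a matrix cannot silently skip a processing step.

## Synthetic study design

The generator emulates a neonatal tractography cohort at desk scale.

**Seed grid.** An origin-anchored cubic lattice clipped to an ellipsoid.
Defaults: 1.75 mm spacing, semi-axes (8, 12.5, 10.25) mm, chosen so the
lattice holds 805 seeds — a thalamus-sized volume at the study's seed
density. The origin is always a lattice point, so the grid is never empty.

**Surface.** An icosphere (trimesh subdivision) with two coordinate systems:
the unit sphere is the "spherical registration"; the same sphere scaled to
60 mm radius stands in for the folded white surface (brain-like scale, used
for distances and areas). A 20° geodesic cap around the −z pole is flagged
as medial wall and excluded from every analysis; on meshes too coarse for
the cap to contain a vertex, the pole-nearest vertex is flagged so the mask
is never empty.

**Planted gradients.** k ≤ 5 components with mean-zero orthonormal columns
over seeds (scores) and over cortical vertices (loadings; zero on the medial
wall). Component 1 scores follow the seed axes with coefficients
proportional to (0.70, −0.85, −0.27) on (x, y, z) — a dominant
medial-lateral plus anterior-posterior gradient with a weak vertical tilt;
component 1 loadings follow the rostral-caudal (y) sphere axis. Higher
components are low-order spatial harmonics (z, x·y, x²−y², …),
Gram–Schmidt-orthonormalized in order. Because the squared norm of that
coefficient triple exceeds 1, and the lattice axes are nearly uncorrelated,
the realized axis correlations come out around (0.61, −0.74, −0.26): the
printed triple is only achievable when the seed coordinates themselves are
correlated, as in a real thalamus.

Component singular-value weights are proportional to (1, 0.767, 0.411) for
components 1–3 — the square roots of a 48.6 / 28.6 / 8.22 % variance
spectrum, the shape reported for term-neonate thalamocortical gradients —
and decay further (0.2, 0.1) beyond. Weights are scaled so the component-1
per-entry signal rms is exactly 1, which makes noise levels directly
interpretable as signal fractions.

**Cohort.** Each subject's matrix is

    M_i = baseline + A diag(w) Bᵀ + ε_i,  ε_i ~ N(0, sd(age_i)²),  clipped at 0.

Noise sd interpolates linearly from 0.5 (youngest scan age) to 0.1 (oldest),
in units of the component-1 signal rms. A linear age→noise map is the
simplest monotone model that produces the qualitative finding the pipeline
must reproduce: template similarity rising with scan age. The constant
baseline (3 max noise sds above the most negative signal entry) keeps the
non-negativity clip a boundary case rather than a systematic truncation of
the planted low-rank structure; the sigmoid normalization is invariant to a
per-column constant shift, so the baseline changes nothing downstream.
Noise is added only at cortical (non-medial) vertices, mirroring the
exclusion of the medial wall from real connectomes. Scan ages are uniform
on 29–45 weeks; sex is balanced; preterm subjects (a configurable fraction)
get uniform birth ages of 24–36.9 weeks and a vertexwise connectivity offset
added to every seed's row at flagged vertices. The oldest term-born subjects
(default 20) are flagged as template members.

**Preterm-effect fixture.** Detection tests plant two 25° caps (one
positive, one negative offset) with amplitude δ = d·σ̄/√n_seeds where σ̄ is
the cohort-mean noise sd, giving a per-vertex-total Cohen's d of 2.0 — a
clearly detectable localized effect, fixed a priori as the fixture's
documented effect size.

**Endpoints.** For testing the assignment stage, endpoints are drawn per
seed as a multinomial over vertices proportional to a target row, placed at
white-surface vertex coordinates plus isotropic Gaussian jitter, with FA
weights uniform on [0.1, 0.5]. The exact multinomial draws are attached to
the table so round-trip tests can compare counts, not just totals.

## Connectome build

**Endpoint assignment.** Nearest non-medial-wall vertex by Euclidean
distance on the white surface; endpoints farther than 5 mm (default) from
every cortical vertex are discarded and counted in the log. Total assigned
FA mass is conserved by construction. Nearest-vertex ties are resolved by
the KD-tree's lowest-index convention; they have measure zero for jittered
endpoints.

**Smoothing.** Geodesic distance is approximated by shortest paths on the
mesh edge graph with Euclidean edge lengths (Dijkstra, truncated at the
radius where the Gaussian weight falls below ε, so the kernel stays sparse).
Gaussian weights use σ = FWHM / (2√(2 ln 2)); defaults FWHM = 3 mm,
ε = 0.01. Weights below ε are zeroed before row normalization. The kernel
is stored row-stochastic in scatter form — row u holds the weights with
which vertex u's mass is redistributed — and applied on the right
(`values @ K`), which conserves each seed's total connectivity exactly; the
medial wall gets identity rows/columns so no mass crosses it. Smoothing is
applied over the cortical dimension by default; one endpoint of every
connection lies in thalamic volume, not on a mesh, so the optional seed-side
kernel (`build_seed_kernel`, off by default) uses plain Euclidean distances
between seed coordinates instead of geodesics. The graph-distance
approximation error is second-order at 3 mm FWHM relative to mesh edge
lengths. Disconnected cortical subgraphs are rejected loudly.

**Seed filtering.** Operating on the across-subject mean of smoothed
matrices, a seed is kept iff its row has at least `min_connected_vertices`
(default 100) strictly positive entries; the retained index set is applied
uniformly to all subjects. This mirrors removing deep/medial seeds whose
cortical connectivity tractography cannot estimate reliably.

**Sigmoid normalization.** Per cortical connection (matrix column):
S(x) = 1/(1 + exp(−(x − ⟨x⟩)/σx)) with the column mean and *population*
(divide-by-n) standard deviation across seeds — the population form is fixed
for reproducibility where the convention is otherwise open — followed by a
per-column min-max rescale to exactly [0, 1]. Zero-variance columns, where
the transform is undefined, map to the constant 0.5 (the symmetric limit);
after centring they contribute nothing. Min-max rescaling is per column,
matching a per-connection linear scaling to the unit interval.

## Decomposition and alignment

Centring removes each vertex column's across-seed mean (recorded for
reuse). The thin SVD's sign ambiguity is fixed by forcing each loading
column's largest-magnitude entry positive; the Procrustes step later absorbs
any residual reflection. Variance fractions divide λ_k = s_k²/(n−1) by the
total column variance of the centred matrix.

The term template averages the normalized matrices of the oldest term-born
subjects (default 20) and decomposes the average with identical centring; a
leave-one-out variant excludes a given subject before selection. Alignment
solves the orthogonal Procrustes problem on the first k_align score columns
(default 5; the acceptance analyses align on 3, the planted rank) and
applies the transform to scores and loadings alike. Reflections are
permitted deliberately: independent SVDs differ by arbitrary sign flips
that a pure rotation could not undo. No scaling or translation is applied.

## Spatial inference

**Spin test.** Each permutation draws a Haar-uniform rotation (QR of a
Gaussian 3×3 with determinant forced positive), rotates the non-medial
sphere coordinates, and maps each rotated vertex to its nearest original
vertex. Only one hemisphere is modelled, so no mirrored-pair machinery is
needed. The test is bidirectional: each direction spins one map, computes
the two-sided add-one p-value of |r|, and the reported p is the average of
the two directions. Constant maps are rejected rather than returning an
undefined correlation.

**Age maps.** Vectorized Pearson correlations per seed or vertex against
scan age, two-sided p from the t distribution with n−2 df (the reference
distribution is otherwise unstated; the t form is standard), BH-FDR at
q = 0.05 per domain — seed and vertex families are corrected separately.
Constant elements are recorded as missing and excluded from the FDR family.

**Group GLM.** The group-difference outcome is the per-vertex total
connectivity of the smoothed/filtered (pre-sigmoid) matrices; an optional
`proportion` mode divides each subject's totals by their sum, testing the
share rather than the absolute amount of connectivity. Design is
intercept + group + scan age + sex with the contrast on group. Permutation
inference follows the Freedman–Lane scheme: reduced-model (covariates-only)
residuals are permuted, added back to the reduced fit, and the full model is
refitted — the standard choice when covariates must be respected under
permutation. Two-tailed inference uses absolute statistics; per-vertex
family-wise p-values compare against the permutation distribution of the
map-wise maximum with the add-one rule, so p ≥ 1/(1+n_perm) always.

**TFCE.** For each sign separately, TFCE(v) = Σ_h e(h,v)^E · h^H · dh with
H = 2, E = 0.5 (the standard surface defaults), where e(h,v) is the surface
area — barycentric vertex areas, one third of incident triangle area — of
the supra-threshold connected component containing v, with connectivity by
shared mesh edges on the cortex. dh defaults to max|t|/100; inside the
permutation loop a common dh from the observed map is used for all
permutations so enhanced values are comparable across the null distribution.

**Scalar ANCOVA.** Group effects on per-subject scalars (variance-explained
fractions) use the partial F test of covariates-only vs covariates+group
(df 1, n − full rank), with a degenerate-fit warning when residuals vanish.

## Problem sizes and calibration checks

The validation suite runs the full pipeline at 805 seeds × 642 vertices ×
50 subjects — small enough to iterate on quickly, large enough that all
asymptotic identities and calibration bands are informative. Calibration
checks use 500 spins × 200 replicate map pairs (type-I error of the spin
test) and 200 permutations × 100 replicates (family-wise error of the
permutation GLM); replicate map pairs share one spin set, which is valid
because the maps are generated independently of the spins.

## What the synthetic validation does and does not show

Passing tests demonstrate that the machinery is correct: exact linear
algebra, calibrated nulls, faithful recovery of planted structure through
the real normalization path. The synthetic cohort is, however, far cleaner
than neonatal diffusion data: noise is Gaussian, i.i.d. across entries, and
purely age-dependent; the planted gradients are exactly low-rank and shared
by all subjects; there is no registration error, no partial-volume bias
against deep seeds, no head motion. Quantities like the similarity-age
correlation therefore come out near their deterministic limits (r ≈ 0.99)
rather than the moderate values real cohorts show; the synthetic results
validate signs, calibration, and recovery guarantees, not effect
magnitudes. The sigmoid normalization is a fixed monotone nonlinearity, so
planted components are recovered through it to |r| ≈ 0.98–0.99 rather than
exactly; the noise-free exact-recovery guarantee holds for the
centring+SVD chain on the raw matrices.

## Known limitations

- Geodesic distances are graph shortest paths, a small overestimate of true
  polyhedral geodesics; negligible at the default kernel width.
- The endpoint generator plants endpoints at vertices plus jitter; it does
  not model curved trajectories, so assignment-radius effects are tested
  only geometrically.
- One hemisphere, one scan per subject; no exchangeability blocks or
  longitudinal structure in the permutation machinery.
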