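# Methods

This note documents the models and procedures implemented in `infonets`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## The analysis pipeline

The pipeline asks where two groups of subjects carry *group-convergent*
item-level representational geometry, and what that geometry encodes. It
proceeds in four stages on a standard cortical surface.

### Surface geometry

All maps live on a subdivided-icosahedron sphere mesh per hemisphere:
every base face is linearly divided into `L**2` triangles and vertices are
projected to the unit sphere, giving `10 L** 2 + 2` nodes. At the standard
resolution `L = 32` the whole-brain surface (left + right) has 20,484
nodes. Node order is fixed (base vertices, edge interiors, face interiors;
left hemisphere before right), so maps are reproducible arrays. Contiguity
everywhere means *shared mesh edge*; this is the substrate for searchlight
patches and cluster correction.

### Stage 1 — searchlight dissimilarity maps

For each subject, an item dissimilarity matrix (DM) is computed at every
node: each item's feature vector is its pattern estimate (beta-like,
arbitrary units) over the node's k-ring patch, and dissimilarity is
correlation distance `1 - Pearson r` (entries in [0, 2], condensed
upper-triangle storage). The searchlight extent is a parameter
(`searchlight_rings`, default 2, i.e. ~19 nodes); patches are defined in
edge rings rather than millimetres because synthetic meshes carry no
physical scale. Nodes where any item's local pattern has zero variance are
flagged missing.

### Stage 2 — intersubject convergence and data-driven thresholding

Within each group, the condensed DMs of every subject pair are correlated
per node (Pearson), Fisher z-transformed (`arctanh`, clipped at
`1 - 1e-7` so perfect convergence stays finite), and averaged. A negative
mean intersubject DM correlation can only be noise, so the magnitude of the
map's most negative value serves as the noise threshold, applied strictly
(`z > threshold`). The rule, not any particular printed value, is the
method; the threshold is recomputed per dataset. When two group maps are
overlaid, the stricter (larger) of the two group thresholds is applied to
both, since the overlay requires one common criterion. An optional
permutation stage (within-subject item-label shuffling, consistent across a
subject's nodes; map-maximum statistic recorded) validates the rule: the
permuted-null 95th percentile of the map maximum brackets the
negative-extent threshold on reference data.

Nodes exceeding the threshold in exactly one group are that group's
distinct regions; nodes exceeding in both are overlap regions. Each label
class is cluster-corrected on the mesh: connected components smaller than
`min_cluster_size = 5` nodes are discarded.

### Stage 3 — informational networks

Within each (group, region class), the group-average condensed DM per node
(entry-wise mean over subjects, missing subjects skipped node-wise) is the
node's feature vector, mean-centered and unit-normed. Nodes are clustered
with Ward linkage (Euclidean on the normalized vectors — Ward's natural
geometry, equivalent to correlation similarity up to a monotone map). The
cluster count is selected by repeated split-half cross-validation: subjects
are split into random halves, each half's node-average DMs are clustered at
every candidate k (one dendrogram per half, cut at all k), and
reproducibility(k) is the adjusted Rand index (ARI) between the halves'
assignments. ARI is label-permutation invariant, so no cluster matching
step is needed. `k*` maximizes mean reproducibility over repetitions, ties
going to the smallest k; the final solution is refit on all subjects at
`k*`. The candidate grid spans 2..100 (truncated to the region size with a
warning) and the default repetition count is 1000; recovery experiments at
the test mesh scale use 100 repetitions, which leaves the selection curve's
ordering unchanged on pilot data while keeping a 20-study experiment inside
a few minutes.

The resulting clusters — informational networks — are purely data-driven:
no representational model enters before this point.

### Stages 3b/4 — model RSA, gradients, peaks

Each participant's average DM per network (entry-wise mean over the
network's non-missing nodes) is compared to a model DM by normalized
correlation: both condensed vectors are mean-centered, scaled to unit norm,
and dotted — exactly the Pearson correlation of the condensed entries,
bounded in [-1, 1]. Per-participant values are Fisher z-transformed and
each network's distribution is tested against zero with a two-sided
one-sample t-test (df = group size - 1). Two models are queried through
the identical code path:

* **mechanical category model** — binary DM, 0 within / 1 between the three
  structure categories (cantilever, truss, vertical load). The discrete
  three-category reading is implemented; an arbitrary model DM can also be
  loaded from CSV.
* **visual similarity model** — correlation distance between HMAX C1
  feature vectors of the stimulus images (below).

Per-network t values are painted onto the surface (every node inherits its
network's t) to give the informational gradient map; the network with the
largest t is the peak (ties: larger network, then smaller id). No
multiple-testing correction is applied by default, matching the practice of
reporting raw peak p values; a Benjamini-Hochberg flag is available.

### HMAX C1 visual encoder

S1 units are zero-mean, unit-norm Gabor filters at 4 orientations and 16
sizes (7..37 px, paired into 8 scale bands), with the standard size-to-
sigma/wavelength mapping (sigma = 0.0036 s^2 + 0.35 s + 0.18, wavelength =
sigma / 0.8, aspect 0.3). The S1 response is the absolute local
mean-removed normalized cross-correlation, which makes responses invariant
to global luminance offset; a half-filter border is zeroed because padded
pixels are not image content. C1 takes the max over the two sizes of each
band, then local maxima over an overlapping spatial grid (pool sizes
8..22 px, stride half the pool). Consequences worth knowing: C1 is
tolerant to small translations (quantified in tests) and, because of the
absolute-value rectification, blind to contrast polarity — an image and its
photometric negative encode identically. Images are resized to 128x128
grayscale before encoding.

### Item-space rendering

For descriptive visualization, a network-average DM can be embedded in 3-D
by nonmetric MDS (monotone-regression stress, best of `n_starts` random
initializations, normalized Kruskal stress-1 in [0, 1]), with a 95%
concentration ellipsoid per category: center = mean, axes = covariance
eigenvectors, semi-axis lengths = sqrt(eigenvalue x chi-square quantile at
0.95 with 3 df). A constant positive DM embeds as a regular simplex; only
an all-zero DM is rejected.

## The synthetic-study generator

No public dataset accompanies this problem, so validation rests on
parameter recovery from synthetic studies that emulate the pipeline's
inputs. The reference conditions are: 16 "expert" and 15 "novice"
subjects, 24 items in three categories of 8, whole-brain mesh at `L = 8`
(1,284 nodes; `L = 32` is supported but slow for repeated experiments),
signal-to-noise ratio 1.0, searchlight of 2 rings.

Signal is planted in six disjoint patches (k-ring balls, radius 5, two per
role on opposite hemispheres, centers ~120 degrees apart):

* `expert_category` — experts share a prototype whose item covariance
  follows the category model; novices get pure noise there;
* `both_visual` — both groups share a prototype following the C1 visual DM
  of the generated stimulus set;
* `novice_only` — novices share an arbitrary prototype orthogonalized
  against both models (convergence without model information).

Construction details that matter:

* **Target similarity.** A model DM is mapped affinely to a similarity
  matrix, its off-diagonal standardized to a common contrast (sd 0.35
  around 0.3) so different models are planted at equal representational
  amplitude, and made positive semidefinite by shrinkage toward the
  identity. Shrinkage scales the planted structure but preserves its
  correlation with the model exactly, which an eigenvalue clip would not.
* **Patch-specific components.** Each patch mixes the model similarity
  (weight 0.75) with a random similarity orthogonalized, in condensed
  space, against both model DMs — patches targeting the same model stay
  distinguishable by clustering without acquiring accidental model
  correlations.
* **Spatial structure.** The shared field over a patch is a rank-6
  combination of smooth spatial modes sampled from a stationary
  squared-exponential Gaussian process (length scale = 2 mesh edge
  lengths), each mode loaded with an item vector drawn from N(0, S). A
  subject's pattern is `sqrt(snr) x field + N(0, 1)` noise, independent per
  subject/item/node. Smooth stationary modes emulate spatially graded
  representations, keep a patch one homogeneous prototype (so the planted
  cluster count is well-defined), and deny split-half reproducibility to
  arbitrarily fine cluster solutions.
* **Support erosion.** The pattern-level signal occupies the declared patch
  eroded by 1 ring, so the set of searchlight centers whose patches see
  signal coincides with the declared region rather than its dilated halo;
  recovered label maps are scored (Jaccard) against the declared regions.
* **Stimuli.** Synthetic line drawings, one per item: cantilevers
  (anchored beam + brace), trusses (triangulated span), vertical loads
  (column under a block), with randomized geometry, line weight, distractor
  strokes, background gradient and noise, and full 0-360 degree viewpoint
  rotation. Full rotation is what keeps C1 orientation statistics from
  encoding category (the measured visual-vs-category DM correlation is
  ~0.0); these are synthetic stand-ins, not any real photograph set.

All planted quantities are in arbitrary beta-like units; the generator
makes no claim of physiological realism. In particular it omits spatial
autocorrelation of the *noise* (an optional smoothing of noise would change
cluster-extent behavior and is deliberately not default), hemodynamic or
GLM structure, between-subject anatomical misalignment, and realistic
cortical geometry. Passing recovery tests therefore demonstrates that the
pipeline's inferential machinery is correct and calibrated under its own
assumptions — not that those assumptions hold in real fMRI data.

## Validation battery (what the tests compute)

* the `L = 32` whole-brain construction reproduces the standard 20,484
  nodes;
* core numerics (DM computation, intersubject convergence, connected
  components, normalized correlation, one-sample t) match brute-force
  oracles to 1e-10 on 100 random instances each;
* the network RSA t-test has a 5% +/- 1.5% type-I error over 1000 null
  networks at n = 16;
* over 20 fresh studies at the reference conditions, the pipeline recovers
  planted regions at median Jaccard >= 0.7 per role, selects the planted
  cluster count in >= 90% of fits, places the expert mechanical peak inside
  the planted category region, finds no novice category signal there, and
  places both groups' visual peaks inside the shared visual regions;
* ~95% of 1e5 trivariate-normal draws fall inside the 95% population
  concentration ellipsoid.

`scripts/acceptance.py` recomputes all of these from scratch for a given
seed.

## Known limitations and numerical notes

* Split-half stability selection has inherent variance at these group
  sizes: with ~8 subjects per half, the ARI of the coarse (k = 2) solution
  occasionally dips enough that a finer stable solution wins; across 40
  fresh studies the planted count was selected in ~92% of fits (80-100%
  depending on the seed batch). This is a property of stability-based
  model selection, not of the implementation.
* Stability selection also cannot distinguish a true k from a stable
  coarser merge: when planted prototypes are at clearly unequal distances,
  the 2-cluster solution is reproducible and the smallest-k tie-break keeps
  it. Recovering k therefore presumes roughly equidistant prototypes.
* The negative-extent threshold degenerates to 0 (with a warning) on maps
  with no negative values, e.g. tiny groups with strong global signal.
* Ward + `maxclust` cuts are deterministic for fixed input; distinct merge
  heights are generic for continuous data, so ties are not handled beyond
  scipy's ordering.
* `arctanh` clipping (`1e-7`) bounds convergence z at ~8.0; this matters
  only for noise-free synthetic data.
* Whole-brain runs at `L = 32` are supported but the searchlight and
  k-selection stages scale linearly in nodes and repetitions; the test
  suite and acceptance script run everything at `L = 8` with 100
  repetitions (problem sizes chosen so a full 20-study recovery experiment
  completes in minutes).
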