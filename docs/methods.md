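# Methods

## The problem

Anterior temporal lobe resection renders many patients with refractory
temporal lobe epilepsy seizure free, but not all, and it is unclear how the
surgical disruption of the white-matter network relates to outcome.
`resectnet` implements a virtual-resection ("change in connectivity",
ChaCo-style) analysis: the patient's own pre-operative structural
connectome is the baseline, the predicted post-operative connectome is
obtained by deleting every tractography streamline that intersects the
resection mask, and the *change* between the two networks — not either
network in isolation — is the object of study and the input to an outcome
classifier.

## Network construction

Nodes are the regions of an integer label parcellation; an edge weight is
the number of streamlines whose two endpoints (first and last polyline
points) terminate in the two regions. Streamlines with an endpoint in
background are discarded; same-region endpoint pairs are stored on the
matrix diagonal and excluded from every measure. Endpoint voxels are found
by applying the inverse affine and rounding to the nearest voxel centre
(ties away from zero, 0-based indices). No label dilation is applied to
near-miss endpoints: the operation is deterministic given the inputs.

For analysis, counts are mapped to `log10(1 + w)`. The offset is a
deliberate choice: a plain `log10` would send single-streamline connections
to zero and absent connections to minus infinity, whereas `log10(1 + w)`
keeps absent connections at exactly 0, single-streamline connections
positive, and is strictly monotone. Graph measures default to the
transformed weights (a configuration switch selects raw counts);
ratio-type change features always use raw counts so that they are
proportions in [0, 1].

In right-sided resections the homologous rows and columns of the matrix are
swapped, so the surgical hemisphere is always reported as ipsilateral. The
flip is a permutation similarity: eigenvalues and all permutation-invariant
statistics are unchanged (tested).

## Virtual resection

A streamline is removed iff *any* of its stored points maps to an in-bounds
voxel where the binary mask (binarised at > 0.5 on load) is 1. Membership is
tested at the stored points only, with no segment rasterisation between
points; typical tractography step sizes (~0.94 mm) are below voxel size, and
the synthetic generator guarantees point spacing below the voxel edge, so
the result does not depend on the rasterisation convention. Out-of-bounds
points count as outside the mask. Consequences that the tests verify:
the kept/removed partition is exhaustive and disjoint; post-operative
count weights never exceed pre-operative ones; growing the mask only grows
the removed set; global efficiency never increases under resection.

Per-region tissue remaining is `1 - (masked voxels) / (region voxels)`:
1 = intact, 0 = fully removed.

## Graph measures

All measures treat the connectome as weighted and undirected, exclude
self-connections, and follow the weighted conventions of the standard
brain-connectivity toolbox family:

- **strength** — sum of incident weights;
- **shortest paths** — Dijkstra on edge lengths `1/w` (heavier = closer);
- **betweenness** (node and edge) — fractional counts of shortest paths
  over all unordered pairs, left *unnormalised* because the analysis works
  with raw-scale differences;
- **clustering** — Onnela geometric-mean triangle intensity with weights
  normalised by the network-wide maximum; 0 for degree < 2;
- **global efficiency** — mean inverse shortest-path distance, with
  `1/inf = 0` for disconnected pairs;
- **communicability** — row sums of `expm(D^{-1/2} W D^{-1/2})` with
  `D = diag(strength)`; zero-strength nodes get a unit normaliser, so an
  isolated node has communicability exactly 1.

Change rules: region volume, region strength and connection strength can
only shrink under resection and are summarised as post/pre ratios with the
convention `0/0 := 1` (a connection absent before and after is unchanged).
Betweenness and clustering can move either way and are summarised as
post − pre differences. Communicability is also treated as a difference:
under strength renormalisation it can rise after resection, so a ratio
would conflate direction with magnitude. Global efficiency is reported pre,
post, and as a ratio. Shortest-path ties need no arbitrary resolution
because all tied paths are counted fractionally.

Every measure is verified against an independent brute-force oracle
(exhaustive simple-path enumeration, Floyd–Warshall, direct triple loops,
truncated Taylor series) on hundreds of random graphs of up to 7 nodes.

## Outcome classification

The feature matrix `A (n x m)` stacks three blocks per subject: eligible
connection-strength ratios (upper-triangle order; a connection is eligible
when its pre-operative count is nonzero in every subject and its ratio is
below 1 in at least one subject), region-strength ratios (all regions), and
volume-remaining fractions (regions touched by at least one subject's
mask). The eligibility rule is this package's declared convention for
trimming the feature space to connections that both exist everywhere and
are actually affected by some surgery.

**Step 1 — selection.** The weighted elastic-net logistic objective

    F(x, c) = sum_i w_i log(1 + exp(-y_i (x.a_i + c)))
              + (rho/2) ||x||_2^2 + lambda ||x||_1

with labels y in {+1 seizure-free, −1 not}, unit sample weights and an
unpenalised intercept, is minimised by accelerated proximal gradient
(FISTA) with backtracking line search, exact soft-thresholding for the l1
term, a monotone restart, convergence at relative objective change
< 1e-8 or 1e5 iterations. Soft-thresholding produces exact zeros, so at or
above the critical lambda (the max absolute smooth-part gradient at x = 0)
the solution is exactly the null model with the weighted log-odds
intercept. Features with `|x_j| > 1e-8` form the binary selection mask.

**Step 2 — classification.** A soft-margin linear SVM on the masked
features with per-class misclassification cost `n / (2 n_k)` (uniform class
priors), so the 68:32 outcome imbalance cannot be learned as a base rate.
The SVM cost constant is C = 1 by default (configurable); the weighting is
equivalent, up to the overall constant, to duplicating minority samples
(tested). If the mask is empty the classifier falls back to a constant
prediction; uniform priors make the two classes tie, and the tie is broken
toward the seizure-free class, recorded via a `fallback_` flag.

**Evaluation.** Leave-one-out cross-validation with, by default, the
elastic net refitted inside every training fold (`selection_scope =
"per_fold"`, no leakage; a `full_cohort` variant is provided because
selecting once on all subjects is a common — leaky — alternative reading of
two-step designs). Confusion counts are aggregated over folds with the
seizure-free class positive. The grid search covers lambda in 0.01..0.96
and rho in 0.01..1.96, both in steps of 0.05 (20 x 40 = 800 points),
maximising accuracy with ties broken toward fewer mean selected features
and then larger lambda — the smallest feature set that separates most
accurately. A consequence worth knowing: when many grid points tie at the
same accuracy, the tie-break legitimately picks an extremely sparse point,
which may select fewer features than the full informative set.

## Cohort statistics

Group comparisons use a two-sided permutation test on the absolute
difference of means with the add-one correction
`p = (1 + #{|T_perm| >= |T_obs|}) / (N + 1)` (N = 10,000 by default, seeded),
uncorrected Pearson chi-square on 2x2 tables (df = 1), and Kruskal–Wallis
with tie correction. No continuity correction is used because the
uncorrected statistic exactly reproduces the published cohort tables
(hippocampal sclerosis chi-square 0.5808, p 0.4460; surgery side p 0.3353).
One published value does not reproduce from its printed counts under either
the uncorrected or the Yates-corrected statistic: the gender table
(16/20 vs 4/13) is printed with chi-square 0.839 but gives 2.150
uncorrected (1.40 with Yates). We document the discrepancy rather than
tune to it.

## Synthetic phantoms

The generator emulates the *structure* of the inputs, not anatomy: regions
are axis-aligned boxes mirrored across the mid-sagittal plane with a
populated homologue table; streamlines are straight polylines between
jittered interior points of their endpoint regions (endpoint jitter sd
0.2 mm against 1 mm voxels, point spacing 0.5 mm — below the voxel edge by
construction); masks are contiguous anterior-to-posterior slabs covering a
requested fraction of target regions within one hemisphere. Endpoints are
drawn from the morphological interior of each region, so a jittered point
that rounds one voxel off still lands in the same region and the
closed loop (generate -> build -> empty-mask resect) reproduces the target
connectome exactly at the default jitter.

Synthetic cohorts draw change-ratio features from a Beta distribution
parameterised by mean and concentration (support [0, 1] matches ratio
semantics; baseline mean 0.5, concentration 20, giving sd ~ 0.11). The
study conditions for recovery tests are: 60 subjects balanced across
outcomes, 200 features in blocks of (160, 34, 6) — the same ~0.8/0.17/0.03
block proportions as a full-scale cohort at desk scale — with 10 planted
connection features whose class means differ by 0.4, split symmetrically
around the baseline (seizure-free class has the greater reduction). A
single global seed fans out to per-component child seeds.

What passing these tests does *not* show: the phantoms contain no crossing
fibres, no partial-volume endpoint ambiguity, no registration error, and
Beta features have none of the dependence structure of real connectome
changes, so recovery results certify the machinery, not clinical
performance. Reproducing the published cohort's headline numbers (79.2%
accuracy, 15 selected connections) requires the clinical MRI data and is
explicitly out of scope.

## Numerical choices and test scale

- Mask binarisation threshold 0.5; zero-weight threshold 1e-8; FISTA
  tolerance 1e-8 (relative objective change).
- LOOCV accuracy of the two-step classifier on *null* cohorts is noticeably
  more variable across cohort draws than an iid-binomial model suggests,
  because the n fold predictions share training data and a weak classifier
  can anti-learn noise. The chance-level test therefore pins a fixed seeded
  cohort at a moderate operating point rather than asserting the band for
  every conceivable draw.
- Test problem sizes are chosen so exhaustive oracles stay exact and fast:
  graph oracles at <= 7 nodes (200 trials), elastic-net grid oracles at
  n = 6, m = 2, recovery runs on the 60 x 200 cohort with a reduced 5 x 8
  grid covering the same (lambda, rho) ranges as the full 800-point ladder.

## Known limitations

- Only the immediate network change is modelled: no plasticity,
  degeneration, or long-term rewiring.
- Streamline counts are the only edge weight; density- or volume-weighted
  variants are not implemented.
- The per-fold/full-cohort selection scope switch exists because two-step
  designs are often ambiguous on this point; the default is the
  leakage-free reading.
- `filter_streamlines` tests stored points only; callers feeding sparsely
  sampled polylines (point spacing above the voxel size) should resample
  first.
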