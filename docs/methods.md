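# Methods

This note documents the models and estimators implemented in `subnets`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Connectivity and density thresholding

Functional connectivity between nodes i, j is the Fisher transform
z = arctanh(r) of the Pearson correlation of their time courses. Because
arctanh diverges at |r| = 1, correlations are clipped to ±0.999999
(`r_max`) first, so duplicated signals produce a large but finite z.
Constant (zero-variance) time courses cannot be correlated; their rows and
columns are set to NaN and reported in the log rather than silently zeroed.
NaN is the single undefined/excluded marker throughout: the diagonal,
excluded short-distance pairs, and undefined entries are all NaN and never
participate in density computations.

Density thresholding keeps, for every row, its `ceil(density · (N−1))`
largest off-diagonal entries. An entry survives if it is top-k in its row
*or* its column (union rule), and the result is symmetrized; the union
preserves the per-row guarantee that at least k entries survive in every
row. Ties at the cutoff are broken by descending value then ascending
partner index, making the mask deterministic. Distances for the optional
short-range exclusion (default 20 mm, applied strictly: pairs with
d < 20 mm are removed) are 3-D Euclidean on the supplied coordinates;
geodesic distance along the mesh is out of scope. All coordinates are mm in
one declared space per analysis (MNI152 by convention); mixing spaces is an
error, never an implicit transform.

## Community detection

The optimizer is a pluggable contract with two backends: the map-equation
optimizer (igraph's Infomap implementation, quality = codelength) and
modularity Louvain (networkx, quality = modularity). Both are seeded and
deterministic given the seed. Graphs use only nonnegative edge weights
(negative z floored to 0), reflecting the positive-connectivity-only
philosophy of the approach. Communities smaller than `min_community_size`
(default 10 nodes; the sparse tier has no principled minimum, so this is a
configurable noise floor) are relabeled 0, and surviving communities are
renumbered 1..K by descending size.

Two tiers matter: a sparse tier whose communities are subnetworks and a
dense tier whose communities are large-scale networks. The canonical sparse
fraction is 0.001 (top 0.1% per row/column), meaningful on full-resolution
cortical matrices with tens of thousands of nodes. On a few-hundred-node
synthetic matrix that fraction retains less than one entry per row, so the
pipeline floors the working density such that each row keeps at least 8
neighbors (`scale_aware_density`), the smallest budget that keeps planted
blocks connected. The network tier default is 0.30: the dense tier must
retain enough neighbors per node to bridge sibling subnetworks (k beyond
the subnetwork block size), and 0.30 does so at every scale this toolkit
runs at; very large matrices can lower it.

A detected community counts as "within" a parent network when at least
`parent_overlap_fraction` (default 0.5, an open choice) of its nodes fall
inside the parent mask. The parent network itself is located by assigning
each dense-tier community to the template network with maximal Jaccard
overlap.

## Cross-subject matching

All subjects' subnetwork instances are compared pairwise by Jaccard
coefficient on binarized node sets (cortical nodes first; subcortex can be
examined afterward via structure tags). The instance × instance matrix is
clustered by Louvain passes repeated until modularity no longer increases,
with resolution 1.0 and a seeded pass schedule for determinism.
Within-subject instance pairs are included in the matrix; they are disjoint
by construction, hence overlap 0, and do not affect the result. Clusters
represented in fewer than `min_subject_fraction` (default 0.5) of subjects
are discarded — the half-of-subjects rule.

Density maps count *individuals*: a subject contributing two instances to
one cluster still adds at most 1 per node. Two thresholding rules are
provided: at-least-k subjects (default 3) and strictly-greater-than a
fraction of subjects (default 10%, strict, so 2 of 15 passes but 1.5 would
not). Winner-take-all maps assign each node to the cluster with the largest
count; zero-count nodes stay unassigned; ties are broken by cluster order
and additionally exported as a tie mask so no tie is silent.

## Meta-analytic annotation

A subnetwork's group topography is reduced to its connected regions:
components of the thresholded density map under mesh adjacency, dropping
components below `min_cluster_area_mm2` (default 20 mm²). A study in the
coordinate database matches the subnetwork when its peaks land strictly
within `peak_match_radius_mm` (default 2 mm) of at least
`region_match_fraction` (default 40%, ≥ with ceil) of the regions.
Peak-to-region distance is the minimum over region nodes (regions are
spatial extents, not points); a centroid mode is available behind a flag.
A study matching several subnetworks contributes its weights to each
matched group (symmetric treatment; multi-matches are countable from the
outputs). Matching is monotone: enlarging the radius or shrinking the
fraction never removes a matched study.

Per term, weights grouped by matched subnetwork enter a fixed-effects
one-way ANOVA; degenerate groupings (fewer than two groups with two
studies, or zero within-group variance) are skipped and logged, and FDR is
corrected only over terms actually tested. Significant terms are assigned
to the argmax-mean group (ties broken to the first-listed subnetwork,
logged) with display magnitude = max group mean − grand mean, a
presentation-only scale for word-cloud exports. Term curation (which terms
are task-related) is data, not code: a user-supplied include/exclude
lexicon applied by `term_filter`.

## Repeated-measures statistics

The ANOVA used for connectivity profiles and task means treats the level
(subnetwork or network) as fixed and the subject as a blocking factor, fit
as an additive two-way least-squares decomposition. With balanced data this
is exactly the classical repeated-measures F with df (k−1, (k−1)(n−1));
with missing cells the model simply omits them from the sums of squares and
reports the partial F for the level factor (this reproduces the slightly
irregular denominator df that unbalanced designs produce). A full
mixed-model REML fit is deliberately out of scope. Zero residual variance
(level differences identical in every subject) yields F = ∞ with an
explicit flag rather than an exception, and identical values across levels
give F = 0. Bonferroni correction is `min(1, p · n_tests)` over the
declared family (the number of networks or task conditions tested). Post
hocs are standard paired t tests on subject-wise differences with missing
pairs dropped.

Profile construction averages the subnetwork's node time courses and the
target network's node time courses, excluding target nodes overlapping the
subnetwork, then correlates the two means. When short-distance exclusion is
requested the estimate switches to the mean Fisher-z over node *pairs*
farther than the cutoff, because a mean time course cannot be pair-masked;
the two estimators agree when no short pairs exist. Negative connectivity
is retained in all statistics; dropping negatives is a plotting convention
only.

Spring-graph export defines nodes as contiguous clusters (> 20 mm²) of the
matched subnetworks and the declared networks, weights edges by the z of
cluster mean time courses, keeps the top 10% of edges, and raises the
density in 5% increments whenever all clusters of any declared network are
disconnected from the giant component, up to full density (then exported
with a warning). Graphs are written as GEXF and weighted edge lists;
force-directed layout is left to external tools.

## Lag estimation

Signals are detrended and band-pass filtered (zero-phase second-order
Butterworth) within each run separately; filters and lag estimates never
cross run boundaries, and per-run delays are combined by frame-weighted
average. The default band is 0.01–0.1 Hz, the conventional infraslow
range; the narrower 0.08–0.1 Hz band is equally selectable
(`lag_band_hz`) — the toolkit takes no position on which is intended, but
defaults to the wider band because a 0.02 Hz sliver of spectrum supports
few effective degrees of freedom on short runs.

The delay of y relative to x is estimated from the normalized cross-
covariance at integer-frame lags within ±`max_lag_s` (default 8 s). The
extremum of |cov| (sign recorded; anticorrelated pairs flagged) and its two
neighbors are fit with a parabola, giving a sub-frame delay; positive means
y lags x. An extremum at the window edge is flagged invalid, as is any node
whose |r| at the extremum falls below `lag_min_abs_r` (default 0.1). Seed
lag maps use the seed subnetwork's mean time course against every node.
Group ordering averages delays over each structure's valid nodes, then over
the seed maps within subject, then centers per subject (the zero point of a
lag map is arbitrary; only relative ordering is meaningful), and tests the
structure effect with a one-way ANOVA across structures with subjects as
observations, followed by paired t post hocs.

## Synthetic data

The generator emulates exactly what the pipeline consumes. Timeseries are
zero-mean Gaussian draws whose covariance is block-structured by the nested
hierarchy (defaults: within-subnetwork r = 0.6, within-network r = 0.3,
background 0; requested covariances that are not positive definite are
eigenvalue-floored with a warning). Planted lags ride on a shared unit-
variance band-limited (0.01–0.1 Hz) component added to every node, delayed
per structure by Fourier-domain fractional shifting, with amplitude
`lag_snr` (default 1) relative to the node noise — mirroring the
interpretation of lags as a travelling global signal. Topographic
variability across subjects is emulated by reassigning exactly
`round(fraction · N)` nodes (default 10%) to other labels. Synthetic
meta-analytic databases place, for "associated" studies, peaks within the
match radius of 80% of one subnetwork's region representatives, plus
background peaks kept at least 15 mm from all regions; planted terms get a
weight shift (default 0.2) in their target group, all weights clipped to
[0, 1]. Task maps are planted mean shifts plus unit Gaussian noise. The
node space is a 4-connected planar grid with 6 mm spacing (36 mm² per
node).

What the generator does *not* emulate: hemodynamics, spatial
autocorrelation of fMRI noise, heavy-tailed signals, AR(1) temporal
structure, subcortical SNR gradients, and real cortical geometry. Passing
the planted-recovery suites therefore demonstrates the correctness and
calibration of the algorithms under their stated assumptions, not
performance on real fMRI.

## Validation scales

The planted-recovery suites (`subnets.validation`, also driven by
`scripts/acceptance.py`) run at desk scale, chosen so the full set
completes in well under a minute of compute per suite: community recovery
on 20 datasets of 400 nodes × 2000 frames with a 3-network / 8-subnetwork
hierarchy; matching recovery on 10 subjects with 10% jitter, four common
and one 3-of-10 rare subnetwork, over 5 seeds; annotation validity on 20
databases of 500 studies × 250 terms with three planted associations
(shift 0.2) and ~247 null terms each; lag recovery over 20 replicates of
±2 s planted shifts at SNR 1 plus a 15-subject ordering ANOVA at 0.5 s
spacing. Determinism everywhere reduces to one integer seed; every derived
RNG stream is spawned from it.

## Known limitations

- Louvain clustering of the overlap matrix fixes resolution at 1.0; very
  unequal cluster sizes may require tuning.
- The repeated-measures ANOVA is the fixed-effects blocked decomposition,
  not REML; variance components are not estimated.
- Region extraction requires mesh adjacency; purely volumetric inputs need
  an edge list supplied by the caller.
- CIFTI-2 dense timeseries are read, not written; all outputs are TSV/JSON
  (and GEXF for graphs).
- The lag estimator assumes a single dominant cross-covariance extremum
  within the window; multi-peaked structures are reported by their largest
  peak only.
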