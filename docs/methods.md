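# Methods

`cortexdepth` implements a depth-resolved cortical quantitative-MRI (qMRI)
analysis for case–control studies of focal epilepsy: joint relaxometry to
estimate qT1/qT2, equivolume laminar sampling of those maps onto cortical
surfaces, permutation inference on depthwise values and intracortical
gradients, lesion z-score profiling, and held-out classification.  A
synthetic cohort generator provides data with the statistical structure
the analysis assumes, so every stage is testable end to end.

## Signal models and joint fitting

Quantitative T1 and T2 are estimated from five steady-state acquisitions
fitted jointly ("joint system relaxometry"): two spoiled gradient echoes
(flips 2.2° and 12.5°, TR 6.2 ms) and three balanced SSFP acquisitions
((12°, 180°), (49°, 0°), (49°, 180°) flip/RF-phase-increment pairs, TR
6 ms).  The SPGR magnitude is the Ernst steady state,
S = M0 sinα (1−E1)/(1−E1 cosα) with E1 = exp(−TR/T1); the bSSFP signal is
the Freeman–Hill phase-cycled steady state, in which the RF phase
increment Δφ acts as an extra precession per TR (θ = 2π f0 TR + Δφ).
With 180° cycling on-resonance tissue sits in the passband; with 0° it
sits at the stopband null, which is what makes the (49°, 0°)
acquisition T2-informative.  Both closed forms are validated against an
independent Bloch steady-state iteration to 1e−6 over a grid of
(T1, T2, flip, TR).

Fitting is bounded trust-region nonlinear least squares over
(M0, T1, T2): initialization T1 = 1000 ms, T2 = 80 ms, M0 scaled from the
largest measured signal; bounds T1 ∈ [100, 5000] ms, T2 ∈ [10, 1000] ms;
magnitude-only, on-resonance (no field maps are simulated).  Noiseless
round trips recover T1 and T2 to ≪0.1% over T1 ∈ [600, 2500] ms,
T2 ∈ [40, 150] ms, i.e. the protocol identifies all three parameters.
When each acquisition is acquired at a per-image SNR, inverse-variance
weights (1/measured signal) can be passed to `fit_jsr`; at per-image SNR
50 the median |T1| error is ≈1.8%, essentially the Cramér–Rao bound of
the protocol.  All-zero or non-finite voxels are flagged degenerate, not
fitted.

## Laminar geometry

A hemisphere is a white/pial surface pair sharing one triangulation, so
each vertex defines a white→pial trajectory.  Intermediate surfaces are
placed at fixed fractions of local cortical **volume**, not distance: the
wedge over a vertex's one-ring has cross-sectional area
A(t) = ((1−t)√A_w + t√A_p)², whose cumulative volume has the closed-form
inverse t(f) = ((a³ + f(b³−a³))^⅓ − a)/(b − a), a=√A_w, b=√A_p.  This
reduces to t = f on a flat slab and to cube-root radius interpolation on
a spherical shell — both used as oracles.  A_w/A_p are barycentric
one-ring vertex areas.

Volume-to-surface sampling is ribbon-weighted: the polyhedron spanned by
a vertex's one-ring between equivolume levels f±0.1 (so consecutive
20%-spaced depths draw from disjoint bands) is approximated by
deterministic quadrature points — one-ring cell points (corner, two edge
midpoints, centroid per incident triangle) at five sub-levels — and each
voxel's weight is the fraction of points it contains, an estimate of the
polyhedron/voxel overlap volume.  Sampling is *ribbon-constrained*:
candidate voxels whose centers fall outside the cortical ribbon (or
above the white surface, for sub-WM levels) receive no weight.  Weights
are non-negative and normalized per vertex, making constant fields exact
by construction; on linear-in-depth fields the error is voxelization
noise that shrinks monotonically as the grid is refined (checked at 2, 1
and 0.5 mm).  A level 1 mm below the WM/GM boundary (vertex − 1 mm ·
normal) supports transmantle probing.

Thickness is the Euclidean white–pial vertex distance.  Mean curvature
uses the cotangent Laplace–Beltrami of the coordinates normalized by
mixed Voronoi cell areas (barycentric areas bias the 12 valence-5
vertices of an icosphere by ~14%; Voronoi areas bring the sphere error
under 0.1%).  Geodesic distances are Dijkstra on the edge graph
augmented with across-edge shortcuts obtained by unfolding each pair of
adjacent triangles into a plane; this removes most metrication bias
(sphere antipode error ~0.04% versus ~6% for plain edge paths).

## Feature assembly

qMRI volumes are Gaussian-smoothed with σ = 0.4 mm before sampling (at
the native 1 mm isotropic resolution a σ in voxels and mm coincide; on
other grids σ is interpreted in mm).  Because fitted maps are zero
outside the brain mask, feature extraction smooths by normalized
convolution over the nonzero support, which prevents the background from
dragging near-pial values down; the plain Gaussian remains available.
Features per subject and modality are the maps at 20/40/60/80% depth
(plus the −1 mm level when requested) and the intracortical gradient,
value(80%) − value(20%) — an index of depthwise microstructural
organization.  For patients with a right-sided seizure focus the
hemisphere blocks are swapped so position 0 is always ipsilateral to the
focus; the mirrored mesh construction makes vertex correspondence exact.

## Group inference

At each vertex, Y = Xb + Zg with X the group indicator (or clinical
variable) and Z an intercept, mean-centered age, binary sex, and
*vertexwise* thickness and curvature columns rebuilt per vertex.
Inference statistics are TFCE enhancements of the t-map:
TFCE(v) = Σ_h extent(v,h)^E · h^H · dh with E=1, H=2, dh = max|t|/100,
extent measured as component surface area, and the negative tail treated
by enhancing −t.  TFCE is computed exactly in one sweep over the
component merge tree (events processed in descending threshold order,
contributions pushed to the leaves), which matches brute-force
per-threshold connected-component integration to machine precision and
keeps a 500-permutation analysis of ten maps on 1284 vertices near two
minutes on one core.

Permutation uses the Draper–Stoneman scheme — rows of X permuted, Y and
Z fixed, preserving the spatial dependence of the data.  Schedules are
drawn as distinct row-orders from a seeded generator; designs with few
distinct arrangements (e.g. 4-vs-4, 70 orders) switch to exhaustive
enumeration, where p-values are exact proportions.  Sampled p-values use
(1+b)/(1+m) counting, so the minimum attainable p is 1/(1+m) and p is
never zero.  FWE control within a contrast uses the max-TFCE null over
vertices; FWE *across* modalities and contrasts pools the per-permutation
maximum over every result sharing the schedule (the two one-sided
contrasts are sign mirrors of one enhancement map and are computed from a
single permutation sweep).  Results significant within a contrast but not
across constitute the trend-level category.  Monotonicity
(p_across ≥ p_within ≥ p_uncorrected) is asserted on every run.
Age-by-group interactions are screened with X = centered(group) ×
centered(age); skewed clinical counts (seizures/year) are
log-transformed before association testing.

## Lesion profiles

Lesion masks are mapped to the surface by sampling the binary mask with
the same ribbon weights; a vertex joins the footprint when its overlap
exceeds 0.5 at any depth, and the lesion center is the geodesic medoid
of the footprint.  Metric maps are residualized as Y − Z·ĝ with ĝ the
nuisance coefficients of the joint fit (group effect retained).  For
each lesion and level, the patient's within-mask mean residual is
z-scored against the distribution of control within-mask means
(mask-mean aggregation, ddof 1); |z| > 2 flags a deviation.  The −1 mm
level probes the transmantle sign.  Distance-decay curves bin a
vertexwise z-map by geodesic distance from the lesion center
(left-closed right-open bins at multiples of the width, empty bins
omitted), optionally zoomed to 50 mm.

## Classification

Whole-brain qT1 and qT2 gradient maps are concatenated per subject
(vertices invalid in any subject dropped cohort-wide), residualized for
age and sex with coefficients estimated on the training stratum only,
and classified by a 100-tree random forest (Gini impurity, √p candidate
features per split, bootstrap resampling — library defaults).  Training
and test strata are disjoint (e.g. MRI-positive patients + part of the
controls vs MRI-negative patients + the rest), in either direction.
Metrics: AUC from predicted probabilities, and accuracy, sensitivity,
specificity and F1 at the 0.5 operating point with patients positive.
The permutation p-value shuffles the class labels end to end
(independently within the training and the held-out stratum, preserving
each stratum's class balance) and reruns the whole
residualize→train→evaluate pipeline with the partition fixed,
p = (1 + #{AUC_perm ≥ AUC_obs})/(1 + n_perm) — the standard
classifier-significance permutation, testing the global null of no
feature–label association.  Permuting only training labels would leave
the held-out labels informative: near a strong effect, permutations
whose labels happen to align with the true groups still classify the
intact test set well, saturating the null distribution at the observed
AUC and capping the attainable p far above 1/(1+n_perm) regardless of
the effect.  An automated audit checks that shuffling held-out labels
changes nothing fitted upstream of evaluation.

## Synthetic cohorts

The generator is a reduced-scale digital phantom chosen to make every
oracle analytic.  Each hemisphere is a closed icosphere (subdivision 3,
642 vertices; left = mirror of right, so homologous vertex
correspondence is exact); white radius 20 mm; thickness 3.0 ± 0.25 mm
varying smoothly (random dipole pattern per subject); 1 mm isotropic
voxels.  Voxels take the laminar profile value at their center's
equivolume fraction, with no partial-volume mixing.  Default profiles
(piecewise linear in fraction): qT1 850→950→1900 ms and qT2 55→60→90 ms
from −0.2 (white matter) through 0 (WM/GM boundary) to 1 (pial),
increasing toward the pial surface as in cortex at 3 T.  Subject
variation: global per-modality offsets (SD 20 ms qT1, 1.5 ms qT2 — the
"control SD" unit in which lesion amplitudes are expressed), linear age
slopes (−5 ms/yr qT1, −0.3 ms/yr qT2 over ages 4–18), additive voxel
noise (30 / 2 ms), and the thickness field.  Clinical variables: onset ~
Uniform(1, age), duration = age − onset, seizures/year ~ LogNormal(3, 1)
(the skewness motivating the log transform).

The default cohort is 20 patients vs 20 controls with a +5%
multiplicative patient effect at equivolume fractions ≥ 0.6 — a
superficial-depth effect that produces steeper white→pial gradients in
patients.  40% of patients are tagged MRI-positive.  Lesions are
geodesic patches (default radius 8 mm) shifted by amplitude_sd ×
per-subject SD down to a transmantle depth; a transmantle column also
marks voxels it intersects (half a voxel beyond its nominal floor),
while purely cortical lesions stop at the boundary — with 1 mm voxels
this is what makes the −1 mm level sensitive to a 1 mm transmantle sign
and blind to a gray-matter-only lesion.  Because a single lesion's
z-profile rides on its subject's global offset (≈ ±1 SD), the test and
acceptance cohorts plant three transmantle and three gray-matter-only
lesions and assess the sub-WM contrast on the mean z per lesion kind,
mirroring the multi-lesion design such profiling is used for.

What the phantom does not emulate: gyrification (curvature varies only
via the sphere), B0/B1 artifacts, motion, partial-volume mixing, spatial
autocorrelation of noise, and realistic effect topographies.  Passing
tests therefore demonstrate correctness of the machinery and calibration
of its inference under the stated generative law, not clinical
performance.

## Problem sizes and numerical choices

Analyses in the test suite and acceptance script use the default
642-vertex hemispheres, 40-subject cohorts and 500 permutations for the
depth analysis; 999 permutations for the classifier p-value; calibration
simulations run 500 (uniformity) and 200 (joint FWE) repeats at 200
permutations on a 42-vertex sphere, where the calibrated object is the
permutation/TFCE machinery itself.  Ties in permutation counts are
resolved with a 1e−12 tolerance in favor of the null (conservative).
Degenerate inputs are flagged rather than silently handled: all-zero
signal vectors, rank-deficient design vertices, zero-SD z-scores,
vertices whose sampling polyhedron meets no usable voxel, and
disconnected mesh components in geodesics.

## Known limitations

Graph-based geodesics (even with unfolding shortcuts) are not exact
polyhedral geodesics; the ribbon overlap estimator is a point quadrature,
not exact clipping; equivolume trajectories are straight segments, which
is exact for the phantom but an approximation on folded cortex; the
voxel-center value assignment makes near-boundary samples biased at
coarse voxel sizes (quantified by the convergence tests).  The joint
FWE-across correction assumes all results share one permutation
schedule; mixing schedules is rejected rather than silently accepted.
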