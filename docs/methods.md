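# Methods

## Model and assumptions

The pipeline treats each body segment (pelvis, femur) as a rigid body
carried by a cluster of skin markers. The neutral (imaging-frame)
coordinates of the skin landmarks and of the bone landmarks/mesh are
assumed known and mutually consistent; per capture frame, the segment
pose is the least-squares rigid transform taking the neutral skin
cluster onto the measured marker positions. The key assumptions are:

* **Rigidity.** Skin markers move rigidly with the underlying bone.
  Soft-tissue artifact (STA) violates this; empirically most STA energy
  is a rigid cluster translation/rotation, which the least-squares fit
  partially absorbs, and the residual non-rigid part appears as
  registration residual. The `add_sta_perturbation` generator injects
  controlled non-rigid motion to quantify this sensitivity; tests
  assert that the residual grows monotonically with STA amplitude.
* **Static marker-bone relation.** The imaging-frame relation between
  skin and bone landmarks (acquired supine) is assumed to hold during
  gait. This restricts validity to low-amplitude movements such as
  walking.
* **Rigid-only transform.** Scaling and deformation are excluded by
  construction; the estimator returns a proper rotation (det = +1) in
  all cases via the reflection correction.

## Registration details

The closed-form Kabsch solution is used (centroids, decentring,
H = P′Q′ᵀ, SVD, R = VUᵀ, t = −RμP + μQ). When det(VUᵀ) < 0 (possible
for noisy or near-planar clusters), the column of V belonging to the
smallest singular value is negated — the standard correction that
preserves least-squares optimality among proper rotations. A minimum
of 3 non-collinear points is enforced (collinearity test: second
singular value of the decentred source < 1e-6 × the largest). Landmark
weights are uniform. The translation is a 3-vector. Geodesic
misorientation — the rotation angle of R₁ᵀR₂, computed via atan2 of the
antisymmetric part so small angles keep full floating-point
resolution — is the angular-error definition used throughout; an
alternative definition through landmark position vectors would be
possible, but cluster misorientation is the quantity the rigid model
actually estimates.

Equivalence with an independently coded quaternion absolute-orientation
solver (Horn's method) is asserted on 1000 random instances to
1e-8 degrees / 1e-8 mm.

## Distance definition

The bone-to-bone distance is the minimum Euclidean distance between two
posed triangulated cortical regions, evaluated point-to-triangle in
both directions (vertices of one surface against faces of the other).
Vertex-to-vertex sampling would bias the minimum upward on smooth
cortical surfaces; point-to-triangle removes most of that bias at mesh
resolution. Faces belong to a region of interest (ROI) when all three
vertices do. ROIs are user-supplied index sets: anatomical phrases
like "lateral cortex of the ischial tuberosity" have no algorithmic
definition, so automatic ROI extraction is out of scope, and a
full-surface ROI reproduces the untrimmed reading.

The search is accelerated by a KD-tree vertex-pair upper bound followed
by triangle bounding-sphere pruning; the pruning is conservative, so
the result is exactly the brute-force all-pairs minimum (asserted
against an independent brute-force oracle on random mesh pairs).
Intersecting surfaces report distance 0 with a contact flag;
penetration depth is not computed.

## Events and normalization

Heel strike and toe off are upward/downward crossings of a 10 N
threshold on the vertical ground-reaction force; crossings closer than
50 ms are merged (debounce — the threshold alone is the stated
protocol, the debounce window is this package's choice for noisy force
plates). A gait cycle runs heel strike to next ipsilateral heel
strike. Curves are linearly interpolated onto **Q = 101** equally
spaced cycle percentages (0, 1, …, 100 %) — the standard grid for 1D
gait inference; sub-percent cluster endpoints come from interpolation
at the threshold crossing, not from a finer grid. Marker gaps of up to
10 frames are filled by cubic spline; longer gaps invalidate the frame,
and frames with fewer than 3 valid markers are flagged invalid rather
than guessed.

## Validation metrics

* **RMSE (distance)**: root mean square Euclidean landmark error over
  frames and landmarks, mm.
* **RMSE (angle)**: root mean square geodesic misorientation, degrees.
* **CMC**: the between-session (Kadaba-style) coefficient of multiple
  correlation,
  CMC = √(1 − [ΣΣ(Y_gf − Ȳ_f)²/(F(G−1))] / [ΣΣ(Y_gf − Ȳ)²/(FG−1)]).
  When the variance ratio exceeds 1 (e.g. parallel constant waveforms)
  the square root is undefined; the implementation returns 0 with a
  degenerate flag rather than a complex value.
* **LFM**: ordinary least squares of the test waveform on the
  reference; R² is the squared Pearson correlation, so it is symmetric
  while the slope is not.
* Group summaries report mean, SD, a normal-approximation 95 % CI
  (mean ± 1.96·SD/√n; at the frame counts involved a t-based interval
  differs negligibly) and RMSE; the pooled "Total" row concatenates
  frames rather than averaging group statistics.

## 1D inference

Pointwise two-sample (pooled variance, df = n₁+n₂−2) or paired
(df = n−1) t statistics are formed at each node; tests are two-sided on
|t| with the signed curve preserved for plotting.

* **Normality gate.** D'Agostino–Pearson K² on the model residuals at
  every node, Bonferroni-corrected across the 101 nodes so that
  Gaussian data do not trip the gate merely by being tested 101 times;
  any corrected rejection selects SnPM, otherwise SPM. Fewer than 8
  residuals per node defaults to SnPM with a warning (K² needs n ≥ 8).
* **SPM threshold.** The 1D Euler-characteristic approximation for
  smooth t fields, P(max T > u) ≈ P(T > u) +
  (L/FWHM)·(√(4 ln 2)/2π)·(1 + u²/ν)^(−(ν−1)/2), with L = Q − 1 node
  intervals and FWHM estimated from normalized residual gradients
  (FWHM = √(4 ln 2 / v̄), v̄ the mean squared gradient of the
  unit-variance residual field); solved for u by bracketing. Cluster
  p-values use the same tail at the cluster maximum (max-t
  approximation; set-level RFT inference is out of scope).
* **SnPM threshold.** The max-over-nodes |t| across group-label
  permutations (independent) or sign flips (paired), vectorized;
  exhaustive enumeration whenever the number of distinct rearrangements
  is ≤ the permutation budget (default 10 000), otherwise seeded random
  sampling that always includes the identity rearrangement (this keeps
  the test level-α). The critical value is the ⌊αM⌋-th largest of the
  M maxima; with exhaustive enumeration the test is exact. Designs
  with fewer than 20 distinct rearrangements cannot reach α = 0.05 and
  are rejected with an error. Cluster p = fraction of permutation
  maxima ≥ the cluster max. SnPM is the primary inferential path; the
  RFT-based SPM mirrors common practice and is validated against
  Monte-Carlo family-wise error only.

Supra-threshold cluster endpoints are linearly interpolated between
nodes and reported as percent of cycle with 2 decimals.

## Synthetic data

The generators define the study conditions rather than emulating any
particular laboratory's noise:

* **Sphere phantom**: radius 50 mm, five surface/bone landmark pairs
  with distinct offsets {5, 8, 11, 14, 17} mm along local normals
  (pairs spread over both sides of the sphere by a Fibonacci layout).
  The commanded motions are a 300 mm constant-speed slide along an
  oblique axis over 990 frames and a 90° constant-rate rotation about a
  fixed axis through the mount point over 1435 frames, both at 100 Hz.
  The slide distance, rotation angle, frame counts and rate follow the
  physical validation protocol; the radius and offsets are free choices
  (the physical sphere's dimensions are not published). Marker noise
  is isotropic Gaussian with user-set SD; real optical noise is
  structured and hardware-dependent, so no attempt is made to reproduce
  any measured error magnitude — what the noiseless tests show is that
  the algorithmic chain is exact, and the noisy tests that error scales
  linearly with injected noise.
* **Gait scene**: deliberately schematic rigid bodies (pelvis block
  with an ischial prominence, femur shaft with a lesser-trochanter
  prominence) whose relative translation follows a smooth two-harmonic
  profile, giving a truth IFS that peaks near 30 % (mid-stance) and
  dips near 65 % (initial swing) of the cycle with a neutral value of
  ≈30 mm, inside the healthy in vivo range. The affected cohort's IFS
  is reduced by a configurable effect over a mid-cycle Gaussian
  window; a synthetic GRF crosses 10 N at the cycle boundaries. No
  anatomical realism, muscle-driven dynamics or STA is implied.
* **Cohort curves**: smooth Gaussian random curves (template + noise of
  given pointwise SD and FWHM ≈ 15 nodes) used for the inference
  calibration studies; Monte-Carlo sizes are 1000 null datasets
  (family-wise error) and 200 effect datasets (power) at 1000
  permutations each, which gives ±1.4 % binomial resolution on a 5 %
  rate while keeping the whole suite interactive.

## Numerical choices and edge cases

* Internal units are fixed (mm, N, Hz, degrees); unit conversion only
  at I/O boundaries (e.g. TRC files declaring metres).
* Orthonormality/properness of rotations validated to 1e-6 on input,
  produced to machine precision by construction.
* Zero-variance nodes in t fields yield t = 0 with a warning instead of
  ±∞ (identical groups otherwise produce NaN thresholds).
* Tie-break in the permutation threshold: the sorted-descending
  ⌊αM⌋-indexed value, with strict exceedance required for cluster
  formation — conservative at small M.
* Degenerate CMC (variance ratio > 1) returns 0 + flag; constant
  reference waveforms make the LFM slope undefined and raise.

## Known limitations

* STA is not modelled dynamically; the static marker-bone relation is
  the main real-data error source and is only probed synthetically.
* Anatomical ROIs must be supplied by the user.
* Penetration depth of intersecting surfaces is reported as 0/contact.
* The independent-groups comparison treats hips as independent
  observations even when both hips of one subject are included — this
  mirrors common practice in the application domain but is a
  statistical caveat, not an endorsement.
* C3D motion-capture files are not read; use the TSV or TRC dialects.
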