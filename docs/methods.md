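# Methods

## Geometry

**Coordinate convention.** All coordinates are right-handed LPS
millimetres (x left, y posterior, z superior), the native convention of CT
imaging. 3D Slicer fiducial files declaring RAS are converted on read by
the involution (x, y, z) → (−x, −y, z). Left-side scapulae can be mirrored
across the sagittal plane (x → −x) so the right-side axis convention
applies throughout; mirroring is off by default because a study may equally
ship all-right data.

**Scapula frame.** Given an AA/IA/TS triplet, Z = unit(TS − AA) (medial
for a right-convention scapula), X = unit(cross(TS − AA, IA − AA)) — the
normal of the landmark plane pointing anteriorly — and Y = Z × X
(superior). The origin is AA: orientation angles are translation
invariant, but a definite origin is needed to re-express coordinates, and
AA is the natural anchor because the Z axis emanates from it. The matrix is
re-orthogonalized by SVD before the strict orthonormality/determinant check
(columns orthonormal to 1e-9, det = +1). Triplets whose triangle area is
below 1 mm² are rejected as degenerate: at CT scale a sub-millimetre
landmark triangle can only be a digitization failure.

**Average frame and re-expression.** Per scapula, the frame is built from
the per-landmark means over all observers and measures; each digitization
is mapped by p → Rᵀ(p − mAA). Because both the mean and each record
undergo the same rigid imaging pose, the re-expression cancels the pose
exactly — the package asserts invariance to an arbitrary rigid transform of
all raw landmarks to 1e-8 mm/deg.

**Thorax frame and Euler angles.** Thorax landmarks are not visible in
shoulder CT volumes, so the thorax frame is pinned at a published resting
scapulothoracic pose, default (41.1, 5.4, 13.5)° of protraction / medial
rotation / anterior tilt. The three successive rotations compose in the
same mobile-axis YXZ sequence used for extraction (R = Ry·Rx·Rz), with
positive pose values mapping identically onto the signed (e1, e2, e3); the
labels follow the field's convention (e3 is called internal/external
rotation even though the pose's third component is named anterior tilt).
Extraction uses e2 = −asin(R[1,2]), e1 = atan2(R[0,2], R[2,2]),
e3 = atan2(R[1,0], R[1,1]); when |R[1,2]| is within 1e-9 of 1 the
decomposition is singular and the package raises rather than clamps —
physiological scapular poses sit far from ±90° of lateral/medial rotation,
so a near-singular configuration indicates corrupt input, not anatomy.

## Reliability model

Each parameter series (9 average-frame coordinates, 3 angles) on the
balanced grid follows the crossed main-effects random model
y_som = μ + a_s + b_o + c_m + ε, with *measure* a crossed random factor
whose levels are the repetition index — the only reading under which a
measure main effect exists. No interaction terms are modelled; the
residual absorbs them (df = N − n_s − n_o − n_m + 2).

Components are the closed-form balanced ANOVA (method-of-moments)
estimators: σ̂²_res = MS_res and σ̂²_s = (MS_s − MS_res)/(n_o n_m) (likewise
for observer and measure). Negative estimates are truncated to zero
*before* summation, so σ²_total equals the reported component sum exactly
and ICCs stay in [0, 1]; pre-truncation values are kept in a diagnostics
field. A closed-form estimator was preferred over REML for exact
reproducibility and testability against an independent expected-mean-squares
oracle.

ICC_intra excludes measure + residual variance from the numerator,
ICC_inter excludes observer + residual; SEM = sqrt(σ²_total (1 − ICC)).
Since both SEMs share σ²_total, sem_intra²(1 − icc_inter) =
sem_inter²(1 − icc_intra) — an identity the tests enforce to 1e-10 and the
acceptance script uses to reconstruct one SEM from the other's printed
pair.

**Mean absolute deviation** is |y_som − ȳ_s| pooled over all N
observations, summarized as mean, SD and the normal-approximation 95% CI
mean ± 1.96·SD/√N. Pooling over all N deviations (rather than over
per-scapula means) is the convention here; it is configurable in the sense
that the per-scapula deviations are recoverable from the coordinate
tables.

**Degenerate series.** When a series' spread is at numerical-noise level
(range ≤ 1e-9 of the value scale — e.g. a zero-noise simulation, where
float residue still leaves ~1e-13 variation), ICCs are reported as
undefined rather than as ratios of rounding error.

## Synthetic generator

The generator emulates the balanced study: per scapula a true triplet =
template + per-coordinate Gaussian anatomy offset (sd_scapula), posed by a
random rigid transform (uniform rotation axis, angle ≤ pose_spread, uniform
translation); per digitization, observer (b_o, constant across scapulae and
measures), measure (c_m) and residual offsets added in the scapula's local
pre-pose axes. Defaults: 81 × 3 × 3; sd_scapula = 5 mm (centimetre-scale
anatomical variation between patients), sd_observer = 0.3 mm,
sd_measure = 0.2 mm, sd_residual = 0.8 mm (sub-millimetre digitization
offsets, the regime reported for manual landmarking on CT surface models);
pose spread 30° / 50 mm. The template is a synthetic convenience, not
anatomy: AA at the origin, TS at (0, 0, 100) mm, IA at (0, −120, 60) mm,
chosen so the canonical frame is the identity. Effects are Gaussian; one
RNG stream per effect type is split from the master seed so toggling one
component does not shift the others.

**What the generator does and does not emulate.** Local-axis injection
makes the observer/measure/residual scales map one-to-one onto the
downstream per-axis series (the noise is isotropic and the per-scapula
frame rotation is fixed). The anatomy component, however, is partially
absorbed by the average-frame alignment: mean AA is pinned to the origin,
mean TS to +Z and mean IA into the Y–Z plane, so between-scapula variance
survives only in IA_Y, IA_Z and TS_Z (and, to first order, var(TS_Z) ≈
2·sd_scapula² because TS_Z is the AA–TS distance). This mirrors the
structure of real digitization studies — poor ICC with small SEM for the
pinned coordinates — and is asserted by the tests. The generator does not
model real morphological variation (acromion shape classes beyond the
polyline profiles, segmentation error, partial scans), so green tests show
the *pipeline and estimators* are correct under the stated model, not that
any particular bone population behaves this way.

The acromion polyline generator produces planar curves whose interior
turning angles equal a requested profile to 1e-9°, covering the observed
morphology classes: one clear angle, several angles (detector warns and
takes the first), and curved transitions with no angle above threshold
(detector raises). The AA rule uses a strict > 45° comparison; the TS rule
("apex of the root triangle") has no operational curve-level definition and
is deliberately not automated — synthetic data carries TS ground truth
directly.

## Estimator-recovery study conditions

The ICC recovery property uses the scalar crossed-effects sampler directly
(2000 scapulae × 3 × 3, 100 seeds) with generative components
(0.90, 0.005, 0.005, 0.09), total 1. The observer and measure components
are deliberately small relative to anatomy: with three observers their mean
squares carry only 2 degrees of freedom, so σ̂²_o ≈ σ²_o·Exp(1) no matter
how many scapulae are sampled — per-seed recovery of ICC to ±0.03 is only
achievable when those components are a small fraction of the total, which
is also the regime of the motivating application (sub-millimetre observer
offsets against centimetre anatomy). Their unbiasedness is tested
separately on batch-averaged pre-truncation estimates.

## Numerical choices

- Orthonormality/determinant tolerance 1e-9 on every constructed frame;
  SVD re-orthogonalization absorbs accumulated rounding first.
- Gimbal tolerance 1e-9 on the arcsine argument; hard error, no clamping.
- Angles are reported in degrees, computed in radians.
- IA detection ties break to the lowest vertex index; AA detection is a
  strict first-exceedance walk from the anterior end of the edge.
- Randomized measurement lists are seeded permutations of the full
  (scapula, measure) grid; blinded ids are zero-padded integers assigned
  *after* shuffling so labels carry no scapula information.
- Display rounding in reports: 1 decimal for mm/deg quantities, 2 for
  ICC; full precision is preserved in the JSON output.

## Limitations

- Balanced designs only: unbalanced data is rejected, not reweighted,
  because the closed-form estimators assume the full grid.
- No F-distribution confidence intervals for ICC, and no REML inference
  for missing data.
- The thorax frame is a population-level resting pose, not
  subject-specific; glenoid version/inclination and mesh-based landmark
  extraction are out of scope.
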