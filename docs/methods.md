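# Methods

## The transform and its conditioning

The core mapping is solved from three landmark pairs per leg. With edge
matrices `M` (segment one) and `M′` (segment two) built from rows `(A−B)`,
`(C−B)` and their cross product, the segment-two→one map is
`X = B + M⁻¹M′(Y−B′)`. Two properties drive the implementation:

- **Existence/uniqueness.** `det M = |(A−B)×(C−B)|²` vanishes exactly for
  collinear landmarks. We normalize `|det M|` by the cube of the RMS side
  length of the landmark triangle, giving a dimensionless non-collinearity
  score, and reject triples below `1e−6` — the exact-zero condition padded
  to keep the solve well conditioned for nearly collinear picks.
- **Rigidity.** For congruent triangles `M⁻¹M′` is a proper rotation
  (never a reflection: a 3-point correspondence with matched handedness of
  the cross product fixes orientation). With real, slightly deformed
  anatomy the matrix drifts off the rotation manifold; the *congruence
  residual* (maximum pairwise-distance mismatch, mm) quantifies this.
  Residuals above 5 mm produce a warning but never an abort — soft-tissue
  change between the sessions is expected and the three-equation solution
  remains the defined behaviour. Reported rotation angles are read off the
  polar factor of the linear part, which is exact in the congruent case and
  the nearest-rotation estimate otherwise.

Landmark pick order is arbitrary: correspondence minimizes the sum of
squared pairwise-distance differences over all six permutations
(exhaustive; ties broken lexicographically). The anchor vertex **B** is the
point with the smallest sum of distances to the other two, chosen on the
segment-one triple and carried to segment two through the correspondence,
so the solved transform is invariant to pick order. Duplicate picks
(coincident points) raise immediately.

All geometry lives in patient-space millimetres. One transform per leg
therefore drives both the CT and the PET resampling of that segment,
which is also what compensates for differing fields of view, zoom factors
and voxel sizes between PET and CT and between the segments.

## Grids, resampling, stitching

The output grid adopts the upper segment's spacing, orientation and
in-plane extent and extends the upper slice lattice toward the feet until
every rigidly transformed corner of the lower grid is covered. Keeping the
upper lattice means upper-segment slices are copied bit-identically — the
method never alters segment one.

The lower segment is populated by inverse mapping (output voxel → segment
two), which is the same point correspondence as the forward statement but
leaves no holes. Sampling is trilinear over the 8 surrounding voxel
centers; points outside the voxel-center hull return air. Each leg is
sampled from its own side of the leg split only (the other side is masked
to air before interpolation), so independently moved legs cannot bleed
into each other; output voxels claimed by neither leg are filled with
−1000 HU (CT) or 0 (PET). There is no seam blending or blur equalization:
both would alter quantitative values, so the seam is a hard cut at the
stitching plane. The default plane is the axial plane through the centroid
of the six upper-segment landmarks (user-overridable); any plane inside
the overlap band is valid.

The leg boundary itself is the per-axial-slice minimizer of the
anterior–posterior column sums over the central half of the left–right
extent (ties to the column nearest the midline), smoothed with a 5-slice
running median. If no column is close to air (legs touching), the slice
falls back to the image midline with a warning.

Interpolation at off-lattice points low-pass filters the lower segment, so
a texture change at the seam and slight widening of oblique structures in
reformats are expected; lattice-aligned motions (pure integer-slice
translations) reproduce input values exactly.

## Decay correction

PET series are conventionally decay-corrected to their own series start.
Bridging the two segments therefore needs one factor,
`2^(Δt/T½)` with Δt the difference of the series reference times, applied
to the *second* segment. The correction multiplies the DICOM
`RescaleSlope` of former segment-two slices; pixel payloads are never
requantized, so no precision is lost. The second segment's acquisition
time is then set to the first segment's so downstream software cannot
correct twice. The half-life comes from the series' radiopharmaceutical
information; when absent, ¹⁸F (6586.2 s) is assumed with a warning.
Date+time composites are used throughout, so acquisitions crossing
midnight cannot produce a negative wrap; genuinely out-of-order segments
(negative Δt) warn and apply a factor below one. Physiological
redistribution between the sessions is out of scope — no decay factor can
account for it.

## BB detection defaults

BBs and metal implants have similar CT values, so a bare threshold cannot
separate them; size and position can. Defaults (all configurable):
threshold 2000 HU; component volume 1–100 mm³ (a 2 mm pellet spans at most
a few voxels at 0.97×0.97×3.27 mm, implants are far larger); centroid
within 10 mm of the body surface (taped to skin vs. implanted bone); body
surface from a −400 HU mask keeping the two largest components per slice.
Candidates are intensity-weighted component centroids ranked by peak HU,
which localizes well below one voxel on synthetic data. Too few survivors
raise an error directing the user to manual specification; extra
candidates are returned with a warning.

## The phantom generator

The generator emulates a two-bottle physical phantom: two water cylinders
(radius 45 mm, spanning the full axial field of view so every slice
carries signal) at ±60 mm, uniform ¹⁸F activity of 3.33 kBq/cc, three BBs
per cylinder on the surface inside the overlap band, a modest per-leg
rigid motion between segments (4° / −3° about near-axial axes plus a few
mm of translation) and a 30-minute inter-segment delay during which the
activity decays by exactly `2^(−Δt/T½)`. Default grids: CT 256×256×120 at
0.97×0.97×3.27 mm, PET 128×128×120 at 2.73×2.73×3.27 mm, 52.32 mm
(16-slice) overlap. Volumes are rendered analytically at voxel centers;
BBs use 4× supersampled partial-volume weighting with 8000 HU at 1.5 mm
radius, chosen so the brightest voxel clears the 2000 HU detection
threshold at any sub-voxel placement. Everything is deterministic given
the seed, and DICOM UIDs are derived from it, so regeneration is
byte-identical.

PET noise is Gaussian with standard deviation proportional to the local
true activity (default 5% coefficient of variation), a stand-in for
reconstruction noise that keeps air at exactly zero; CT noise defaults to
off. What the generator does *not* model: PET projection/reconstruction
physics (OSEM texture, scatter, randoms, partial-volume blur at the
cylinder edge), CT beam hardening, and soft-tissue deformation — so
passing tests demonstrate the correctness of the geometry, resampling,
decay and DICOM bookkeeping under the stated noise, not robustness to
scanner-specific artifacts. A feet-first option writes the lower segment
with flipped orientation tags to exercise patient-frame normalization in
the reader.

The activity profile mirrors the validation convention: per axial slice,
the mean over exactly 50 pixels nearest the activity-weighted in-plane
centroid of the selected leg. The acceptance evaluation excludes the two
lowest output slices, which sit at the foot-end boundary of the extended
grid where the rigid motion leaves the lower acquisition only partially
covering the slice.

## Numerical choices and degeneracies

- Values are carried in stored integer units with the rescale mapping
  alongside; resampled values are rounded to the nearest stored integer,
  so lattice-aligned resampling is bit-exact.
- Slice ordering uses the projection of `ImagePositionPatient` on the
  slice normal; a slice-interval spread above 0.01 mm, mixed series UIDs
  or missing geometry tags abort the read.
- The stitched series keeps the study UID, generates fresh series and
  instance UIDs, and records the actual output slice count in
  `NumberOfSlices` (overlap slices replaced by upper-segment content are
  not double-counted).
- Stored-value overflow of int16 after a slope change raises with the
  minimal slope that would fit.
- Output voxels where both legs' inverse maps land in valid territory
  (possible only in the air between the legs) deterministically take the
  left leg's sample.

## Problem sizes

Unit and property tests run on coarse grids (96×96×36 CT at 2×2×3 mm,
scaled BBs) chosen to exercise every code path in seconds; the end-to-end
accuracy evaluation and the acceptance script use the full default scale
above. Parameter-recovery checks use an intermediate 192×192×60 grid at
1.2×1.2×3.27 mm, where the CT voxel diagonal — the natural localization
limit for detected BBs — is 3.7 mm.
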