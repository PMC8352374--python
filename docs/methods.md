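# Methods

## Problem and scope

`hifuplan` answers a geometric accessibility question: what fraction of a
pelvic target can an MRgHIFU treatment cell reach without any part of the
acoustic beam crossing bone, extracorporeal air, or an organ at risk? It
covers transducer/couch geometry, ray-traced obstruction testing, the
exhaustive pose sweep and coverage metrics, landmark affine registration,
automatic body/air segmentation, home-position estimation from couch
deformation, and phantom generation. Acoustic propagation, thermal dose
and tissue heating are deliberately out of scope: a "covered" voxel is
geometrically reachable, not necessarily ablatable.

## Coordinate conventions

World coordinates are right-handed millimetres: LR (x), AP (y, positive
anterior — up on the couch, since the transducer sits below the patient),
IS (z, positive superior). Volumes are axis-aligned with voxel-centre
convention and 0-based indices; world→voxel mapping rounds to the nearest
centre with `np.rint` (exact half-voxel ties round to even). The magnetic
isocentre is the spatial reference; the transducer home position lies
`home_below_isocentre` (140 mm) straight below it.

## Device model

* **Elements.** The 256 element centres lie on a spherical cap of radius
  equal to the focal length (140 mm), curvature centre at the focus,
  within a 130 mm aperture. The physical element arrangement is not
  public; the default layout is a deterministic Fermat (sunflower) spiral,
  which gives near-uniform area density, with a concentric-rings layout
  available (`layout="rings"`). Coverage results depend on the ray
  *envelope* far more than on the exact arrangement.
* **Beam.** One straight ray per element, element centre → focus,
  discretised at 0.2 mm (`sample_spacing`); each ray includes its element
  endpoint and excludes the focus (the focus lies inside the target, which
  must not block its own beam). Point count per ray is
  `floor(length / spacing)` with a 1e-6 relative tolerance so exact
  multiples are not lost to floating point. The post-focal far field is
  not tested.
* **Poses.** Translation grid: LR/IS clipped to the target bounding box
  (configurable margin), AP over the full device range (−33 … +34 mm),
  all at `translation_step` (default 4 mm, the whole-pelvis step; 2 mm is
  the tumor-scale setting); tilt −10° … +10° in 2.5° steps about the IS
  axis only, pivoting at the transducer apex (the gimbal sits under the
  dish; the pivot is not documented for the physical device). Positive
  tilt leans the beam toward +LR. Pose ordering is LR, IS, AP, tilt,
  ascending; coverage is a pure union so the order never affects results.
* **Treatment cell.** Ellipsoid, semi-axes (4, 4, 10.92) mm, long axis
  along the beam axis, boundary inclusive (≤). Its analytic volume,
  (4/3)π·4²·10.92 ≈ 731.9 mm³, anchors the Monte-Carlo integration test.

## Obstruction test and coverage

A pose is usable iff no ray sample maps (nearest voxel) into
bone ∪ extracorporeal air ∪ OAR. Samples outside the volume are treated as
unobstructed — they lie in the oil bath / couch region outside the imaged
field of view. A `tolerated_blocked_fraction` option (default 0, the
strict any-ray rule) exists for sensitivity studies. Soft tissue other
than the listed obstructions is acoustically transparent, and no safety
margin is dilated onto obstructions by default.

Implementation: per tilt angle the rotated ray cloud (~179k samples) is
cached in voxel units; per pose one add + round + gather against the
obstruction volume padded with a one-voxel `False` border (clipped indices
of out-of-bounds samples land on the border, implementing
"outside = unobstructed"). The 0.2 mm sampling is finer than any voxel
spacing in use, so a ray cannot step over a voxel; tests bound the
discretisation error against a brute-force 0.01 mm ray walk and an
independent naive sweep must reproduce the covered voxel set exactly.

`TVC_pat = 100·CV/TV` uses covered-voxel count × voxel volume.
`TVC_vol = 100·|A∩B|/|B|` is computed voxel-wise on the shared treatment
grid (B = treatment covered set); when nothing is reachable during
treatment the ratio is undefined and reported as null.

## Registration

A full 12-parameter affine (not rigid/similarity — the reference clinical
tool computed an affine) is fitted by linear least squares to ≥4
non-coplanar paired landmarks; degeneracy is detected via the smallest
singular value of the centred source points. A Kabsch rigid fit is
available for sensitivity checks, and the fit is cross-checked against
SimpleITK's landmark initializer in the tests. Resampling pulls each
reference voxel through the inverse transform: trilinear interpolation for
intensities, nearest-neighbour for masks (labels stay binary; the
interpolation used by the original software is unknown). Registration
error is the mean Euclidean distance between corresponding points —
landmark placement is a file input; interactive picking is out of scope.

## Segmentation

Body outline: 2-class Otsu on the full volume histogram (256 bins)
separates air from material; connected components below
`min_component_volume` (default 10⁴ mm³) are dropped. When the gel-pad is
fused to the body, the lowest of the 3-class multi-Otsu thresholds inside
the foreground splits it off — the pad is always the lowest-intensity
foreground class, whereas a plain 2-class split can be captured by
brighter classes (bone) depending on class proportions. The split is only
accepted under three guards (pad candidate is 0.5–45% of the foreground,
clearly posterior to the body, and separated by > 4× the within-class
noise), so a pad-free image is never split. Then: morphological closing
(`closing_radius` 3 mm ≈ 2 voxels), slice-wise hole filling in axial
planes (bowel gas etc.), largest component.

Extracorporeal air: below-Otsu voxels outside the body within
`air_band_height` (10 mm) of the coupling interface, restricted to
contact-plane columns. The contact plane is the *modal* inferior-surface
height over columns — the flattened skin resting on the pad shares one
lattice row, and a mode is robust to single-column artefacts of
morphological closing, unlike the minimum. Both trapped and
exterior-connected air are included; an empty mask is valid. This is a
simplified rule, not a reproduction of published fat/water air-detection
pipelines. `coupling_extent` returns the largest contiguous LR run of
contact columns free of interface air; an LR position counts as coupled if
any of its IS columns is coupled.

## Home-position estimation

The skin point is the most-posterior body voxel centre on the vertical
line through the isocentre (nearest-voxel; sub-voxel refinement was judged
unnecessary, and an optional 15×15 mm neighbourhood average exists but is
off by default). The chain

    home_AP = skin_AP − t + b − membrane_to_home

follows the couch construction: the bowed membrane lies b below the
undeformed membrane plane, the compressed pad of thickness t sits on the
bowed membrane, the skin on the pad, and home is the calibrated
67.5 mm (= 140 − 72.5) below the undeformed plane. The chain is linear, so
assuming wrong deformations (Δt, Δb) displaces home by exactly Δb − Δt;
this error law is unit-tested and driven end-to-end in the acceptance
suite. Defaults t = 9.8 mm and b = 10.0 mm are the bundled volunteer
cohort means (`hifuplan.cohort`).

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks. Mean
contour-to-contour distance is symmetric (mean of the two directed means)
and slice-wise 2D by default, matching per-axial-slice validation
workflows; boundary voxels have ≥1 face-adjacent background neighbour
(4-connectivity in-plane, 6-connectivity for the 3D mode). One-directional
and 3D variants exist because the original validation protocol does not
pin these choices down. `descriptive_stats` reports the sample SD (n−1
divisor).

## Phantom generator

The generator emulates a subject lying (optionally tilted toward oblique
supine decubitus, the treatment orientation) on a compressed gel-pad over
the bowed couch membrane:

* elliptic-cylinder trunk, clipped flat at the skin plane
  `−(72.5 + b) + t` so the couch arithmetic closes exactly;
* a parametric pelvic-ring bone shell with one angular gap as the
  acoustic window (default half-angle 55°, centred posterior) — coverage
  logic depends only on obstruction topology, so no anatomical mesh is
  used; extra axis-aligned bone boxes support constructed test cases;
* ellipsoidal tumor (default half-axes 17 mm, ≈ 2·10⁴ mm³, the
  patient-target scale) and optional OAR ellipsoids;
* lens-shaped air defects carved out of the pad top (coupling failures);
* Gaussian intensity noise per tissue class with a fixed seed
  (bit-identical regeneration; Rician MR noise is not modelled); class
  means 50/700/1000/1300 a.u. for air/pad/body/bone with SD 20;
* ≥10 analytic bone landmarks on the ring surface that rotate exactly
  with the phantom tilt, written as CSV.

`make_referral_treatment_pair` produces a supine referral twin (tilt 0, no
pad, no defects, independent noise) plus the exact affine linking the two.
Because the treatment body is flattened in world space after tilting while
the referral body is flattened supine, the registered-referral skin point
under the isocentre sits `y_skin(1/cosα − 1)` too low — the same
skin-point failure mode seen with real subjects — which the AP pose sweep
largely absorbs.

What passing tests on phantoms do *not* show: performance on real MR
contrast (multi-modal intensity distributions, bias fields, partial
volume), realistic pelvic bone shape, organ motion between referral and
treatment, or soft-tissue deformation beyond the flat-compression model.
The phantom's tissue classes are separated by ~15 noise SDs, so
segmentation recovers ground truth essentially exactly (Dice ≈ 1.0);
against real data the same pipeline would land near the ~0.99 (body) /
~0.89 (air) level that slice-based validation studies report, and the
test thresholds are set at those levels.

## Numerical choices and problem sizes

* Nearest-voxel lookup of 0.2 mm ray samples rather than exact ray/box
  traversal, matching the sampled-ray construction; the 0.01 mm oracle
  bounds the difference in tests.
* Cell membership and pose grids are tie-inclusive (≤, and a 1e-9 slack
  in grid arithmetic) so printed step counts are reproduced exactly.
* Default full-size phantom is 192×160×96 voxels at 1.5 mm; the test and
  acceptance pipelines run 96×96×64 at 2 mm with the 4 mm whole-pelvis
  translation step, a desk-scale setting that keeps a full
  referral-vs-treatment comparison under a minute while exercising every
  stage; a 48³ mini profile backs the brute-force oracle comparisons.
* All randomness flows from explicit seeds; segmentation and coverage are
  fully deterministic.

## Known limitations

* No acoustics: refraction, attenuation, standing waves and heating are
  not modelled, so coverage is an upper bound on treatability.
* Axis-aligned volumes only; oblique acquisitions must be resampled first.
* The any-ray-blocked rule is conservative; partial-aperture sonication
  strategies would need the tolerated-blocked-fraction option.
* TVC_vol compares voxel sets on the treatment grid; no sub-voxel
  interpolation of the covered sets is attempted.
* The deformation chain assumes the isocentre-to-skin distance is
  preserved between orientations; systematic violations appear directly
  as home-position AP error (exactly Δb − Δt per the error law).
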