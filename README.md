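# hifuplan

Geometric treatment-planning toolkit for MR-guided high-intensity focused
ultrasound (MRgHIFU) of pelvic targets. Given co-registered 3D label maps
(body outline, bone, extracorporeal air, organs at risk, target), it
predicts how much of the target an idealised treatment cell can reach
through the available acoustic window — the quantitative screening question
behind "is this patient treatable on this device?" — and lets that
prediction be made from supine *referral* imaging before the patient is
ever positioned on the HIFU couch.

Intended users are medical-physics and image-analysis researchers working
on HIFU patient screening and planning. No clinical data is required: a
deterministic digital pelvis phantom generator produces every input the
pipeline consumes.

## The model

The simulated device is a Sonalleve-V2-class system: a 256-element
phased-array transducer (130 mm aperture, 140 mm focal length) under the
couch, whose home position lies 140 mm below the magnetic isocentre and
whose undeformed oil-bath membrane lies 72.5 mm below it. From home it
translates ±72.5 mm left-right (LR) and inferior-superior (IS), +34/−33 mm
anterior-posterior (AP), and tilts ±10° in 2.5° steps about the IS axis.

The acoustic beam is 256 straight rays, one per element centre, converging
on the focus and discretised at 0.2 mm. A candidate pose is usable only if
*no* ray sample falls in an obstruction voxel (bone ∪ extracorporeal air ∪
organs at risk). For every usable pose an 8 mm × 21.84 mm ellipsoidal
treatment cell is drawn around the focus and all target-grid points (one
per target voxel) inside it are marked covered. Sweeping the pose grid
exhaustively — LR/IS restricted to the target extents, full AP range, all
tilts — yields the covered volume CV and

    TVC_pat = 100% · CV / TV                      (covered fraction of the target)
    TVC_vol = 100% · |CV_regref ∩ CV_treat| / |CV_treat|   (referral-vs-treatment overlap)

To position the virtual transducer on referral imaging, the referral
dataset is first mapped into treatment orientation with a 12-parameter
affine fitted by least squares to ≥10 paired bony landmarks, and the home
position is then estimated from the skin point under the isocentre via the
couch deformation chain

    home_AP = skin_AP − t + b − 67.5 mm

with compressed gel-pad thickness *t* (default 9.8 mm) and membrane bowing
*b* (default 10.0 mm), the bundled volunteer-cohort means.

## Worked example

```python
import hifuplan as hp

# a tilted subject on the couch, open acoustic window, 17 mm tumor at the isocentre
phantom = hp.generate_phantom(hp.PhantomSpec(tilt_deg=22.0, seed=3))
result = hp.compute_coverage(phantom.anatomy, hp.build_transducer())
print(f"poses tested {result.n_poses_tested}, clear {result.n_poses_clear}")
print(f"CV = {result.covered_volume_mm3:.0f} mm^3 of TV = {result.total_volume_mm3:.0f} mm^3")
print(f"TVC_pat = {result.tvc_pat:.2f} %")
```

prints

```
poses tested 9792, clear 5032
CV = 20301 mm^3 of TV = 20547 mm^3
TVC_pat = 98.80 %
```

i.e. 9792 transducer poses were enumerated over the tumor extents, 5032 of
them reach the target unobstructed through the bone-ring window, and the
union of their treatment cells covers 98.8% of the 20.5 cm³ tumor.

The same computation is available from the shell, including the full
referral-vs-treatment comparison:

```bash
hifuplan phantom generate --out data/ --pair        # synthetic referral + treatment pair
hifuplan run --config pipeline.yaml --out-dir out/  # register, segment, position, cover, compare
hifuplan coverage compute --anatomy-dir data/treatment --out report.json
```

where `pipeline.yaml` names `referral_dir` and `treatment_dir`. The `run`
report contains the registration error, the estimated home position, both
TVC_pat values, their difference, and TVC_vol.

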