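"""End-to-end planning pipeline: register, segment, position, cover, compare.

Given a referral (supine) and a treatment dataset directory, the pipeline

1. fits a landmark affine taking referral into treatment space and
   resamples the referral image and masks onto the treatment grid,
2. segments the body outline automatically on both datasets and
   extracorporeal air on the treatment dataset,
3. estimates the transducer home position for the registered-referral
   dataset from the skin point under the isocentre (the treatment dataset
   uses the known couch isocentre directly),
4. sweeps the transducer over both datasets to compute covered target
   volume and TVC_pat, assuming perfect coupling for the referral
   prediction (no air obstructions), and
5. compares the two covered-voxel sets (TVC_vol) and the TVC_pat values.

Every run's report embeds the full effective configuration, so equal
configs reproduce identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .coverage import compute_coverage, tvc_vol
from .errors import InputError
from .positioning import DeformationParams, estimate_home_position, find_skin_point, isocentre_from_home
from .registration import LandmarkSet, apply_transform, fit_landmark_affine, registration_error
from .segmentation import SegmentationParams, segment_body_outline, segment_extracorporeal_air
from .transducer import PoseLimits, TreatmentCell, build_transducer
from .volume import LabelMask, LabelledAnatomy, read_anatomy, write_mask

log = logging.getLogger("hifuplan")

DEFAULT_CONFIG = {
    "gelpad_thickness_mm": 9.8,
    "membrane_bowing_mm": 10.0,
    "step_mm": 4.0,
    "sample_spacing_mm": 0.2,
    "margin_mm": 0.0,
    "tilt_max_deg": 10.0,
    "tilt_step_deg": 2.5,
    "cell_diameter_mm": 8.0,
    "cell_length_mm": 21.84,
    "n_elements": 256,
    "aperture_mm": 130.0,
    "focal_length_mm": 140.0,
    "use_segmented_air": True,
}


class StageFailure(Exception):
    """Wraps an exception with the pipeline stage it occurred in."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage '{stage}' failed: {error}")
        self.stage = stage
        self.error = error


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full referral-vs-treatment comparison; return the report."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("referral_dir", "treatment_dir"):
        if key not in cfg:
            raise InputError(f"pipeline config must name '{key}'")
        if not Path(cfg[key]).is_dir():
            raise InputError(f"{key} does not exist: {cfg[key]}")
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        log.info("stage: %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - labelled and re-raised
            raise StageFailure(name, exc) from exc

    # --- load ------------------------------------------------------------
    treat = stage("load-treatment", read_anatomy, cfg["treatment_dir"])
    ref = stage("load-referral", read_anatomy, cfg["referral_dir"])
    lm_ref = stage("load-landmarks", LandmarkSet.read_csv,
                   Path(cfg["referral_dir"]) / "landmarks.csv")
    lm_treat = stage("load-landmarks", LandmarkSet.read_csv,
                     Path(cfg["treatment_dir"]) / "landmarks.csv")

    # --- registration ----------------------------------------------------
    def _register():
        transform, residuals = fit_landmark_affine(lm_ref, lm_treat)
        err = registration_error(transform.apply_landmarks(lm_ref), lm_treat)
        return transform, residuals, err

    transform, residuals, reg_error = stage("registration", _register)

    def _resample():
        image = apply_transform(ref.image, transform, treat.image)
        masks = {
            name: apply_transform(mask, transform, treat.image)
            for name, mask in ref.masks().items()
        }
        return LabelledAnatomy(
            image=image,
            body=masks["body"],
            bone=masks["bone"],
            target=masks["target"],
            oar=masks["oar"],
            couch=treat.couch,
        )

    regref = stage("resampling", _resample)

    # --- segmentation ----------------------------------------------------
    seg_params = SegmentationParams()
    body_treat = stage("segmentation", segment_body_outline, treat.image, seg_params)
    body_regref = stage("segmentation", segment_body_outline, regref.image, seg_params)
    if cfg["use_segmented_air"]:
        air_treat = stage(
            "segmentation", segment_extracorporeal_air, treat.image, body_treat,
            None, seg_params,
        )
        air_treat = LabelMask.like(air_treat.data & ~treat.body.data, treat.image)
        treat = LabelledAnatomy(
            image=treat.image, body=treat.body, bone=treat.bone, target=treat.target,
            extracorporeal_air=air_treat, oar=treat.oar, couch=treat.couch,
        )

    # --- positioning -----------------------------------------------------
    couch_treat = treat.couch
    iso = couch_treat.isocentre

    def _position():
        skin = find_skin_point(body_regref, (iso[0], iso[2]))
        params = DeformationParams(
            gelpad_thickness=cfg["gelpad_thickness_mm"],
            membrane_bowing=cfg["membrane_bowing_mm"],
        )
        home = estimate_home_position(skin, params, couch_treat)
        est_iso = isocentre_from_home(home, couch_treat)
        return skin, home, est_iso

    skin, home, est_iso = stage("positioning", _position)
    couch_regref = couch_treat.with_isocentre(est_iso)

    # --- coverage --------------------------------------------------------
    transducer = build_transducer(
        n_elements=int(cfg["n_elements"]),
        aperture_diameter=cfg["aperture_mm"],
        focal_length=cfg["focal_length_mm"],
    )
    limits = PoseLimits(
        tilt_max=cfg["tilt_max_deg"],
        tilt_step=cfg["tilt_step_deg"],
        translation_step=cfg["step_mm"],
    )
    cell = TreatmentCell(diameter=cfg["cell_diameter_mm"], length=cfg["cell_length_mm"])

    cov_treat = stage(
        "coverage-treatment", compute_coverage, treat, transducer, couch_treat,
        limits, None, cell, cfg["step_mm"], cfg["sample_spacing_mm"], cfg["margin_mm"],
    )
    cov_regref = stage(
        "coverage-referral", compute_coverage, regref, transducer, couch_regref,
        limits, None, cell, cfg["step_mm"], cfg["sample_spacing_mm"], cfg["margin_mm"],
    )

    # --- comparison ------------------------------------------------------
    if cov_treat.covered_mask.n_voxels:
        tvcvol = stage("comparison", tvc_vol, cov_regref.covered_mask, cov_treat.covered_mask)
    else:
        # nothing reachable during treatment: the overlap ratio is undefined
        tvcvol = None

    report = {
        "hifuplan_version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()},
        "registration": {
            "error_mm": reg_error,
            "max_residual_mm": float(residuals.max()),
            "transform": transform.to_json(),
            "n_landmarks": len(lm_ref),
        },
        "positioning": {
            "skin_point_mm": [float(v) for v in skin],
            "home_mm": [float(v) for v in home],
            "estimated_isocentre_mm": [float(v) for v in est_iso],
            "treatment_isocentre_mm": [float(v) for v in iso],
        },
        "treatment": cov_treat.to_report(),
        "registered_referral": cov_regref.to_report(),
        "comparison": {
            "tvc_vol": tvcvol,
            "tvc_pat_treatment": cov_treat.tvc_pat,
            "tvc_pat_registered_referral": cov_regref.tvc_pat,
            "tvc_pat_difference": cov_regref.tvc_pat - cov_treat.tvc_pat,
        },
    }

    if out_dir:
        write_mask(cov_treat.covered_mask, out_dir / "covered_treatment.nii.gz")
        write_mask(cov_regref.covered_mask, out_dir / "covered_registered_referral.nii.gz")
        transform.to_json(out_dir / "transform.json")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
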