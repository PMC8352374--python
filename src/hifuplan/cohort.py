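"""Reference cohort measurements for the emulated Sonalleve V2 pelvic setup.

These per-subject measurements (five healthy volunteers scanned in two
treatment positions each, five patients) are the provenance of the
package's deformation defaults: the volunteer-mean compressed gel-pad
thickness (9.8 mm) and membrane bowing at the isocentre line (10.0 mm)
used by :class:`hifuplan.positioning.DeformationParams`. They also feed
the descriptive-statistics checks in the test suite.

Gel-pad thickness / membrane bowing could not be measured in every
volunteer position; only the measurable entries are listed. Patient P1
lay in a custom-cut 40 mm pad (all other pads are nominally 15 mm).
"""

VOLUNTEER_AGE_YEARS = (28, 44, 29, 27, 36)
VOLUNTEER_BMI_KG_M2 = (20.2, 26.4, 23.5, 23.8, 20.9)
VOLUNTEER_HEIGHT_CM = (165, 165, 170, 160, 168)
VOLUNTEER_WEIGHT_KG = (55, 72, 68, 61, 59)
#: pelvic tilt from supine, degrees: steep position then shallow position
VOLUNTEER_TILT_STEEP_DEG = (23, 19, 17, 24, 29)
VOLUNTEER_TILT_SHALLOW_DEG = (17, 12, 8, 13, 16)
#: the seven measurable compressed gel-pad thicknesses, mm (steep then shallow)
VOLUNTEER_GELPAD_THICKNESS_MM = (10.2, 9.8, 9.7, 9.8, 9.8, 9.3, 10.0)
#: the seven measurable membrane bowing distances, mm (steep then shallow)
VOLUNTEER_MEMBRANE_BOWING_MM = (10.4, 8.6, 10.9, 11.7, 9.4, 10.9, 7.8)

PATIENT_AGE_YEARS = (64, 53, 72, 74, 59)
PATIENT_WEIGHT_KG = (42, 76, 57, 61, 61)
PATIENT_TREATMENT_ANGLE_DEG = (6, 33, 16, 9, 24)
PATIENT_GELPAD_THICKNESS_MM = (5.3, 10.9, 8.6, 12.3, 8.0)
PATIENT_GELPAD_NOMINAL_MM = (40, 15, 15, 15, 15)
PATIENT_MEMBRANE_BOWING_MM = (4.1, 10.0, 9.0, 5.0, 10.0)

#: gel-pad thicknesses of the patients on nominal 15 mm pads (excludes the
#: custom 40 mm pad of P1, whose thickness was measured independently)
PATIENT_GELPAD_THICKNESS_15MM_PADS = tuple(
    t for t, nom in zip(PATIENT_GELPAD_THICKNESS_MM, PATIENT_GELPAD_NOMINAL_MM)
    if nom == 15
)
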