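"""Canonical anatomical vocabulary.

Structure identifiers name the echogenic interfaces the detector locks
onto, ordered superficial to deep.  Variable names follow the clinical
reporting convention for abdominal fat layers and the quadriceps muscles
(rectus femoris = "Anterior Rectus", vastus intermedius).
"""

ABDOMEN = "abdomen"
LEG = "leg"
LONGITUDINAL = "longitudinal"
TRANSVERSE = "transverse"

REGIONS = (ABDOMEN, LEG)
PLANES = (LONGITUDINAL, TRANSVERSE)

# Interfaces, superficial -> deep.  Abdomen: skin/fat boundary, the
# superficial fascia splitting superficial from deep subcutaneous fat,
# the anterior abdominal-wall muscle fascia ending the subcutaneous
# compartment, and the peritoneal line bounding the visceral fat.
ABDOMEN_STRUCTURES = ("skin_fat", "fascia", "muscle_wall", "peritoneum")

# Leg: skin/fat boundary, superficial aponeurosis of the rectus femoris,
# the intermuscular aponeurosis between rectus femoris and vastus
# intermedius, and the deep (femoral) boundary of the vastus.
LEG_STRUCTURES = (
    "skin_fat",
    "rectus_superficial",
    "rectus_intermuscular",
    "vastus_deep",
)

ABDOMEN_VARIABLES = (
    "Total Subcutaneous Fat",
    "Superficial Subcutaneous Fat",
    "Peritoneal Fat",
)

LEG_VARIABLES = (
    "Y-axis Anterior Rectus",
    "X-axis Anterior Rectus",
    "Anterior Rectus Area",
    "Y-axis Vastus Intermedius",
    "X-axis Vastus Intermedius",
    "Vastus Intermedius Area",
)

ALL_VARIABLES = ABDOMEN_VARIABLES + LEG_VARIABLES

TEXTURE_VARIABLES = (
    "asm",
    "contrast",
    "correlation",
    "dissimilarity",
    "entropy",
    "histogram_mean",
    "homogeneity",
)


def structures_for(region: str) -> tuple[str, ...]:
    """Interface identifiers for a body region, superficial to deep."""
    if region == ABDOMEN:
        return ABDOMEN_STRUCTURES
    if region == LEG:
        return LEG_STRUCTURES
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def variables_for(region: str) -> tuple[str, ...]:
    """Length/area variable names applicable to a body region."""
    return ABDOMEN_VARIABLES if region == ABDOMEN else LEG_VARIABLES
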