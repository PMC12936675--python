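"""Anatomical labels and aggregation rules for the femorotibial joint.

The weight-bearing femorotibial cartilage is analyzed as four plates:
medial/lateral tibia (MT, LT) and central (weight-bearing) medial/lateral
femur (cMF, cLF).  Each tibial plate carries five subregions (central,
exterior, interior, anterior, posterior) and each central femoral plate
three mediolateral bands (central, exterior, interior), for 16 subregions
in total.  Compartments aggregate articulating plates: MFTC = MT + cMF,
LFTC = LT + cLF, and FTJ = (MFTC + LFTC) / 2 for thickness; for T2 the
compartment/joint value is the unweighted mean of its member regions.
"""

from __future__ import annotations

PLATES = ("MT", "cMF", "LT", "cLF")
TIBIAL_PLATES = ("MT", "LT")
FEMORAL_PLATES = ("cMF", "cLF")
MEDIAL_PLATES = ("MT", "cMF")
LATERAL_PLATES = ("LT", "cLF")

# Fixed subregion listing order; also the deterministic tie-break order for
# ordered-value ranking.
SUBREGIONS = (
    "cMT", "eMT", "iMT", "aMT", "pMT",
    "ccMF", "ecMF", "icMF",
    "cLT", "eLT", "iLT", "aLT", "pLT",
    "ccLF", "ecLF", "icLF",
)

SUBREGIONS_OF_PLATE = {
    "MT": ("cMT", "eMT", "iMT", "aMT", "pMT"),
    "cMF": ("ccMF", "ecMF", "icMF"),
    "LT": ("cLT", "eLT", "iLT", "aLT", "pLT"),
    "cLF": ("ccLF", "ecLF", "icLF"),
}

PLATE_OF_SUBREGION = {
    sub: plate for plate, subs in SUBREGIONS_OF_PLATE.items() for sub in subs
}

COMPARTMENTS = ("MFTC", "LFTC", "FTJ")
PLATES_OF_COMPARTMENT = {"MFTC": MEDIAL_PLATES, "LFTC": LATERAL_PLATES,
                         "FTJ": PLATES}

THICKNESS_LOCATIONS = SUBREGIONS + PLATES + COMPARTMENTS
T2_LOCATIONS = PLATES + COMPARTMENTS

LAYERS = ("total", "deep", "superficial")

OV_LABELS = tuple(f"OV{i}" for i in range(1, 17))
# Ranks reported in the occurrence table and modeled alongside subregions.
DEFAULT_OV_RANKS = ("OV1", "OV2", "OV15", "OV16")

KNEE_ROLES = ("ACL_in", "ACL_unin", "HEA_l", "HEA_r")
ANALYSIS_GROUPS = ("ACL_in", "ACL_unin", "HEA")

# Mirror map under a left<->right flip of the mediolateral axis: interior and
# exterior swap roles is FALSE -- interior always faces the intercondylar
# notch, so mirrored geometry keeps each label.  The map is the identity and
# exists to make that explicit in tests.
MIRROR_MAP = {s: s for s in SUBREGIONS}


def interior_sign(plate: str, laterality: str) -> int:
    """Direction (+1/-1 along the mediolateral axis 0) that faces the
    intercondylar notch for this plate.

    Convention: image axis 0 runs medial->lateral for right knees and
    lateral->medial for left knees (a scanner-space mirror).  The notch lies
    lateral of the medial plates and medial of the lateral plates.
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    if plate not in PLATES:
        raise ValueError(f"unknown plate {plate!r}")
    sign = 1 if plate in MEDIAL_PLATES else -1
    return sign if laterality == "right" else -sign
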