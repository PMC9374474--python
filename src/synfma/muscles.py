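"""Default 41-muscle montage and anatomical-area map.

The montage covers the upper body and trunk: shoulder/upper-arm muscles,
forearm muscles, extrinsic and intrinsic finger/thumb muscles, chest,
abdominal wall, posterior trunk, and neck.  Muscle identity throughout the
package is by label string, never by column position, so this table doubles
as the canonical ordering for synthetic cohorts and as the default
muscle-to-area map used when labelling standard synergies.
"""

from __future__ import annotations

# area name -> ordered muscle labels
DEFAULT_AREA_MAP: dict[str, list[str]] = {
    "upper arm": [
        "DeltAnt", "DeltMed", "DeltPost", "BicepsLong", "BicepsShort",
        "TricepsLat", "TricepsLong", "Brachialis",
    ],
    "forearm": [
        "Brachiorad", "ExtCarpRad", "ExtCarpUln", "FlexCarpRad",
        "FlexCarpUln", "PronTeres", "Supinator", "ExtDigitorum",
    ],
    "finger/thumb": [
        "FlexDigSup", "FlexDigProf", "FlexPollLong", "AbdPollBrev",
        "FirstDorsInt",
    ],
    "chest": [
        "PectMajClav", "PectMajStern", "PectMinor", "SerrAntSup",
        "SerrAntInf", "IntercostAnt",
    ],
    "abdomen": [
        "RectAbdUp", "RectAbdLow", "ObliqExt", "ObliqInt", "TransAbd",
        "Pyramidalis",
    ],
    "posterior trunk": [
        "TrapUp", "TrapMid", "TrapLow", "LatDorsi", "ErSpThor", "ErSpLumb",
    ],
    "other": [
        "SternoMast", "Splenius",
    ],
}

#: Canonical 41-label ordering (areas in anatomical proximal-to-distal order).
DEFAULT_MUSCLE_LABELS: list[str] = [
    m for area in DEFAULT_AREA_MAP.values() for m in area
]

#: muscle label -> area name, for the default montage.
DEFAULT_MUSCLE_TO_AREA: dict[str, str] = {
    m: area for area, muscles in DEFAULT_AREA_MAP.items() for m in muscles
}

N_MUSCLES = len(DEFAULT_MUSCLE_LABELS)
assert N_MUSCLES == 41
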