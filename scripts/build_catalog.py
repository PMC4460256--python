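"""Regenerate the bundled acupoint catalog JSON (with payload checksum)."""

import hashlib
import json
from pathlib import Path

F = 1.3 / 1.5
THIRD = 1.0 / 3.0

# name: (meridian, category, laterality, surface_model, description)
POINTS = {
    # anatomical (34)
    "GV15": ("GV", "anatomical", "midline", "bone",
             "depression above the spinous process of C2 on the posterior midline"),
    "GV16": ("GV", "anatomical", "midline", "bone",
             "directly below the external occipital protuberance"),
    "GV17": ("GV", "anatomical", "midline", "bone",
             "external occipital protuberance"),
    "GV25": ("GV", "anatomical", "midline", "skin", "tip of the nose"),
    "GV26": ("GV", "anatomical", "midline", "skin",
             "midpoint of the philtrum midline"),
    "GV27": ("GV", "anatomical", "midline", "skin",
             "midpoint of the tubercle of the upper lip"),
    "GB1": ("GB", "anatomical", "bilateral", "skin_and_bone",
            "outer canthus of the eye"),
    "GB2": ("GB", "anatomical", "bilateral", "bone",
            "depression between the intertragic notch and the condylar process"),
    "GB3": ("GB", "anatomical", "bilateral", "bone",
            "depression above the midpoint of the zygomatic arch"),
    "GB7": ("GB", "anatomical", "bilateral", "skin",
            "posterior temple hairline at the level of the auricular apex"),
    "GB8": ("GB", "anatomical", "bilateral", "skin",
            "directly above the auricular apex"),
    "GB9": ("GB", "anatomical", "bilateral", "skin",
            "directly above the posterior border of the auricular root"),
    "GB12": ("GB", "anatomical", "bilateral", "bone",
             "depression behind and below the mastoid process"),
    "GB20": ("GB", "anatomical", "bilateral", "bone",
             "below the occipital bone, between the sternocleidomastoid and "
             "trapezius origins"),
    "ST1": ("ST", "anatomical", "bilateral", "skin_and_bone",
            "between the eyeball and the infraorbital margin, below the pupil"),
    "ST2": ("ST", "anatomical", "bilateral", "bone", "in the infraorbital foramen"),
    "ST3": ("ST", "anatomical", "bilateral", "skin",
            "below the pupil, level with the lower border of the ala of the nose"),
    "ST4": ("ST", "anatomical", "bilateral", "skin", "angle of the mouth"),
    "ST5": ("ST", "anatomical", "bilateral", "bone",
            "in front of the angle of the mandible, anterior to the masseter"),
    "ST6": ("ST", "anatomical", "bilateral", "bone", "angle of the mandible"),
    "ST7": ("ST", "anatomical", "bilateral", "bone",
            "between the lower border of the zygomatic arch and the mandibular notch"),
    "TE17": ("TE", "anatomical", "bilateral", "skin",
             "behind the ear lobe, in front of the lower end of the mastoid process"),
    "TE20": ("TE", "anatomical", "bilateral", "skin", "auricular apex"),
    "TE21": ("TE", "anatomical", "bilateral", "skin_and_bone",
             "depression between the supratragic notch and the condylar process"),
    "TE22": ("TE", "anatomical", "bilateral", "skin",
             "in front of the auricular root, behind the superficial temporal artery"),
    "TE23": ("TE", "anatomical", "bilateral", "skin",
             "depression at the lateral end of the eyebrow"),
    "BL1": ("BL", "anatomical", "bilateral", "skin_and_bone",
            "between the inner canthus of the eye and the medial orbital wall"),
    "BL2": ("BL", "anatomical", "bilateral", "skin",
            "depression at the medial end of the eyebrow"),
    "CV23": ("CV", "anatomical", "midline", "bone",
             "front of the neck, above the hyoid bone on the anterior midline"),
    "CV24": ("CV", "anatomical", "midline", "skin",
             "depression at the centre of the mentolabial sulcus"),
    "LI19": ("LI", "anatomical", "bilateral", "skin",
             "level with the midpoint of the philtrum"),
    "LI20": ("LI", "anatomical", "bilateral", "skin",
             "in the nasolabial sulcus, level with the ala of the nose"),
    "SI17": ("SI", "anatomical", "bilateral", "bone",
             "behind the angle of the mandible, in front of the sternocleidomastoid"),
    "SI18": ("SI", "anatomical", "bilateral", "skin_and_bone",
             "below the zygomatic bone, directly below the outer canthus"),
    # auxiliary (3)
    "Pupil": ("AUXILIARY", "auxiliary", "bilateral", "skin", "centre of the pupil"),
    "Yintang": ("AUXILIARY", "auxiliary", "midline", "skin",
                "midpoint between the eyebrows"),
    "TOP": ("AUXILIARY", "auxiliary", "midline", "skin",
            "highest point of the head"),
    # proportional (24)
    **{f"GV{n}": ("GV", "proportional", "midline", "skin", "")
       for n in range(18, 25)},
    **{f"GB{n}": ("GB", "proportional", "bilateral", "skin", "")
       for n in range(13, 20)},
    "ST8": ("ST", "proportional", "bilateral", "skin", ""),
    **{f"BL{n}": ("BL", "proportional", "bilateral", "skin", "")
       for n in range(3, 11)},
    "SI19": ("SI", "proportional", "bilateral", "skin", ""),
    # morphological (7)
    "GB4": ("GB", "morphological", "bilateral", "skin", ""),
    "GB5": ("GB", "morphological", "bilateral", "skin", ""),
    "GB6": ("GB", "morphological", "bilateral", "skin", ""),
    "GB10": ("GB", "morphological", "bilateral", "skin", ""),
    "GB11": ("GB", "morphological", "bilateral", "skin", ""),
    "TE18": ("TE", "morphological", "bilateral", "skin", ""),
    "TE19": ("TE", "morphological", "bilateral", "skin", ""),
}


def ratio(target, kind, numerator):
    return {
        "target": target,
        "kind": kind,
        "numerator": numerator,
        "denominator": 12.5,
    }


def coord(target, constraints, hemisphere):
    return {
        "target": target,
        "kind": "coordinate",
        "constraints": [
            {"axis": axis, "terms": [[c, p, a] for c, p, a in terms]}
            for axis, terms in constraints
        ],
        "hemisphere": hemisphere,
    }


PROPORTIONAL_RULES = [
    ratio("GV18", "sagittal_ratio", 1.5),
    ratio("GV19", "sagittal_ratio", 3.0),
    ratio("GV20", "sagittal_ratio", 4.5),
    ratio("GV21", "sagittal_ratio", 6.0),
    ratio("GV22", "sagittal_ratio", 7.5),
    ratio("GV23", "sagittal_ratio", 8.5),
    ratio("GV24", "sagittal_ratio", 9.0),
    ratio("AUX", "sagittal_ratio", 11.0),
    ratio("ST8", "transverse_ratio", 2.25),
    ratio("GB13", "transverse_ratio", 1.5),
    ratio("BL3", "transverse_ratio", 0.25),
    ratio("BL4", "transverse_ratio", 0.5),
    coord("GB14", [("x", [(1.0, "Pupil", "x")]),
                   ("z", [(1.0, "AUX", "z")])], "anterior"),
    coord("GB15", [("x", [(1.0, "Pupil", "x")]),
                   ("z", [(1.0, "GV24", "z")])], "anterior"),
    coord("GB16", [("x", [(1.0, "Pupil", "x")]),
                   ("z", [(1.0, "GV23", "z")])], "anterior"),
    coord("GB17", [("x", [(1.0, "Pupil", "x")]),
                   ("z", [(0.5, "GV22", "z"), (0.5, "GV23", "z")])], "anterior"),
    coord("BL5", [("x", [(1.0, "BL4", "x")]),
                  ("z", [(1.0, "GV23", "z")])], "anterior"),
    coord("BL6", [("x", [(1.0, "BL4", "x")]),
                  ("y", [(THIRD, "GV21", "y"), (2 * THIRD, "GV22", "y")])],
          "superior"),
    coord("BL7", [("x", [(1.0, "BL4", "x")]),
                  ("y", [(THIRD, "GV20", "y"), (2 * THIRD, "GV21", "y")])],
          "superior"),
    coord("BL8", [("x", [(1.0, "BL4", "x")]),
                  ("y", [(THIRD, "GV19", "y"), (2 * THIRD, "GV20", "y")])],
          "superior"),
    coord("BL9", [("x", [(1.0, "GV17", "x"), (-F, "BL4", "x"), (F, "GV24", "x")]),
                  ("z", [(1.0, "GV17", "z")])], "posterior"),
    coord("GB18", [("x", [(1.0, "GB17", "x")]),
                   ("z", [(1.0, "BL7", "z")])], "posterior"),
    coord("GB19", [("x", [(1.0, "GB20", "x")]),
                   ("z", [(1.0, "GV17", "z")])], "posterior"),
    coord("BL10", [("x", [(0.5, "GV16", "x"), (0.5, "GB20", "x")]),
                   ("z", [(1.0, "GV15", "z")])], "posterior"),
    {"target": "SI19", "kind": "midpoint", "points": ["TE21", "GB2"]},
]

# Standard-source model-frame coordinates for the morphological solver.
MORPH_RULES = [
    {
        "targets": ["GB4", "GB5", "GB6"],
        "control_a": "ST8",
        "control_b": "GB7",
        "standard": {
            "GB4": {"left": [-0.539, 0.274, -0.912], "right": [0.560, 0.274, -0.912]},
            "GB5": {"left": [-0.610, 0.272, -0.759], "right": [0.628, 0.272, -0.759]},
            "GB6": {"left": [-0.639, 0.239, -0.594], "right": [0.655, 0.239, -0.594]},
            "ST8": {"left": [-0.447, 0.278, -1.026], "right": [0.457, 0.278, -1.026]},
            "GB7": {"left": [-0.641, 0.155, -0.474], "right": [0.651, 0.155, -0.474]},
        },
    },
    {
        "targets": ["GB10", "GB11"],
        "control_a": "GB9",
        "control_b": "GB12",
        "standard": {
            "GB10": {"left": [-0.584, -0.266, -0.467], "right": [0.541, -0.266, -0.467]},
            "GB11": {"left": [-0.556, -0.266, -0.220], "right": [0.541, -0.266, -0.220]},
            "GB9": {"left": [-0.641, -0.089, -0.714], "right": [0.613, -0.089, -0.714]},
            "GB12": {"left": [-0.529, -0.138, 0.027], "right": [0.529, -0.138, 0.027]},
        },
    },
    {
        "targets": ["TE18", "TE19"],
        "control_a": "TE17",
        "control_b": "TE20",
        "standard": {
            "TE18": {"left": [-0.555, -0.159, -0.128], "right": [0.555, -0.134, -0.128]},
            "TE19": {"left": [-0.604, -0.159, -0.284], "right": [0.585, -0.159, -0.284]},
            "TE17": {"left": [-0.546, -0.004, 0.027], "right": [0.566, -0.004, 0.027]},
            "TE20": {"left": [-0.628, -0.004, -0.459], "right": [0.623, -0.004, -0.459]},
        },
    },
]


def main() -> None:
    payload = {
        "points": [
            {
                "name": name,
                "meridian": meridian,
                "category": category,
                "laterality": laterality,
                "surface_model": surface_model,
                "description": description,
            }
            for name, (meridian, category, laterality, surface_model, description)
            in POINTS.items()
        ],
        "proportional_rules": PROPORTIONAL_RULES,
        "morph_rules": MORPH_RULES,
    }
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    doc = {
        "version": 1,
        "checksum": hashlib.sha256(canonical.encode()).hexdigest(),
        "payload": payload,
    }
    out = Path(__file__).resolve().parents[1] / "src" / "acuhead" / "data" / "catalog.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(doc, indent=1) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
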