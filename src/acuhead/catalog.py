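"""Bundled acupoint registry: taxonomy, anatomical descriptions, proportional
rules and morphological rules with standard-source coordinates."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .landmarks import LandmarkSet

MERIDIANS = ("GV", "GB", "ST", "TE", "BL", "CV", "LI", "SI", "AUXILIARY")
CATEGORIES = ("anatomical", "proportional", "morphological", "auxiliary")

# AUX is a computation intermediate (an extra angle-ratio target used by one
# coordinate rule); it is not a registry record.
INTERNAL_NAMES = ("AUX",)

EXPECTED_COUNTS = {
    "anatomical": 34,
    "proportional": 24,
    "morphological": 7,
    "auxiliary": 3,
}


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class AcupointRecord:
    name: str
    meridian: str
    category: str
    laterality: str
    surface_model: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIANS:
            raise CatalogError(f"{self.name}: unknown meridian {self.meridian}")
        if self.category not in CATEGORIES:
            raise CatalogError(f"{self.name}: unknown category {self.category}")
        if self.laterality not in ("midline", "bilateral"):
            raise CatalogError(f"{self.name}: unknown laterality {self.laterality}")

    @property
    def sides(self) -> tuple[str, ...]:
        return ("left", "right") if self.laterality == "bilateral" else ("midline",)


@dataclass(frozen=True)
class Constraint:
    """One coordinate equation: target[axis] == sum(coef * point[axis_ref])."""

    axis: str
    terms: tuple[tuple[float, str, str], ...]

    def evaluate(self, resolve) -> float:
        """``resolve(name)`` must return a 3-vector."""
        axis_index = "xyz".index
        return float(
            sum(c * resolve(p)[axis_index(a)] for c, p, a in self.terms)
        )

    @property
    def referenced(self) -> tuple[str, ...]:
        return tuple(p for _c, p, _a in self.terms)


@dataclass(frozen=True)
class ProportionalRule:
    target: str
    rule_kind: str  # sagittal_ratio | transverse_ratio | coordinate | midpoint
    numerator: float = 0.0
    denominator: float = 12.5
    constraints: tuple[Constraint, ...] = ()
    hemisphere: str = ""  # anterior | posterior | superior for coordinate rules
    midpoint_of: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise CatalogError(f"{self.target}: denominator must be > 0")
        if self.rule_kind not in (
            "sagittal_ratio", "transverse_ratio", "coordinate", "midpoint"
        ):
            raise CatalogError(f"{self.target}: unknown kind {self.rule_kind}")

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator

    @property
    def referenced(self) -> tuple[str, ...]:
        names: list[str] = []
        for c in self.constraints:
            names.extend(c.referenced)
        names.extend(self.midpoint_of)
        return tuple(names)


@dataclass(frozen=True)
class MorphRule:
    """Targets on one surface curve between two control points, with the
    standard-source model-frame coordinates for both sides."""

    targets: tuple[str, ...]
    control_a: str
    control_b: str
    standard: dict  # name -> {"left": [x,y,z], "right": [x,y,z]}

    def __post_init__(self) -> None:
        for name in (*self.targets, self.control_a, self.control_b):
            if name not in self.standard:
                raise CatalogError(f"morph rule missing standard coords for {name}")

    def standard_point(self, name: str, side: str) -> np.ndarray:
        return np.asarray(self.standard[name][side], dtype=float)


@dataclass
class Catalog:
    points: dict[str, AcupointRecord]
    proportional_rules: list[ProportionalRule]
    morph_rules: list[MorphRule]
    version: int = 1

    def record(self, name: str) -> AcupointRecord:
        return self.points[name]

    def names(self, category: str | None = None) -> list[str]:
        return [
            n for n, r in self.points.items()
            if category is None or r.category == category
        ]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for rec in self.points.values():
            counts[rec.category] += 1
        return counts

    def proportional_rule(self, target: str) -> ProportionalRule:
        for rule in self.proportional_rules:
            if rule.target == target:
                return rule
        raise KeyError(f"no proportional rule for {target}")

    def morph_rule_for(self, target: str) -> MorphRule:
        for rule in self.morph_rules:
            if target in rule.targets:
                return rule
        raise KeyError(f"no morphological rule for {target}")

    def resolvable(self, name: str) -> bool:
        return name in self.points or name in INTERNAL_NAMES

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        counts = self.category_counts()
        if counts != EXPECTED_COUNTS:
            raise CatalogError(f"category counts {counts} != {EXPECTED_COUNTS}")
        if len(self.points) != 68:
            raise CatalogError("registry must hold 65 standard + 3 auxiliary records")

        rule_targets = {r.target for r in self.proportional_rules}
        for name in self.names("proportional"):
            if name not in rule_targets:
                raise CatalogError(f"proportional point {name} has no rule")
        for rule in self.proportional_rules:
            for ref in (rule.target, *rule.referenced):
                if not self.resolvable(ref):
                    raise CatalogError(
                        f"rule for {rule.target} references unknown point {ref}"
                    )

        morph_targets = [t for r in self.morph_rules for t in r.targets]
        for name in self.names("morphological"):
            if name not in morph_targets:
                raise CatalogError(f"morphological point {name} has no rule")
        for rule in self.morph_rules:
            for ref in (*rule.targets, rule.control_a, rule.control_b):
                if not self.resolvable(ref):
                    raise CatalogError(f"morph rule references unknown point {ref}")
            for name, coords in rule.standard.items():
                asym = abs(coords["left"][0] + coords["right"][0])
                if asym > 0.05:
                    raise CatalogError(
                        f"standard coords of {name} break mirror symmetry: {asym}"
                    )
                if not (coords["left"][0] < 0 < coords["right"][0]):
                    raise CatalogError(f"standard x signs wrong for {name}")


def _data_text() -> str:
    return (
        resources.files("acuhead").joinpath("data/catalog.json").read_text()
    )


@lru_cache(maxsize=1)
def load_catalog() -> Catalog:
    """Load, checksum-verify and validate the bundled registry."""
    doc = json.loads(_data_text())
    payload = doc["payload"]
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(canonical.encode()).hexdigest()
    if digest != doc["checksum"]:
        raise CatalogError("bundled catalog checksum mismatch")

    points = {
        rec["name"]: AcupointRecord(**rec) for rec in payload["points"]
    }
    prop_rules = []
    for raw in payload["proportional_rules"]:
        kind = raw["kind"]
        if kind in ("sagittal_ratio", "transverse_ratio"):
            prop_rules.append(
                ProportionalRule(
                    raw["target"], kind,
                    numerator=raw["numerator"],
                    denominator=raw["denominator"],
                )
            )
        elif kind == "coordinate":
            constraints = tuple(
                Constraint(c["axis"], tuple((t[0], t[1], t[2]) for t in c["terms"]))
                for c in raw["constraints"]
            )
            prop_rules.append(
                ProportionalRule(
                    raw["target"], kind,
                    constraints=constraints,
                    hemisphere=raw["hemisphere"],
                )
            )
        elif kind == "midpoint":
            prop_rules.append(
                ProportionalRule(
                    raw["target"], kind, midpoint_of=tuple(raw["points"])
                )
            )
        else:
            raise CatalogError(f"unknown rule kind {kind}")
    morph_rules = [
        MorphRule(
            tuple(raw["targets"]), raw["control_a"], raw["control_b"],
            raw["standard"],
        )
        for raw in payload["morph_rules"]
    ]
    catalog = Catalog(points, prop_rules, morph_rules, version=doc["version"])
    catalog.validate()
    return catalog


REQUIRED_AUXILIARY = ("Pupil", "Yintang", "TOP")


def required_annotation_keys(catalog: Catalog | None = None) -> list[tuple[str, str]]:
    """(name, side) pairs a complete manual annotation must provide: all 34
    anatomical points plus the three auxiliary landmarks, bilateral ones on
    both sides."""
    catalog = catalog or load_catalog()
    keys = []
    for name in (*catalog.names("anatomical"), *REQUIRED_AUXILIARY):
        for side in catalog.record(name).sides:
            keys.append((name, side))
    return keys


def load_annotations(path: str | Path, catalog: Catalog | None = None) -> LandmarkSet:
    """Read a manual-annotation file (JSON or CSV) and verify completeness."""
    catalog = catalog or load_catalog()
    landmarks = LandmarkSet.load(path)
    unknown = [lm.name for lm in landmarks if not catalog.resolvable(lm.name)]
    if unknown:
        raise CatalogError(f"unknown point names in annotation: {sorted(set(unknown))}")
    missing = [
        key for key in required_annotation_keys(catalog) if key not in landmarks
    ]
    if missing:
        raise CatalogError(f"annotation missing required landmarks: {missing}")
    return landmarks
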