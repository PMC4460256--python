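"""Named 3D landmark sets with laterality and provenance, plus JSON/CSV I/O."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

SIDES = ("left", "right", "midline")


@dataclass(frozen=True)
class Landmark:
    """A single named point.

    ``side`` is ``left``/``right`` for bilateral points and ``midline``
    otherwise.  ``frame`` tags the coordinate system (``stack`` = voxel
    indices, ``model`` = centered/scaled).  ``provenance`` records whether the
    point was annotated by hand (or by the phantom generator) or computed.
    """

    name: str
    side: str
    xyz: tuple[float, float, float]
    frame: str = "stack"
    provenance: str = "manual"
    category: str = ""

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r} for {self.name}")
        if len(self.xyz) != 3:
            raise ValueError(f"{self.name}: xyz must have 3 components")
        object.__setattr__(self, "xyz", tuple(float(v) for v in self.xyz))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


class LandmarkSet:
    """Mapping of ``(name, side)`` to :class:`Landmark`, insertion ordered."""

    def __init__(self, landmarks: Iterable[Landmark] = ()) -> None:
        self._items: dict[tuple[str, str], Landmark] = {}
        for lm in landmarks:
            self.add(lm)

    def add(self, lm: Landmark, *, overwrite: bool = False) -> None:
        key = (lm.name, lm.side)
        if key in self._items and not overwrite:
            raise ValueError(f"duplicate landmark {key}")
        self._items[key] = lm

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Landmark]:
        return iter(self._items.values())

    def __getitem__(self, key: tuple[str, str]) -> Landmark:
        try:
            return self._items[tuple(key)]
        except KeyError:
            raise KeyError(f"landmark {key} not present") from None

    def get(self, name: str, side: str = "midline") -> Landmark:
        return self[(name, side)]

    def point(self, name: str, side: str = "midline") -> np.ndarray:
        """Coordinate array of a landmark; falls back to midline for a name
        stored without laterality (and vice versa)."""
        for key in ((name, side), (name, "midline")):
            if key in self._items:
                return self._items[key].array
        raise KeyError(f"landmark ({name}, {side}) not present")

    def names(self) -> list[str]:
        seen: dict[str, None] = {}
        for lm in self:
            seen.setdefault(lm.name, None)
        return list(seen)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        wanted = set(names)
        return LandmarkSet(lm for lm in self if lm.name in wanted)

    def transformed(self, func, frame: str) -> "LandmarkSet":
        """Apply ``func`` (ndarray (N,3) -> (N,3)) to all points, retagging."""
        out = LandmarkSet()
        for lm in self:
            new_xyz = np.asarray(func(lm.array[None, :]))[0]
            out.add(replace(lm, xyz=tuple(new_xyz), frame=frame))
        return out

    # ---------------------------------------------------------------- I/O
    def to_records(self) -> list[dict]:
        return [
            {
                "name": lm.name,
                "side": lm.side,
                "x": lm.xyz[0],
                "y": lm.xyz[1],
                "z": lm.xyz[2],
                "frame": lm.frame,
                "provenance": lm.provenance,
                "category": lm.category,
            }
            for lm in self
        ]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1) + "\n")

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "name", "side", "x", "y", "z",
                    "frame", "provenance", "category",
                ],
            )
            writer.writeheader()
            for rec in self.to_records():
                writer.writerow(rec)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "LandmarkSet":
        out = cls()
        for rec in records:
            out.add(
                Landmark(
                    name=rec["name"],
                    side=rec.get("side", "midline"),
                    xyz=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
                    frame=rec.get("frame", "stack"),
                    provenance=rec.get("provenance", "manual"),
                    category=rec.get("category", ""),
                )
            )
        return out

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkSet":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_records(json.loads(path.read_text()))
        with open(path, newline="") as fh:
            return cls.from_records(list(csv.DictReader(fh)))
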