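"""Landmark schema and per-specimen landmark containers.

The measurement battery is defined on a fixed catalogue of 38 landmark IDs:
21 midline landmarks digitized once per skull and 17 bilaterally paired
landmarks digitized on both sides, for a total of 21 + 2*17 = 55 coordinate
points per specimen.  Midline landmarks lie on the sagittal symmetry plane;
paired landmarks occur as left/right antimeres.

Two landmarks (13, bregma; 14, lambda) are not ossified at postnatal day 7
and are digitized there from soft-tissue proxies.  The schema records these
proxy ages so that downstream measurements can carry a provenance flag.

The default midline/paired classification is induced by how each ID is used
in the measurement table (IDs measured as right-left widths are paired;
IDs used in mid-sagittal angles and vertical spans are midline).  The exact
anatomical identity of a handful of IDs is not fully determined by that
usage, so the classification and the landmark names are user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError

# Side tags used throughout the package.
MID = "mid"
LEFT = "left"
RIGHT = "right"
SIDES = (MID, LEFT, RIGHT)

MIDLINE = "midline"
PAIRED = "paired"

#: Default paired IDs.  The 14 IDs measured as right-left widths, plus the
#: zygomatic partner 9 and the condylar/angular mandibular landmarks 35, 36.
#: The symphyseal mandibular landmarks 37, 38 default to midline so that the
#: catalogue totals 21 midline + 17 paired.
DEFAULT_PAIRED_IDS = frozenset(
    {4, 6, 7, 8, 9, 10, 11, 12, 17, 21, 23, 29, 30, 32, 34, 35, 36}
)

#: Landmarks digitized from soft-tissue proxies at the given ages (days).
DEFAULT_PROXY_AGES = {13: frozenset({7}), 14: frozenset({7})}

N_IDS = 38
TOTAL_POINTS = 55


@dataclass(frozen=True)
class LandmarkEntry:
    """One catalogue entry: an ID, a name, and its laterality."""

    id: int
    name: str
    laterality: str  # MIDLINE or PAIRED
    proxy_ages: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.laterality not in (MIDLINE, PAIRED):
            raise ValidationError(
                f"landmark {self.id}: laterality must be "
                f"'{MIDLINE}' or '{PAIRED}', got {self.laterality!r}"
            )


@dataclass(frozen=True)
class LandmarkSchema:
    """The fixed landmark catalogue against which specimens are validated."""

    entries: tuple[LandmarkEntry, ...]

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("landmark IDs must be unique")

    # -- lookups ---------------------------------------------------------
    def entry(self, landmark_id: int) -> LandmarkEntry:
        for e in self.entries:
            if e.id == landmark_id:
                return e
        raise KeyError(f"unknown landmark ID {landmark_id}")

    def __contains__(self, landmark_id: int) -> bool:
        return any(e.id == landmark_id for e in self.entries)

    def is_paired(self, landmark_id: int) -> bool:
        return self.entry(landmark_id).laterality == PAIRED

    @property
    def midline_ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries if e.laterality == MIDLINE)

    @property
    def paired_ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries if e.laterality == PAIRED)

    @property
    def total_points(self) -> int:
        """Number of coordinate points a complete specimen carries."""
        return len(self.midline_ids) + 2 * len(self.paired_ids)

    def sides_for(self, landmark_id: int) -> tuple[str, ...]:
        return (LEFT, RIGHT) if self.is_paired(landmark_id) else (MID,)

    def expected_keys(self) -> tuple[tuple[int, str], ...]:
        """All (id, side) keys a complete specimen must provide."""
        keys = []
        for e in self.entries:
            for side in self.sides_for(e.id):
                keys.append((e.id, side))
        return tuple(keys)

    def proxy_ids_at(self, age_days: int) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries if age_days in e.proxy_ages)

    # -- overrides -------------------------------------------------------
    def with_overrides(
        self,
        laterality: Mapping[int, str] | None = None,
        names: Mapping[int, str] | None = None,
    ) -> "LandmarkSchema":
        """Return a copy with per-ID laterality and/or name overrides."""
        laterality = dict(laterality or {})
        names = dict(names or {})
        new = []
        for e in self.entries:
            kw = {}
            if e.id in laterality:
                kw["laterality"] = laterality[e.id]
            if e.id in names:
                kw["name"] = names[e.id]
            new.append(replace(e, **kw) if kw else e)
        return LandmarkSchema(tuple(new))


def default_schema(
    names: Mapping[int, str] | None = None,
    laterality_overrides: Mapping[int, str] | None = None,
) -> LandmarkSchema:
    """Build the built-in 38-ID catalogue (21 midline + 17 paired = 55 points).

    Names default to ``landmark_<k>``; anatomical names can be supplied via
    ``names``.  The default laterality classification can be adjusted via
    ``laterality_overrides`` (e.g. to reclassify landmark 33).
    """
    entries = []
    for k in range(1, N_IDS + 1):
        entries.append(
            LandmarkEntry(
                id=k,
                name=f"landmark_{k}",
                laterality=PAIRED if k in DEFAULT_PAIRED_IDS else MIDLINE,
                proxy_ages=DEFAULT_PROXY_AGES.get(k, frozenset()),
            )
        )
    schema = LandmarkSchema(tuple(entries))
    if names or laterality_overrides:
        schema = schema.with_overrides(laterality_overrides, names)
    return schema


@dataclass
class SpecimenLandmarks:
    """One specimen's digitized 3D landmark coordinates (mm) plus metadata.

    ``coords`` maps ``(landmark_id, side)`` to a length-3 float array.
    Midline landmarks use side ``"mid"``; paired landmarks use ``"left"``
    and/or ``"right"``.
    """

    specimen_id: str
    age_days: int
    sex: str = "unknown"
    coords: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if self.age_days <= 0:
            raise ValidationError(
                f"specimen {self.specimen_id}: age_days must be positive"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(
                f"specimen {self.specimen_id}: sex must be male/female/unknown"
            )
        self.coords = {
            k: np.asarray(v, dtype=float) for k, v in self.coords.items()
        }

    # -- access ----------------------------------------------------------
    def get(self, landmark_id: int, side: str) -> np.ndarray | None:
        return self.coords.get((landmark_id, side))

    def has(self, landmark_id: int, side: str) -> bool:
        return (landmark_id, side) in self.coords

    def set(self, landmark_id: int, side: str, xyz: Iterable[float]) -> None:
        if side not in SIDES:
            raise ValidationError(f"unknown side {side!r}")
        self.coords[(landmark_id, side)] = np.asarray(list(xyz), dtype=float)

    # -- validation ------------------------------------------------------
    def validate(self, schema: LandmarkSchema) -> None:
        """Raise ValidationError on any schema or finiteness violation."""
        for (lid, side), xyz in self.coords.items():
            if lid not in schema:
                raise ValidationError(
                    f"specimen {self.specimen_id}: unknown landmark ID {lid}"
                )
            allowed = schema.sides_for(lid)
            if side not in allowed:
                raise ValidationError(
                    f"specimen {self.specimen_id}: landmark {lid} is "
                    f"{schema.entry(lid).laterality}; side {side!r} is not "
                    f"allowed (expected one of {allowed})"
                )
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"specimen {self.specimen_id}: landmark ({lid}, {side}) "
                    "has a non-finite or malformed coordinate"
                )

    def missing_report(self, schema: LandmarkSchema) -> list[tuple[int, str]]:
        """Enumerate (id, side) keys absent relative to the schema."""
        return [k for k in schema.expected_keys() if k not in self.coords]

    def is_complete(self, schema: LandmarkSchema) -> bool:
        return not self.missing_report(schema)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    suffix: str = "") -> "SpecimenLandmarks":
        """Return a copy with every coordinate mapped to R @ x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SpecimenLandmarks(
            specimen_id=self.specimen_id + suffix,
            age_days=self.age_days,
            sex=self.sex,
            coords={k: R @ v + t for k, v in self.coords.items()},
            provenance=self.provenance,
        )
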