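"""The craniometric measurement registry and evaluation engine.

The measurement battery comprises 46 named measurements (labels A..TT)
over the 38-ID landmark catalogue, in five kinds:

* ``transverse`` -- Euclidean distance between the left and right
  instances of one paired landmark;
* ``vertical`` -- distance between two (mostly midline) landmarks in the
  vertical dimension; by default the plain 3D Euclidean distance, with a
  dorso-ventral projected mode available;
* ``ap_projected`` -- antero-posterior projected distance: the absolute
  difference of the two landmarks' coordinates along the frame's ap axis,
  i.e. the distance between parallel coronal planes through the landmarks;
* ``euclidean`` -- plain 3D distance, used on the mandible, which is not
  reliably in occlusion with the cranium and therefore never uses the
  cranial reference frame;
* ``angle`` -- interior angle at the middle (vertex) landmark of a
  mid-sagittal landmark triple, in degrees.

Whenever a measurement involves a paired landmark, the left- and
right-side values are computed separately and averaged (bilateral
averaging).  The composite key ``(10/11)`` denotes the per-side midpoint
of landmarks 10 and 11 (the midpoint of the zygomatic process of the
temporal bone, used as the articulation point of the lower jaw).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateGeometryError
from .frames import FrameConfig, ReferenceFrame, build_frame, \
    signed_axis_coordinate
from .schema import LEFT, MID, RIGHT, LandmarkSchema, SpecimenLandmarks, \
    default_schema

KINDS = ("transverse", "vertical", "ap_projected", "euclidean", "angle")

#: Quality flags attached to evaluated measurements.
FLAG_OK = "ok"
FLAG_MISSING = "missing_landmarks"
FLAG_PROXY = "proxy_used"
FLAG_SINGLE_SIDE = "single_side"
FLAG_PAIRED_MIDPOINT = "paired_midpoint"
FLAG_DEGENERATE = "degenerate_geometry"


@dataclass(frozen=True)
class Midpoint:
    """Composite landmark key: the per-side midpoint of two landmark IDs."""

    ids: tuple[int, int]

    def __str__(self):
        return f"({self.ids[0]}/{self.ids[1]})"


LandmarkKey = int | Midpoint | tuple


def parse_key(text) -> LandmarkKey:
    """Parse a landmark key from its serialized form (``"29"``,
    ``"(10/11)"``, or ``"id:side"``)."""
    if isinstance(text, (int, Midpoint)):
        return text
    text = str(text).strip()
    if text.startswith("(") and "/" in text:
        a, b = text.strip("()").split("/")
        return Midpoint((int(a), int(b)))
    if ":" in text:
        id_str, side = text.split(":")
        return (int(id_str), side.strip().lower())
    return int(text)


@dataclass(frozen=True)
class MeasurementDef:
    """One registry entry: a label, its kind, and its landmark keys."""

    label: str
    name: str
    kind: str
    landmarks: tuple[LandmarkKey, ...]
    region: str
    units: str = "mm"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"{self.label}: unknown kind {self.kind!r}")
        n = len(self.landmarks)
        if self.kind == "angle" and n != 3:
            raise ValueError(f"{self.label}: angles need 3 landmarks")
        if self.kind == "transverse" and n != 1:
            raise ValueError(
                f"{self.label}: transverse widths reference one paired key")
        if self.kind in ("vertical", "ap_projected", "euclidean") and n != 2:
            raise ValueError(f"{self.label}: distances need 2 landmarks")
        if self.kind == "angle" and self.units != "degrees":
            object.__setattr__(self, "units", "degrees")

    def landmark_ids(self) -> set[int]:
        ids: set[int] = set()
        for key in self.landmarks:
            if isinstance(key, Midpoint):
                ids.update(key.ids)
            elif isinstance(key, tuple):
                ids.add(key[0])
            else:
                ids.add(key)
        return ids


_M1011 = Midpoint((10, 11))

# label, name, kind, landmarks, region
_TABLE1 = [
    ("A", "Basisphenoid (rostral)", "transverse", (29,), "cranial"),
    ("B", "Basisphenoid (caudal)", "transverse", (30,), "cranial"),
    ("C", "Cranial base (posterior region)", "transverse", (32,), "cranial"),
    ("D", "Inter-mastoid width", "transverse", (17,), "cranial"),
    ("E", "Inter-zygomatic root width", "transverse", (_M1011,), "cranial"),
    ("F", "Anterior cranial vault width", "transverse", (12,), "cranial"),
    ("G", "Interior frontal arch width", "transverse", (34,), "cranial"),
    ("H", "Inter-zygomatic arch width", "transverse", (8,), "facial"),
    ("I", "Inter-orbital width", "transverse", (6,), "facial"),
    ("J", "Anterior nasal width", "transverse", (4,), "facial"),
    ("K", "Inter-maxillary width", "transverse", (7,), "facial"),
    ("L", "Inter-molar width", "transverse", (23,), "facial"),
    ("M", "Palatal width", "transverse", (21,), "facial"),
    ("N", "Posterior cranial vault", "vertical", (31, 15), "cranial"),
    ("O", "Middle cranial vault", "vertical", (28, 14), "cranial"),
    ("P", "Anterior cranial vault", "vertical", (27, 13), "cranial"),
    ("Q", "Frontal crest height", "vertical", (26, 33), "cranial"),
    ("R", "Anterior nasal height", "vertical", (2, 3), "facial"),
    ("S", "Facial height", "vertical", (19, 5), "facial"),
    ("T", "Posterior nasal height", "vertical", (20, 26), "facial"),
    ("U", "Anterior pharyngeal height", "vertical", (22, 27), "pharyngeal"),
    ("V", "Posterior pharyngeal height", "vertical", (24, 28), "pharyngeal"),
    ("W", "Total skull length", "ap_projected", (1, 16), "global"),
    ("X", "Cranial vault length", "ap_projected", (25, 16), "cranial"),
    ("Y", "Cranial base (rostral)", "ap_projected", (26, 31), "cranial"),
    ("Z", "Anterior cranial base", "ap_projected", (25, 26), "cranial"),
    ("AA", "Basiocciput", "ap_projected", (28, 31), "cranial"),
    ("BB", "Basisphenoid", "ap_projected", (27, 28), "cranial"),
    ("CC", "Presphenoid", "ap_projected", (26, 27), "cranial"),
    ("DD", "Facial region length", "ap_projected", (1, 22), "facial"),
    ("EE", "Palate", "ap_projected", (22, 20), "facial"),
    ("FF", "Maxilla", "ap_projected", (20, 18), "facial"),
    ("GG", "Premaxilla", "ap_projected", (18, 1), "facial"),
    ("HH", "Nasal", "ap_projected", (3, 5), "facial"),
    ("II", "Zygomatic", "ap_projected", (8, 9), "facial"),
    ("JJ", "Mandibular posterior height", "euclidean", (35, 36), "mandible"),
    ("KK", "Mandibular length (superior)", "euclidean", (35, 38), "mandible"),
    ("LL", "Mandibular length (inferior)", "euclidean", (36, 37), "mandible"),
    ("MM", "Upper Jaw", "ap_projected", (1, _M1011), "global"),
    ("NN", "Cranial base angle", "angle", (31, 27, 25), "cranial"),
    ("OO", "Anterior cranial vault angle", "angle", (27, 25, 13), "cranial"),
    ("PP", "Mid-anterior cranial vault angle", "angle", (25, 13, 14),
     "cranial"),
    ("QQ", "Mid-posterior cranial vault angle", "angle", (13, 14, 15),
     "cranial"),
    ("RR", "Posterior cranial vault angle", "angle", (14, 15, 16), "cranial"),
    ("SS", "Snout angle", "angle", (27, 25, 2), "facial"),
    ("TT", "Facial angle", "angle", (22, 5, 2), "facial"),
]


def table1_registry() -> list[MeasurementDef]:
    """The built-in 46-measurement registry (labels A..TT)."""
    return [
        MeasurementDef(label, name, kind, tuple(lms), region,
                       "degrees" if kind == "angle" else "mm")
        for label, name, kind, lms, region in _TABLE1
    ]


def registry_by_label(registry: Sequence[MeasurementDef] | None = None
                      ) -> dict[str, MeasurementDef]:
    return {d.label: d for d in (registry or table1_registry())}


# ---------------------------------------------------------------------------
# registry (de)serialization
# ---------------------------------------------------------------------------

def registry_to_records(registry: Sequence[MeasurementDef]) -> list[dict]:
    return [
        {"label": d.label, "name": d.name, "kind": d.kind,
         "landmarks": [str(k) if isinstance(k, Midpoint)
                       else (f"{k[0]}:{k[1]}" if isinstance(k, tuple)
                             else int(k))
                       for k in d.landmarks],
         "region": d.region, "units": d.units}
        for d in registry
    ]


def save_registry(registry: Sequence[MeasurementDef], path) -> None:
    path = Path(path)
    records = registry_to_records(registry)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        path.write_text(json.dumps(records, indent=2))


def load_registry(path) -> list[MeasurementDef]:
    path = Path(path)
    text = path.read_text()
    records = (yaml.safe_load(text)
               if path.suffix.lower() in (".yaml", ".yml")
               else json.loads(text))
    return [
        MeasurementDef(r["label"], r.get("name", r["label"]), r["kind"],
                       tuple(parse_key(k) for k in r["landmarks"]),
                       r.get("region", "global"), r.get("units", "mm"))
        for r in records
    ]


# ---------------------------------------------------------------------------
# key resolution
# ---------------------------------------------------------------------------

def _resolve(spec: SpecimenLandmarks, schema: LandmarkSchema,
             key: LandmarkKey) -> dict[str, np.ndarray]:
    """Resolve a landmark key to per-side points ({side: xyz}).  Paired
    keys yield entries for whichever of left/right are present; composite
    midpoints require both constituent IDs on a side."""
    if isinstance(key, Midpoint):
        a, b = key.ids
        out = {}
        for side in _sides_union(schema, a, b):
            pa, pb = spec.get(a, side), spec.get(b, side)
            if pa is not None and pb is not None:
                out[side] = 0.5 * (pa + pb)
        return out
    if isinstance(key, tuple):  # explicit (id, side)
        pt = spec.get(key[0], key[1])
        return {key[1]: pt} if pt is not None else {}
    sides = schema.sides_for(key)
    return {s: spec.get(key, s) for s in sides if spec.has(key, s)}


def _sides_union(schema: LandmarkSchema, a: int, b: int) -> tuple[str, ...]:
    sa, sb = schema.sides_for(a), schema.sides_for(b)
    if sa != sb:
        raise ValueError(
            f"composite midpoint ({a}/{b}) mixes lateralities")
    return sa


def _pair_sides(pa: dict, pb: dict) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Match the per-side points of two resolved keys into measurement
    pairs: same side with same side for two paired keys; each side against
    the midline point when one key is midline.  The bool marks whether the
    pairing could have used two sides but only one was available."""
    if not pa or not pb:
        return []
    a_mid, b_mid = MID in pa, MID in pb
    if a_mid and b_mid:
        return [(pa[MID], pb[MID], False)]
    pairs = []
    if a_mid or b_mid:
        mid_pt = pa[MID] if a_mid else pb[MID]
        lateral = pb if a_mid else pa
        partial = len(lateral) < 2
        for side in (LEFT, RIGHT):
            if side in lateral:
                pairs.append((mid_pt, lateral[side], partial))
        return pairs
    partial = not (len(pa) == len(pb) == 2)
    for side in (LEFT, RIGHT):
        if side in pa and side in pb:
            pairs.append((pa[side], pb[side], partial))
    return pairs


# ---------------------------------------------------------------------------
# elementary measurement operations
# ---------------------------------------------------------------------------

def transverse_width(spec: SpecimenLandmarks, key: int | Midpoint,
                     schema: LandmarkSchema | None = None) -> float | None:
    """Euclidean distance between the left and right instances of a paired
    landmark (or composite midpoint); None if either side is missing."""
    schema = schema or default_schema()
    pts = _resolve(spec, schema, key)
    if LEFT not in pts or RIGHT not in pts:
        return None
    return float(np.linalg.norm(pts[LEFT] - pts[RIGHT]))


def ap_projected_distance(spec: SpecimenLandmarks, frame: ReferenceFrame,
                          a: LandmarkKey, b: LandmarkKey,
                          schema: LandmarkSchema | None = None
                          ) -> float | None:
    """|ap(a) - ap(b)|, bilaterally averaged over matched sides."""
    schema = schema or default_schema()
    pairs = _pair_sides(_resolve(spec, schema, a), _resolve(spec, schema, b))
    if not pairs:
        return None
    vals = [abs(signed_axis_coordinate(p, frame, "ap")
                - signed_axis_coordinate(q, frame, "ap"))
            for p, q, _ in pairs]
    return float(np.mean(vals))


def vertical_distance(spec: SpecimenLandmarks, frame: ReferenceFrame | None,
                      a: LandmarkKey, b: LandmarkKey,
                      mode: str = "euclidean",
                      schema: LandmarkSchema | None = None) -> float | None:
    """Vertical measurement between two landmarks.

    Default mode is the plain 3D Euclidean distance (the projection
    language of the measurement scheme is reserved for the antero-posterior
    dimension); ``dv_projected`` measures along the frame's dv axis.
    """
    schema = schema or default_schema()
    pairs = _pair_sides(_resolve(spec, schema, a), _resolve(spec, schema, b))
    if not pairs:
        return None
    if mode == "euclidean":
        vals = [float(np.linalg.norm(p - q)) for p, q, _ in pairs]
    elif mode == "dv_projected":
        if frame is None:
            raise ValueError("dv_projected mode requires a frame")
        vals = [abs(signed_axis_coordinate(p, frame, "dv")
                    - signed_axis_coordinate(q, frame, "dv"))
                for p, q, _ in pairs]
    else:
        raise ValueError(f"unknown vertical mode {mode!r}")
    return float(np.mean(vals))


def euclidean_distance(spec: SpecimenLandmarks, a: LandmarkKey,
                       b: LandmarkKey,
                       schema: LandmarkSchema | None = None) -> float | None:
    """Frame-free 3D distance, bilaterally averaged over matched sides."""
    schema = schema or default_schema()
    pairs = _pair_sides(_resolve(spec, schema, a), _resolve(spec, schema, b))
    if not pairs:
        return None
    return float(np.mean([np.linalg.norm(p - q) for p, q, _ in pairs]))


def mandible_measurements(spec: SpecimenLandmarks,
                          schema: LandmarkSchema | None = None
                          ) -> dict[str, float | None]:
    """Evaluate the mandibular battery (labels JJ, KK, LL).

    The mandible is measured with Euclidean distances only and never uses
    the cranial reference frame, because the scans are not necessarily
    acquired with the teeth in occlusion.  Values are bilaterally averaged;
    a single present side is used as-is.
    """
    schema = schema or default_schema()
    defs = registry_by_label()
    return {label: euclidean_distance(spec, *defs[label].landmarks,
                                      schema=schema)
            for label in ("JJ", "KK", "LL")}


def angle_3pt(spec_or_points, a=None, vertex=None, c=None,
              schema: LandmarkSchema | None = None) -> float:
    """Interior angle (degrees, in [0, 180]) at the vertex of a landmark
    triple, from the two vertex-to-endpoint vectors.

    Accepts either (specimen, id_a, id_vertex, id_c) or a sequence of three
    3-vectors.  Paired endpoints are resolved to their left/right midpoint.
    """
    if isinstance(spec_or_points, SpecimenLandmarks):
        schema = schema or default_schema()
        pts = []
        for key in (a, vertex, c):
            resolved = _resolve(spec_or_points, schema, key)
            if not resolved:
                raise DegenerateGeometryError(
                    f"angle landmark {key} missing")
            pts.append(np.mean(list(resolved.values()), axis=0))
        p, v, q = pts
    else:
        p, v, q = (np.asarray(x, float) for x in spec_or_points)
    u1, u2 = p - v, q - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 <= 1e-12 or n2 <= 1e-12:
        raise DegenerateGeometryError(
            "angle undefined: vertex coincides with an endpoint")
    cosang = np.clip((u1 @ u2) / (n1 * n2), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


# ---------------------------------------------------------------------------
# full battery evaluation
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("specimen_id", "age_days", "label", "kind", "value",
                 "units", "flags")


def evaluate_all(spec: SpecimenLandmarks, frame: ReferenceFrame,
                 registry: Sequence[MeasurementDef] | None = None,
                 schema: LandmarkSchema | None = None,
                 vertical_mode: str = "euclidean") -> pd.DataFrame:
    """Evaluate every registry measurement for one specimen.

    Failures never raise: missing landmarks and degenerate geometry become
    quality flags with a NaN value.  The proxy flag is set whenever any
    contributing landmark is a soft-tissue proxy at the specimen's age
    (provenance only -- proxy landmarks are measured like any other).
    """
    schema = schema or default_schema()
    registry = list(registry or table1_registry())
    proxy_ids = set(schema.proxy_ids_at(spec.age_days))
    rows = []
    for d in registry:
        flags: list[str] = []
        value = math.nan
        try:
            if d.kind == "transverse":
                value = transverse_width(spec, d.landmarks[0], schema)
            elif d.kind == "ap_projected":
                value = ap_projected_distance(spec, frame, *d.landmarks,
                                              schema=schema)
            elif d.kind == "vertical":
                value = vertical_distance(spec, frame, *d.landmarks,
                                          mode=vertical_mode, schema=schema)
            elif d.kind == "euclidean":
                value = euclidean_distance(spec, *d.landmarks, schema=schema)
            elif d.kind == "angle":
                for key in d.landmarks:
                    if isinstance(key, int) and schema.is_paired(key):
                        flags.append(FLAG_PAIRED_MIDPOINT)
                        break
                value = angle_3pt(spec, *d.landmarks, schema=schema)
        except DegenerateGeometryError:
            flags.append(FLAG_DEGENERATE)
            value = math.nan
        if value is None:
            flags.append(FLAG_MISSING)
            value = math.nan
        elif d.kind != "angle":
            if _used_single_side(spec, schema, d):
                flags.append(FLAG_SINGLE_SIDE)
        if proxy_ids & d.landmark_ids() and FLAG_MISSING not in flags:
            flags.append(FLAG_PROXY)
        rows.append({
            "specimen_id": spec.specimen_id, "age_days": spec.age_days,
            "label": d.label, "kind": d.kind, "value": value,
            "units": d.units,
            "flags": ";".join(flags) if flags else FLAG_OK,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _used_single_side(spec, schema, d: MeasurementDef) -> bool:
    if d.kind == "transverse":
        return False
    resolved = [_resolve(spec, schema, k) for k in d.landmarks]
    pairs = _pair_sides(*resolved)
    return any(partial for _, _, partial in pairs)


def measure_cohort(specimens: Iterable[SpecimenLandmarks],
                   registry: Sequence[MeasurementDef] | None = None,
                   schema: LandmarkSchema | None = None,
                   frame_config: FrameConfig = FrameConfig(),
                   vertical_mode: str = "euclidean",
                   on_frame_error: str = "raise"
                   ) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Fit a frame and evaluate the full battery for every specimen.

    Returns the tidy measurement table (one row per specimen x label) and
    a per-specimen frame fit report.  ``on_frame_error="skip"`` drops
    specimens whose frame cannot be fitted, recording the error in the
    report instead of raising.
    """
    schema = schema or default_schema()
    tables, reports = [], {}
    for spec in specimens:
        try:
            frame = build_frame(spec, schema, frame_config)
        except Exception as exc:
            if on_frame_error == "skip":
                reports[spec.specimen_id] = {"error": str(exc)}
                continue
            raise
        reports[spec.specimen_id] = frame.fit_report
        tables.append(evaluate_all(spec, frame, registry, schema,
                                   vertical_mode=vertical_mode))
    table = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=TABLE_COLUMNS))
    return table, reports
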