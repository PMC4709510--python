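"""Reading and writing landmark coordinate files.

Two on-disk dialects are supported:

* the canonical landmark table, a plain CSV with columns
  ``specimen_id,age_days,sex,landmark_id,side,x,y,z`` (one row per
  coordinate point, ``#`` comment lines ignored); and
* 3D Slicer fiducial files, both the legacy ``.fcsv`` dialect and the JSON
  markup dialect, whose free-text labels are mapped onto ``(id, side)``
  keys through a user-supplied label map.

All coordinates are interpreted as millimetres.  Fiducial files written in
the LPS orientation convention are converted to RAS (x and y negated) so
that every specimen lives in a right-handed frame; since the measurement
frame is refitted per specimen and all measurements are unsigned, the
choice of convention does not affect any measurement.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParseError, ValidationError
from .schema import LEFT, MID, RIGHT, SIDES, LandmarkSchema, SpecimenLandmarks

TABLE_COLUMNS = ("specimen_id", "age_days", "sex", "landmark_id", "side",
                 "x", "y", "z")


# ---------------------------------------------------------------------------
# canonical landmark table
# ---------------------------------------------------------------------------

def read_landmark_table(path, schema: LandmarkSchema) -> list[SpecimenLandmarks]:
    """Read the canonical landmark CSV into one SpecimenLandmarks per specimen.

    Rows are validated against the schema: unknown landmark IDs and
    laterality violations (e.g. ``side=mid`` for a paired ID) are rejected
    with an error naming the ID; malformed rows report their line number.
    Specimens are returned in order of first appearance.
    """
    path = Path(path)
    specimens: dict[str, SpecimenLandmarks] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = set(TABLE_COLUMNS) - set(header)
                if missing:
                    raise ParseError(
                        f"missing columns {sorted(missing)}", line=lineno)
                idx = {c: header.index(c) for c in TABLE_COLUMNS}
                continue
            if len(row) < len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}",
                    line=lineno)
            try:
                sid = row[idx["specimen_id"]].strip()
                age = int(row[idx["age_days"]])
                sex = row[idx["sex"]].strip() or "unknown"
                lid = int(row[idx["landmark_id"]])
                side = row[idx["side"]].strip().lower()
                xyz = [float(row[idx[c]]) for c in ("x", "y", "z")]
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if side not in SIDES:
                raise ParseError(
                    f"unknown side {side!r} for landmark {lid}", line=lineno)
            if lid not in schema:
                raise ValidationError(
                    f"line {lineno}: unknown landmark ID {lid}")
            if side not in schema.sides_for(lid):
                raise ValidationError(
                    f"line {lineno}: landmark {lid} is "
                    f"{schema.entry(lid).laterality}; side {side!r} invalid")
            if not np.all(np.isfinite(xyz)):
                raise ParseError(
                    f"non-finite coordinate for landmark ({lid}, {side})",
                    line=lineno)
            spec = specimens.get(sid)
            if spec is None:
                spec = SpecimenLandmarks(sid, age, sex, provenance=str(path))
                specimens[sid] = spec
            if spec.has(lid, side):
                raise ValidationError(
                    f"line {lineno}: duplicate landmark ({lid}, {side}) "
                    f"for specimen {sid}")
            spec.set(lid, side, xyz)
    return list(specimens.values())


_SIDE_ORDER = {MID: 0, LEFT: 1, RIGHT: 2}


def write_landmark_table(specimens: list[SpecimenLandmarks], path,
                         header_comment: str | None = None) -> None:
    """Write specimens to the canonical CSV.

    Rows are grouped by specimen in input order and sorted by
    (landmark_id, side) within each specimen.  Non-finite coordinates are
    refused with an error naming the offending (id, side).
    """
    path = Path(path)
    for spec in specimens:
        for (lid, side), xyz in spec.coords.items():
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"specimen {spec.specimen_id}: refusing to write "
                    f"non-finite coordinate for landmark ({lid}, {side})")
    with path.open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for spec in specimens:
            keys = sorted(spec.coords,
                          key=lambda k: (k[0], _SIDE_ORDER[k[1]]))
            for lid, side in keys:
                x, y, z = spec.coords[(lid, side)]
                writer.writerow([spec.specimen_id, spec.age_days, spec.sex,
                                 lid, side, repr(float(x)), repr(float(y)),
                                 repr(float(z))])


# ---------------------------------------------------------------------------
# label maps for fiducial files
# ---------------------------------------------------------------------------

def parse_id_map(source) -> dict[str, tuple[int, str]]:
    """Parse a label map from a text config or a mapping.

    The text form has one ``label = id:side`` entry per line (``#`` starts
    a comment); the mapping form maps label to ``"id:side"`` or
    ``(id, side)``.
    """
    if isinstance(source, Mapping):
        items = source.items()
    else:
        items = []
        for lineno, line in enumerate(
                Path(source).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError("expected 'label = id:side'", line=lineno)
            label, value = (s.strip() for s in line.split("=", 1))
            items.append((label, value))
    out: dict[str, tuple[int, str]] = {}
    for label, value in items:
        if isinstance(value, str):
            try:
                id_str, side = value.split(":")
                key = (int(id_str), side.strip().lower())
            except ValueError as exc:
                raise ParseError(
                    f"bad id:side value {value!r} for label {label!r}"
                ) from exc
        else:
            key = (int(value[0]), str(value[1]).lower())
        if key[1] not in SIDES:
            raise ParseError(f"unknown side in mapping for label {label!r}")
        out[str(label)] = key
    return out


# ---------------------------------------------------------------------------
# 3D Slicer fiducials (.fcsv and JSON markups)
# ---------------------------------------------------------------------------

def _orient_to_ras(points: np.ndarray, convention: str) -> np.ndarray:
    convention = convention.upper()
    if convention == "RAS":
        return points
    if convention == "LPS":
        return points * np.array([-1.0, -1.0, 1.0])
    raise ParseError(f"unknown orientation convention {convention!r}")


def read_fiducials(path, id_map, *, specimen_id: str, age_days: int,
                   sex: str = "unknown",
                   orientation: str | None = None) -> SpecimenLandmarks:
    """Read a 3D Slicer fiducial file into a SpecimenLandmarks.

    ``id_map`` maps fiducial labels to ``(id, side)`` (see parse_id_map).
    Labels without a mapping are collected on the returned specimen's
    ``unmapped_labels`` attribute rather than silently dropped.
    ``orientation`` overrides the file's declared RAS/LPS convention.
    """
    path = Path(path)
    id_map = parse_id_map(id_map) if not isinstance(id_map, dict) else {
        k: v if isinstance(v, tuple) else parse_id_map({k: v})[k]
        for k, v in id_map.items()}
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        labels, points, file_orient = _read_fcsv(path)
    elif suffix in (".json", ".mrk"):
        labels, points, file_orient = _read_markups_json(path)
    else:
        raise ParseError(f"unknown fiducial dialect {path.suffix!r}")
    points = _orient_to_ras(points, orientation or file_orient)

    spec = SpecimenLandmarks(specimen_id, age_days, sex,
                             provenance=str(path))
    unmapped: list[str] = []
    seen: set[str] = set()
    for label, xyz in zip(labels, points):
        if label in seen:
            raise ValidationError(f"duplicate fiducial label {label!r}")
        seen.add(label)
        key = id_map.get(label)
        if key is None:
            unmapped.append(label)
            continue
        if key in spec.coords:
            raise ValidationError(
                f"labels map to duplicate landmark key {key}")
        spec.set(key[0], key[1], xyz)
    spec.unmapped_labels = unmapped  # type: ignore[attr-defined]
    return spec


def _read_fcsv(path: Path):
    labels, points = [], []
    orient = "LPS"  # Slicer >= 4.11 default
    with path.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.lower().startswith("coordinatesystem"):
                    value = stripped.split("=", 1)[1].strip()
                    orient = {"0": "LPS", "1": "RAS"}.get(value, value)
                continue
            if not line.strip():
                continue
            fields = next(csv.reader([line]))
            if len(fields) < 4:
                raise ParseError("fcsv row needs id,x,y,z,...", line=lineno)
            try:
                xyz = [float(v) for v in fields[1:4]]
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            label = fields[11].strip() if len(fields) > 11 else fields[0]
            labels.append(label)
            points.append(xyz)
    return labels, np.asarray(points, dtype=float).reshape(-1, 3), orient


def _read_markups_json(path: Path):
    try:
        doc = json.loads(path.read_text())
        markups = doc["markups"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"not a Slicer markups JSON file: {exc}") from exc
    labels, points = [], []
    orient = "LPS"
    for markup in markups:
        orient = markup.get("coordinateSystem", orient)
        for cp in markup.get("controlPoints", []):
            labels.append(str(cp.get("label", "")))
            points.append([float(v) for v in cp["position"]])
    return labels, np.asarray(points, dtype=float).reshape(-1, 3), orient
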