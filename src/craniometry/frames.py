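"""Per-specimen anatomical reference frames.

Each specimen gets a measurement frame built from its own landmarks, so no
global scanner orientation is ever assumed:

1. the mid-sagittal plane (MSP), a total-least-squares plane through the
   midline landmarks (optionally, a bilateral-symmetry plane estimated from
   left/right pairs); its unit normal is the medio-lateral (ml) axis;
2. the occlusal plane, constrained to be perpendicular to the MSP and
   fitted through the palatal cusp tips of the first and second molars;
   its unit normal is the dorso-ventral (dv) axis;
3. the antero-posterior (ap) axis, the cross product ml x dv, oriented
   rostrally.

Antero-posterior "projected distances" between two landmarks are then the
absolute difference of their ap coordinates, i.e. the distance between the
two parallel coronal planes (perpendicular to both reference planes)
passing through the landmarks.

Sign conventions are landmark-anchored: ml points toward the side labelled
right (sign of the right-side paired-landmark centroid), dv toward the
calvarium (landmark 13 positive), and ap rostrally (landmark 1 minus
landmark 16 positive).  The three anchors over-determine chirality; when
they conflict, the rostral ap anchor wins and the ml sign is flipped, which
is recorded in the fit report.  Every measurement is unsigned, so sign
conventions never change a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InsufficientLandmarksError
from .schema import LEFT, RIGHT, LandmarkSchema, SpecimenLandmarks

#: Default molar palatal cusp landmarks (first and second molars, both
#: sides).  At P7 the unerupted molars' crypt cusps are digitized like any
#: other landmark, so no special casing is needed.
DEFAULT_CUSP_KEYS = ((21, LEFT), (21, RIGHT), (23, LEFT), (23, RIGHT))


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float))
        n = np.asarray(self.normal, float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class FrameConfig:
    """Options controlling reference-frame construction."""

    msp_mode: str = "midline_tls"      # or "symmetry"
    occlusal_mode: str = "best_fit"    # or "tangent"
    cusp_keys: tuple = DEFAULT_CUSP_KEYS
    dv_anchor: int = 13                # landmark on the calvarial side
    rostral_pair: tuple[int, int] = (1, 16)   # (rostral, caudal) anchors
    rostral_fallback: tuple[int, int] | None = (2, 15)


@dataclass
class ReferenceFrame:
    """Fitted MSP + occlusal plane and the derived orthonormal axes."""

    msp: Plane
    occlusal: Plane
    axis_ml: np.ndarray
    axis_dv: np.ndarray
    axis_ap: np.ndarray
    fit_report: dict = field(default_factory=dict)

    @property
    def origin(self) -> np.ndarray:
        return self.msp.point

    def axis(self, name: str) -> np.ndarray:
        return {"ml": self.axis_ml, "dv": self.axis_dv,
                "ap": self.axis_ap}[name]


# ---------------------------------------------------------------------------
# mid-sagittal plane
# ---------------------------------------------------------------------------

def _tls_plane(points: np.ndarray) -> tuple[Plane, float]:
    """Total-least-squares plane: minimizes sum of squared point-plane
    distances.  Returns the plane and the RMS residual."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # smallest right singular vector = normal of the best-fit plane
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 1e-12 * max(svals[0], 1.0):
        raise DegenerateGeometryError(
            "landmarks are collinear; plane fit is underdetermined")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(centroid, normal), rms


def fit_midsagittal(spec: SpecimenLandmarks,
                    midline_ids: list[int] | tuple[int, ...],
                    schema: LandmarkSchema | None = None,
                    mode: str = "midline_tls") -> Plane:
    """Fit the mid-sagittal plane.

    ``midline_tls`` (default) fits a total-least-squares plane through the
    present midline landmarks.  ``symmetry`` additionally uses the
    midpoints of left/right antimere pairs (requires ``schema``); the two
    estimators agree exactly on mirror-symmetric specimens.

    The normal sign is chosen so that the centroid of right-side paired
    landmarks has positive signed distance (when any right-side landmarks
    are present).
    """
    pts = [spec.coords[(lid, "mid")] for lid in midline_ids
           if spec.has(lid, "mid")]
    if mode == "symmetry":
        if schema is None:
            raise ValueError("symmetry mode requires a schema")
        for lid in schema.paired_ids:
            left, right = spec.get(lid, LEFT), spec.get(lid, RIGHT)
            if left is not None and right is not None:
                pts.append(0.5 * (left + right))
    elif mode != "midline_tls":
        raise ValueError(f"unknown msp mode {mode!r}")
    if len(pts) < 3:
        raise InsufficientLandmarksError(
            f"mid-sagittal fit needs >=3 landmarks, found {len(pts)}")
    plane, _rms = _tls_plane(np.array(pts))

    right_pts = np.array([v for (lid, side), v in spec.coords.items()
                          if side == RIGHT])
    if len(right_pts) and plane.signed_distance(
            right_pts.mean(axis=0)).item() < 0:
        plane = plane.flipped()
    return plane


def midsagittal_rms(spec: SpecimenLandmarks, plane: Plane,
                    midline_ids) -> float:
    pts = np.array([spec.coords[(lid, "mid")] for lid in midline_ids
                    if spec.has(lid, "mid")])
    return float(np.sqrt(np.mean(plane.signed_distance(pts) ** 2)))


# ---------------------------------------------------------------------------
# occlusal plane (constrained perpendicular to the MSP)
# ---------------------------------------------------------------------------

def _msp_inplane_basis(msp: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the MSP (both perpendicular to its
    normal)."""
    n = msp.normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def fit_occlusal(spec: SpecimenLandmarks, msp: Plane,
                 cusp_keys=DEFAULT_CUSP_KEYS,
                 mode: str = "best_fit",
                 dv_anchor: int | None = 13) -> Plane:
    """Fit the occlusal plane, constrained to have its normal in the MSP
    (hence exactly perpendicular to the MSP normal).

    The cusp points are projected into the MSP, a total-least-squares line
    is fitted in that 2D subspace, and the line is swept along the MSP
    normal.  ``tangent`` mode afterwards translates the plane along its
    normal until every cusp lies on the non-calvarial side (anchored by
    ``dv_anchor``).
    """
    pts = np.array([spec.coords[k] for k in cusp_keys if k in spec.coords])
    if len(pts) < 2:
        raise InsufficientLandmarksError(
            f"occlusal fit needs >=2 cusp landmarks, found {len(pts)}")
    u, v = _msp_inplane_basis(msp)
    centered = pts - pts.mean(axis=0)
    p2 = np.column_stack([centered @ u, centered @ v])
    if np.linalg.norm(p2, axis=1).max() <= 1e-12:
        raise DegenerateGeometryError(
            "cusp points project to a single point in the mid-sagittal "
            "plane; occlusal orientation is underdetermined")
    # TLS line through the 2D points: direction = leading right singular
    # vector; the occlusal normal (within the MSP) is its perpendicular.
    _, _, vt = np.linalg.svd(p2, full_matrices=False)
    d2 = vt[0]
    n2 = np.array([-d2[1], d2[0]])
    normal = n2[0] * u + n2[1] * v
    plane = Plane(pts.mean(axis=0), normal)
    if mode == "tangent":
        anchor = spec.get(dv_anchor, "mid") if dv_anchor else None
        if anchor is None:
            raise InsufficientLandmarksError(
                "tangent mode requires the dorso-ventral anchor landmark")
        toward_anchor = plane.normal
        if plane.signed_distance(anchor).item() < 0:
            toward_anchor = -plane.normal
        # shift so all cusps are at or below the plane (opposite the anchor)
        shift = max(float(((p - plane.point) @ toward_anchor))
                    for p in pts)
        plane = Plane(plane.point + shift * toward_anchor, plane.normal)
    elif mode != "best_fit":
        raise ValueError(f"unknown occlusal mode {mode!r}")
    return plane


def occlusal_rms(spec: SpecimenLandmarks, plane: Plane,
                 cusp_keys=DEFAULT_CUSP_KEYS) -> float:
    pts = np.array([spec.coords[k] for k in cusp_keys if k in spec.coords])
    return float(np.sqrt(np.mean(plane.signed_distance(pts) ** 2)))


# ---------------------------------------------------------------------------
# full frame
# ---------------------------------------------------------------------------

def build_frame(spec: SpecimenLandmarks, schema: LandmarkSchema,
                config: FrameConfig = FrameConfig()) -> ReferenceFrame:
    """Construct the specimen's ReferenceFrame (see module docstring)."""
    midline_ids = [lid for lid in schema.midline_ids if spec.has(lid, "mid")]
    msp = fit_midsagittal(spec, midline_ids, schema=schema,
                          mode=config.msp_mode)
    occlusal = fit_occlusal(spec, msp, cusp_keys=config.cusp_keys,
                            mode=config.occlusal_mode,
                            dv_anchor=config.dv_anchor)

    ml = msp.normal.copy()
    dv = occlusal.normal.copy()
    # re-orthogonalize dv against ml (exact by construction; guards rounding)
    dv = dv - (dv @ ml) * ml
    dv /= np.linalg.norm(dv)

    report: dict = {
        "msp_rms": midsagittal_rms(spec, msp, midline_ids),
        "occlusal_rms": occlusal_rms(spec, occlusal, config.cusp_keys),
        "ml_flipped_for_rostral_ap": False,
    }

    anchor = spec.get(config.dv_anchor, "mid")
    if anchor is not None and occlusal.signed_distance(anchor).item() < 0:
        dv = -dv
    ap = np.cross(ml, dv)
    ap /= np.linalg.norm(ap)

    pair = config.rostral_pair
    if not (spec.has(pair[0], "mid") and spec.has(pair[1], "mid")):
        pair = config.rostral_fallback
        report["rostral_fallback_used"] = True
        if pair is None or not (spec.has(pair[0], "mid")
                                and spec.has(pair[1], "mid")):
            raise InsufficientLandmarksError(
                "rostral-orientation landmarks missing and no usable "
                "fallback pair configured")
    rostral = spec.get(pair[0], "mid") - spec.get(pair[1], "mid")
    if rostral @ ap < 0:
        # rostral anchor wins over the right-side ml anchor (chirality clash)
        ml, ap = -ml, -ap
        report["ml_flipped_for_rostral_ap"] = True

    report["orthogonality"] = {
        "ml.dv": float(ml @ dv), "ml.ap": float(ml @ ap),
        "dv.ap": float(dv @ ap)}
    return ReferenceFrame(msp=Plane(msp.point, ml),
                          occlusal=Plane(occlusal.point, dv),
                          axis_ml=ml, axis_dv=dv, axis_ap=ap,
                          fit_report=report)


def signed_axis_coordinate(point: np.ndarray, frame: ReferenceFrame,
                           axis: str) -> float:
    """Signed coordinate of ``point`` along a frame axis (mm), measured
    from the frame origin.  The projected distance between two landmarks
    along an axis is the absolute difference of their coordinates."""
    return float((np.asarray(point, float) - frame.origin) @ frame.axis(axis))
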