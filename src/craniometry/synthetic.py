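"""Synthetic landmark cohorts with the structure the pipeline assumes.

The generator produces cross-sectional cohorts of mouse-skull-like
landmark configurations so that every pipeline stage (I/O, frame fitting,
measurement, growth analysis) is testable without any scan data:

* a deterministic, exactly mirror-symmetric adult-scale template of all 55
  coordinate points, with the midline landmarks coplanar, the molar cusp
  landmarks defining a plane perpendicular to the symmetry plane, and the
  cranial/facial spans overlapping as in the real skull;
* a monomolecular (von Bertalanffy-type) growth law per (region, axis)
  that shrinks the template toward younger ages -- rapid growth before
  ~P28 and a plateau by ~P56-P84, with the cranial region maturing earlier
  than the facial region and the lower jaw transiently outgrowing the
  upper jaw between P7 and P14;
* per-specimen Gaussian landmark placement noise, optional extra
  left/right asymmetry, and optional random rigid motion, all driven by
  one master seed through deterministic per-specimen substreams.

The asymptotic (adult) value of every measurement is its template value;
the laws only set the fraction of that asymptote attained at each age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .schema import LEFT, MID, RIGHT, SpecimenLandmarks, default_schema

DEFAULT_AGES = (7, 14, 21, 28, 56, 84, 112)
DEFAULT_N_PER_AGE = 4        # animals per age group
DEFAULT_NOISE_SD = 0.05      # mm, landmark placement error


# ---------------------------------------------------------------------------
# growth laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthLaw:
    """Monomolecular growth: L(t) = Linf * (1 - (1 - f0) exp(-k (t - a0))).

    ``f0`` is the fraction of the asymptote attained at the reference age
    ``a0`` (days); ``k`` (1/day) sets how fast the remaining growth
    completes.  The curve is increasing, bounded by the asymptote, and has
    no inflection after a0 -- growth velocity decreases monotonically.
    """

    f0: float
    k: float
    a0: float = 7.0

    def __post_init__(self):
        if not (0.0 < self.f0 <= 1.0):
            raise ValueError("f0 must be in (0, 1]")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def fraction(self, age_days: float) -> float:
        """Fraction of the asymptotic size attained at ``age_days``."""
        if age_days < self.a0:
            raise ValueError(
                f"age {age_days} precedes the law's reference age {self.a0}")
        return 1.0 - (1.0 - self.f0) * math.exp(-self.k * (age_days - self.a0))


def monomolecular(t, linf, f0, k, a0=7.0):
    """The growth-law curve L(t); vectorized for fitting."""
    return linf * (1.0 - (1.0 - f0) * np.exp(-k * (np.asarray(t, float) - a0)))


#: Region assignment of each landmark ID for growth scaling.  The facial
#: block is the rostral skeleton; the palatal/molar landmarks follow the
#: cranial (early-maturing) laws because central facial widths plateau
#: early, unlike the lateral facial skeleton.
REGION_OF_LANDMARK = {
    **{k: "facial" for k in (1, 2, 3, 4, 5, 6, 7, 8, 9, 18, 19, 20)},
    **{k: "cranial" for k in (10, 11, 12, 13, 14, 15, 16, 17, 21, 22, 23,
                              24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34)},
    **{k: "mandible" for k in (35, 36, 37, 38)},
}


def default_growth_laws() -> dict[tuple[str, str], GrowthLaw]:
    """Per-(region, axis) laws calibrated to the observed ontogeny:

    * about 55% of the adult A-P dimension is already present at P7 and
      ~80% of the remaining cranial A-P growth completes by P14 (facial by
      ~P21);
    * cranial widths and heights plateau after ~P14-P21 while the lateral
      facial skeleton keeps widening past P28;
    * the mandible grows proportionally faster than the upper jaw from P7
      to P14 (upper/lower jaw ratio dips at P14, then recovers), and
      mandibular height outpaces mandibular length early on.
    """
    return {
        ("cranial", "ap"): GrowthLaw(f0=0.64, k=0.22),
        ("cranial", "ml"): GrowthLaw(f0=0.87, k=0.28),
        ("cranial", "dv"): GrowthLaw(f0=0.85, k=0.22),
        ("facial", "ap"): GrowthLaw(f0=0.55, k=0.16),
        ("facial", "ml"): GrowthLaw(f0=0.78, k=0.06),
        ("facial", "dv"): GrowthLaw(f0=0.70, k=0.08),
        ("mandible", "ap"): GrowthLaw(f0=0.44, k=0.168),
        ("mandible", "ml"): GrowthLaw(f0=0.44, k=0.168),
        ("mandible", "dv"): GrowthLaw(f0=0.40, k=0.12),
    }


# ---------------------------------------------------------------------------
# template skull
# ---------------------------------------------------------------------------

# Adult-scale template coordinates in a canonical frame: x = antero-
# posterior (rostral positive, caudal origin at landmark 16), y = medio-
# lateral (right positive), z = dorso-ventral (occlusal plane at z = 0).
# Midline landmarks at y = 0; paired landmarks mirrored at +/- y.
_TEMPLATE_MID = {
    1: (24.0, 1.5), 2: (23.0, 5.0), 3: (22.5, 2.5), 5: (14.8, 7.0),
    13: (10.0, 8.2), 14: (4.0, 7.8), 15: (1.0, 5.0), 16: (0.0, 1.8),
    18: (19.5, 0.8), 19: (14.5, 0.2), 20: (13.0, 0.3), 22: (11.9, -0.3),
    24: (5.5, -0.8), 25: (16.0, 4.2), 26: (12.6, 3.2), 27: (9.2, 2.6),
    28: (5.8, 2.2), 31: (2.2, 2.0), 33: (13.5, 8.0), 37: (21.6, -3.2),
    38: (22.3, -0.8),
}
_TEMPLATE_PAIRED = {
    4: (21.8, 1.5, 2.0), 6: (14.5, 2.6, 5.2), 7: (14.3, 3.3, 0.5),
    8: (14.0, 6.0, 2.5), 9: (10.5, 5.8, 2.8), 10: (10.4, 4.8, 1.5),
    11: (10.2, 4.9, 2.1), 12: (10.1, 4.0, 7.0), 17: (1.5, 5.2, 0.5),
    21: (11.6, 2.4, 0.0), 23: (14.6, 3.0, 0.0), 29: (9.0, 1.1, 2.4),
    30: (6.0, 1.4, 2.1), 32: (3.0, 2.6, 1.2), 34: (13.8, 3.6, 7.6),
    35: (10.2, 4.2, 0.5), 36: (9.0, 4.0, -4.0),
}


def template_skull(specimen_id: str = "template",
                   age_days: int = 112) -> SpecimenLandmarks:
    """The deterministic, exactly mirror-symmetric adult-scale template."""
    spec = SpecimenLandmarks(specimen_id, age_days, sex="male",
                             provenance="synthetic template")
    for lid, (x, z) in _TEMPLATE_MID.items():
        spec.set(lid, MID, (x, 0.0, z))
    for lid, (x, y, z) in _TEMPLATE_PAIRED.items():
        spec.set(lid, RIGHT, (x, y, z))
        spec.set(lid, LEFT, (x, -y, z))
    return spec


def grow(template: SpecimenLandmarks,
         laws: dict[tuple[str, str], GrowthLaw],
         age_days: int,
         region_of_landmark: dict[int, str] | None = None
         ) -> SpecimenLandmarks:
    """Shrink the adult template to ``age_days`` by region-wise
    anisotropic scaling about the canonical origin.  Exact bilateral
    symmetry is preserved (noise is added separately)."""
    regions = region_of_landmark or REGION_OF_LANDMARK
    coords = {}
    for (lid, side), xyz in template.coords.items():
        region = regions[lid]
        scale = np.array([laws[(region, ax)].fraction(age_days)
                          for ax in ("ap", "ml", "dv")])
        coords[(lid, side)] = xyz * scale
    return SpecimenLandmarks(f"{template.specimen_id}_P{age_days}",
                             age_days, sex=template.sex, coords=coords,
                             provenance="synthetic grown template")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cross-sectional cohort (ages in days)."""

    ages: tuple[int, ...] = DEFAULT_AGES
    n_per_age: int = DEFAULT_N_PER_AGE
    noise_sd: float = DEFAULT_NOISE_SD     # mm, per coordinate
    asymmetry_sd: float = 0.0              # mm, extra noise on paired points
    rigid_jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_per_age < 1:
            raise ValueError("n_per_age must be >= 1")
        if self.noise_sd < 0 or self.asymmetry_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def sample_cohort(cohort: CohortSpec = CohortSpec(),
                  laws: dict[tuple[str, str], GrowthLaw] | None = None,
                  template: SpecimenLandmarks | None = None
                  ) -> list[SpecimenLandmarks]:
    """Generate the cohort: per age, ``n_per_age`` specimens = grown
    template + i.i.d. Gaussian placement noise per coordinate (+ optional
    asymmetric perturbation of paired points, + optional random rigid
    motion).  Deterministic given ``cohort.seed``."""
    laws = laws or default_growth_laws()
    template = template or template_skull()
    streams = np.random.SeedSequence(cohort.seed).spawn(
        len(cohort.ages) * cohort.n_per_age)
    specimens = []
    i = 0
    for age in cohort.ages:
        grown = grow(template, laws, age)
        for j in range(cohort.n_per_age):
            rng = np.random.default_rng(streams[i])
            i += 1
            coords = {}
            for key, xyz in grown.coords.items():
                pt = xyz + rng.normal(0.0, cohort.noise_sd, size=3)
                if cohort.asymmetry_sd > 0 and key[1] in (LEFT, RIGHT):
                    pt = pt + rng.normal(0.0, cohort.asymmetry_sd, size=3)
                coords[key] = pt
            if cohort.rigid_jitter:
                R = _random_rotation(rng)
                t = rng.uniform(-10.0, 10.0, size=3)
                coords = {k: R @ v + t for k, v in coords.items()}
            specimens.append(SpecimenLandmarks(
                specimen_id=f"P{age}_s{j + 1}", age_days=age, sex="male",
                coords=coords,
                provenance=f"synthetic cohort seed={cohort.seed}"))
    return specimens


# ---------------------------------------------------------------------------
# growth-parameter recovery (validation harness)
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    """Result of fitting the growth-law form to per-age means."""

    linf: float
    f0: float
    k: float
    a0: float
    residual_rms: float
    converged: bool
    message: str = ""
    covariance: np.ndarray | None = field(default=None, repr=False)


def recover_growth_parameters(ages, means, a0: float = 7.0) -> GrowthFit:
    """Nonlinear least-squares fit of the monomolecular growth law to
    per-age mean measurements.

    Needs at least 4 age points.  Degenerate series (e.g. a constant
    measurement, where k and f0 are unidentifiable) and non-convergence
    are flagged rather than raised.
    """
    ages = np.asarray(ages, float)
    means = np.asarray(means, float)
    if len(ages) < 4:
        raise ValueError("growth-law fit needs >= 4 age points")
    linf0 = float(means.max())
    f00 = min(max(float(means[np.argmin(ages)] / linf0), 1e-3), 1.0 - 1e-3)
    try:
        popt, pcov = curve_fit(
            lambda t, linf, f0, k: monomolecular(t, linf, f0, k, a0),
            ages, means, p0=[linf0, f00, 0.1],
            bounds=([0.0, 1e-6, 0.0], [np.inf, 1.0, 5.0]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return GrowthFit(math.nan, math.nan, math.nan, a0, math.nan,
                         converged=False, message=str(exc))
    linf, f0, k = (float(v) for v in popt)
    resid = means - monomolecular(ages, linf, f0, k, a0)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    degenerate = k <= 1e-6 or f0 >= 1.0 - 1e-9
    return GrowthFit(linf, f0, k, a0, rms, converged=True,
                     message="degenerate (flat) series" if degenerate else "",
                     covariance=pcov)


__all__ = [
    "DEFAULT_AGES", "DEFAULT_N_PER_AGE", "DEFAULT_NOISE_SD",
    "GrowthLaw", "monomolecular", "REGION_OF_LANDMARK",
    "default_growth_laws", "template_skull", "grow", "CohortSpec",
    "sample_cohort", "GrowthFit", "recover_growth_parameters",
]
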