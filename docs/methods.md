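# Methods

`craniometry` implements a classical ("traditional") morphometric scheme
for the postnatal mouse craniofacial skeleton: named linear distances and
angles between homologous 3D landmarks, rather than Procrustes-based
geometric morphometrics.  This note records the models, conventions and
numerical choices the package makes, and what the synthetic data can and
cannot show.

## Landmark catalogue

A specimen is a set of 55 coordinate points in millimetres: 21 midline
landmarks (one point each) and 17 bilaterally paired landmarks (left and
right antimeres), drawn from a fixed catalogue of 38 landmark IDs.  The
midline/paired classification is induced by how each ID is used in the
measurement battery: IDs measured as right–left widths are paired, IDs
used in mid-sagittal angles and vertical spans are midline.  That usage
does not fully determine every ID, so the defaults make three judgement
calls, all user-overridable via `LandmarkSchema.with_overrides`:

* landmark 9 (the caudal zygomatic point, partner of paired landmark 8)
  is paired;
* mandibular landmarks 35 (condylar) and 36 (angular) are paired, while
  the symphyseal/incisal points 37 and 38 are midline — this is the only
  assignment of the mandibular quartet consistent with the catalogue
  totalling 21 + 17;
* landmark 33 (frontal crest) is midline, since the frontal crest is a
  midline structure.

Landmarks 13 (bregma) and 14 (lambda) are not ossified at postnatal day 7
(P7); at that age they are digitized from soft-tissue proxies.  The
schema records `proxy_ages = {7}` for both, and every measurement that
uses them at P7 carries a `proxy_used` provenance flag.  Proxy status
never changes a value.

Anatomical names for the 38 IDs are not bundled; the schema ships
`landmark_<k>` placeholders plus a user-overridable name map, because
every measurement depends only on IDs and laterality.

## Reference frame

Each specimen's measurement frame is fitted from its own landmarks; no
scanner orientation is assumed and the original scheme's manually
constructed planes are replaced by deterministic fits:

1. **Mid-sagittal plane (MSP)** — total-least-squares plane through the
   present midline landmarks (SVD of the centred coordinates; the normal
   is the smallest right singular vector).  An alternative estimator, a
   symmetry plane that additionally uses the midpoints of left/right
   antimere pairs, is available behind `FrameConfig(msp_mode="symmetry")`;
   the two agree exactly on mirror-symmetric specimens.  Fewer than three
   usable landmarks or a collinear configuration raises an error.
2. **Occlusal plane** — constrained to be exactly perpendicular to the
   MSP and fitted through the palatal cusp tips of the right and left
   first and second molars (default landmark pairs 21 and 23,
   configurable; at P7 the unerupted crypt cusps are digitized like any
   landmark).  The cusp points are projected into the MSP, a
   total-least-squares line is fitted in that 2D subspace, and the line
   is swept along the MSP normal.  "Touching" the cusps is interpreted as
   best-fit through them; a tangent mode (plane translated along its
   normal until all cusps lie on the non-calvarial side) exists but is
   off by default because tangency is ill-posed under landmark noise.
3. **Axes** — medio-lateral (ml) = MSP normal; dorso-ventral (dv) =
   occlusal normal, re-orthogonalized against ml (a rounding guard; the
   construction already makes the dot product zero); antero-posterior
   (ap) = ml × dv.  Orthogonality residuals above 1e-9 are never
   accepted.

Sign conventions are landmark-anchored and testable: ml toward the
right-side paired-landmark centroid, dv toward landmark 13 (calvarium),
ap toward landmark 1 (rostral, anchored by the landmark 1 vs 16
difference, with a configurable fallback pair when either is missing).
The three anchors over-determine chirality: for data whose labelled right
side makes (ml, dv, ap) left-handed, ap = ml × dv points caudally.  The
rostral anchor then takes precedence and ml is flipped, which is recorded
in the frame's fit report.  Because every measurement is an absolute
distance or an interior angle, sign conventions never affect a value;
this is why fiducial files in RAS and LPS orientation conventions yield
identical measurements.

## Measurements

The 46-entry registry (labels A–TT) evaluates five kinds:

* **transverse** (A–M): Euclidean distance between the left and right
  instances of one paired landmark;
* **vertical** (N–V): by default the plain 3D Euclidean distance between
  the two landmarks.  The scheme's projection language is reserved for
  the antero-posterior dimension, so verticals are not projected by
  default; a `dv_projected` mode is available;
* **antero-posterior projected** (W–II, MM): |Δ ap-coordinate|, i.e. the
  distance between the two parallel coronal planes through the landmarks.
  This is the right quantity for regions whose internal architecture
  rearranges during growth, and it makes regional spans additive along
  the skull axis;
* **mandibular Euclidean** (JJ, KK, LL): plain 3D distances that never
  use the cranial frame, because the scans need not be acquired with the
  teeth in occlusion;
* **angles** (NN–TT): interior angle at the vertex of a mid-sagittal
  triple, in degrees, clamped into [0°, 180°].

Whenever a key is paired, left- and right-side values are computed
separately and averaged; a measurement spanning a paired and a midline
landmark averages the two per-side distances to the midline point.  If
only one side is present, that side's value is used and flagged
`single_side`.  The composite key `(10/11)` is the per-side midpoint of
landmarks 10 and 11 (the midpoint of the zygomatic process of the
temporal bone, used as the articulation point of the lower jaw); it is
computed on demand, never stored.  Missing landmarks yield a flagged NaN
(`missing_landmarks`), never a silent omission and never an exception
from the batch evaluator.

## Growth analysis

The study design is cross-sectional (each animal measured at one age), so
all statistics operate on per-age groups:

* per-(label, age) mean and SE (sample SD, n−1 denominator, over √n; SE
  is undefined for n = 1 and reported missing);
* two-tailed equal-variance (pooled) Student t-tests between consecutive
  ages, df = n₁ + n₂ − 2, significant at p < α with α = 0.05 and **no**
  multiple-testing correction, matching the original analysis; a Holm
  option exists but is off by default;
* growth velocity per interval: Δ(per-age means) / Δ(days) × 1000, in
  μm/day; per-age group means are used rather than per-animal deltas
  because the design is cross-sectional.  Velocities may be negative;
* regional proportions: cranial% = 100·X/W, facial% = 100·DD/W,
  overlap% = cranial% + facial% − 100 (the cranial and facial spans share
  the palatal/presphenoid territory).  The identity
  cranial% + facial% − overlap% = 100 holds algebraically per specimen.
  Computed per specimen then averaged within age (ratio-of-means mode
  behind a flag); negative overlap is flagged, not raised;
* ratios (upper/lower jaw MM/KK, mandible KK/JJ, regional
  length/width/height) are computed per specimen and summarized as
  mean ± SE, preserving specimen-level variability; ratio-of-means is
  available by configuration.  The regional triplets are interpretive
  config defaults: cranial length X vs width D vs height O, facial
  length DD vs width K vs height S.  K (inter-maxillary width) rather
  than the wider inter-zygomatic H is the default facial width because
  the facial length/width ratio is expected to stay above 1 throughout
  ontogeny, and H is as long as the facial region itself in the adult.

## Synthetic cohorts

The generator exists so that every stage is testable without scan data.
Its defaults mirror the study design: ages {P7, P14, P21, P28, P56, P84,
P112}, n = 4 male specimens per age, 0.05 mm i.i.d. Gaussian landmark
placement noise per coordinate (below the reported ~0.14–0.17 mm
soft-tissue proxy repeatability, appropriate for hard-tissue points).

* **Template** — a deterministic, exactly mirror-symmetric adult-scale
  configuration of all 55 points: midline points exactly coplanar, molar
  cusp landmarks (21, 23) coplanar in a plane perpendicular to the
  symmetry plane and ~3 mm apart antero-posteriorly (so the occlusal fit
  is well-conditioned), landmarks 1…16 ordered rostro-caudally, and the
  cranial (25→16) and facial (1→22) spans overlapping: X + DD > W.
* **Growth law** — monomolecular (von Bertalanffy-type):
  L(t) = L∞·(1 − (1 − f0)·e^(−k·(t − a0))), a0 = 7 d.  Chosen over
  logistic/Gompertz because the observed postnatal curves show no
  inflection after P7; the family is pluggable.  Growth is region-wise
  anisotropic scaling of the template about a caudal origin, one law per
  (region ∈ {cranial, facial, mandible}) × (axis ∈ {ap, ml, dv}); the
  asymptote of every measurement is its template value.  The palatal and
  molar landmarks follow the cranial laws because central facial widths
  plateau early, unlike the lateral facial skeleton.
* **Calibration** — the default laws target the printed anchors: ~55% of
  adult total skull length at P7 with ~80% of the remaining cranial A-P
  growth complete by P14 (facial by ~P21); cranial widths/heights
  plateauing after P14–P21 while lateral facial widths stay significant
  past P28; a cranial-vault share of total length falling from ~78% to
  ~66.5% while the facial share rises to ~50.5%; and an upper/lower jaw
  ratio of ~1.17 at P7 dipping to its minimum at P14 before recovering.
  No attempt is made to reproduce exact printed group means — the raw
  landmark data are not deposited — so calibration targets orderings and
  plateaus, not values.
* **Noise and nuisance factors** — coordinate-level Gaussian noise (the
  digitization error model), optional extra left/right asymmetric
  perturbation, and optional random rigid motion of each specimen (which
  must not, and does not, change any measurement).  One master seed
  drives deterministic per-specimen substreams (`numpy` `SeedSequence`),
  so cohorts are bit-reproducible.

What passing tests on these cohorts do **not** show about real data:
landmark noise is isotropic and homoscedastic (real digitization error is
landmark- and surface-dependent), growth is smooth and monotone per
coordinate (no remodelling, no resorption, no inter-individual growth-law
variation beyond placement noise), specimens are near-perfectly
symmetric, and angular trends are whatever the scaling laws imply — the
angle battery is validated geometrically, not calibrated
ontogenetically.  Velocity monotonicity holds only for measurements
governed by a single law; region-mixed spans (e.g. the palate EE) can
transiently accelerate.

## Numerical choices and degenerate inputs

* Plane fits use SVD; collinearity is detected via the second singular
  value (relative threshold 1e-12) and raised as degenerate geometry.
* Angles clamp the normalized dot product into [−1, 1] before arccos;
  coincident vertex/endpoint raises degenerate geometry.
* The t statistic for two identical groups (zero pooled variance, zero
  mean difference) is defined as 0 with p = 1.
* The growth-law fit (`scipy.optimize.curve_fit`, bounded
  Levenberg–Marquardt/TRF) seeds L∞ from the series maximum and f0 from
  the first/last ratio; non-convergence and degenerate (flat) series are
  flagged with diagnostics rather than raised.
* Tolerances asserted in tests: round-trip I/O 1e-9 mm; frame
  orthogonality 1e-9; rigid-motion invariance of all measurements 1e-8
  (mm or degrees); geometric oracle agreement 1e-6; statistical oracle
  agreement 1e-10.

## Problem sizes

The default analyses and the acceptance script use the study-design
cohort size (7 ages × 4 specimens = 28 specimens, 46 measurements each).
Oracle suites use 200 random instances per geometric operation, 500
random group pairs for the statistical oracle, 200 Monte-Carlo replicates
for growth-parameter recovery, and 50 seeded replicates for the
qualitative-trend checks — sizes at which each check's sampling error is
far below the asserted margins.
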