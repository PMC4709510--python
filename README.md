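# craniometry

Landmark-based craniofacial morphometrics and postnatal growth analysis
for the mouse skull.

Mouse models of craniofacial disease are phenotyped by measuring the
skull, but interpreting a mutant requires a quantitative picture of how
the normal skull grows. This package implements a classical (landmark
distance/angle) morphometric pipeline for cross-sectional μCT-derived
landmark data from postnatal mice: it is aimed at researchers who digitize
3D skull landmarks (e.g. in 3D Slicer or Drishti) and want reproducible
craniometric measurements and growth statistics across age groups.

## What it computes

A specimen is a set of 55 landmark points (21 midline + 17 bilaterally
paired, from a 38-ID catalogue) with age and sex metadata. For each
specimen the package:

1. fits a **mid-sagittal plane** (total-least-squares over midline
   landmarks; normal = medio-lateral axis **m̂**),
2. fits an **occlusal plane** constrained perpendicular to it through the
   molar palatal cusp tips (normal = dorso-ventral axis **d̂**), and sets
   the antero-posterior axis **â** = **m̂** × **d̂** (rostral),
3. evaluates a 46-measurement battery (labels A–TT): transverse widths
   ‖x_R − x_L‖, vertical distances, antero-posterior **projected**
   distances |(x_a − x_b)·â| (distance between parallel coronal planes
   through the landmarks, bilaterally averaged for paired landmarks),
   frame-free mandibular Euclidean distances, and mid-sagittal angles.

Cohorts are then summarized as growth curves (mean ± SE per age),
consecutive-age equal-variance Student t-tests (two-tailed, α = 0.05, no
multiple-testing correction), growth velocities in μm/day, regional
antero-posterior proportions

    cranial% + facial% − overlap% = 100,   cranial% = 100·X/W,  facial% = 100·DD/W,

and upper/lower-jaw and length/width/height shape ratios.

A synthetic-cohort generator (mirror-symmetric template + monomolecular
growth laws L(t) = L∞(1 − (1 − f₀)e^{−k(t−7)}) per region and axis +
Gaussian landmark noise) emulates the study design — ages P7–P112, n = 4
per age — so the whole pipeline is testable without scan data.

## Worked example

```python
import craniometry as cm

cohort = cm.sample_cohort(cm.CohortSpec(seed=1))   # 7 ages x 4 specimens
table, reports = cm.measure_cohort(cohort)         # frames + 46 measurements

summary = cm.growth_curves(table)
print(summary[summary.label == "W"].to_string(index=False))
```

```
label  age_days  n      mean       se
    W         7  4 13.187280 0.040186
    W        14  4 20.398637 0.017733
    W        21  4 22.822337 0.019472
    W        28  4 23.642704 0.038773
    W        56  4 23.992712 0.038602
    W        84  4 24.001551 0.039371
    W       112  4 23.991279 0.025503
```

Total skull length (label W, landmark 1 → 16 projected) grows rapidly
from ~13.2 mm at P7 and plateaus near 24 mm by P56. Interval statistics
show where growth stops being detectable at n = 4:

```python
intervals = cm.consecutive_ttests(table)
print(intervals[intervals.label == "W"][
    ["age1", "age2", "delta_mean", "t", "p", "significant",
     "velocity_um_per_day"]].round(4).to_string(index=False))
```

```
 age1  age2  delta_mean         t      p  significant  velocity_um_per_day
    7    14      7.2114 -164.1746 0.0000         True            1030.1938
   14    21      2.4237  -92.0284 0.0000         True             346.2430
   21    28      0.8204  -18.9078 0.0000         True             117.1953
   28    56      0.3500   -6.3972 0.0007         True              12.5003
   56    84      0.0088   -0.1603 0.8779        False               0.3157
   84   112     -0.0103    0.2190 0.8339        False              -0.3668
```

Regional proportions show the cranial share of skull length shrinking as
the face outgrows it, with the shared (overlap) territory contracting:

```python
print(cm.regional_proportions(table).round(1)[
    ["age_days", "cv_pct", "fr_pct", "overlap_pct"]].to_string(index=False))
```

```
 age_days  cv_pct  fr_pct  overlap_pct
        7    78.0    42.6         20.6
       14    72.1    46.0         18.1
       21    68.7    48.6         17.3
       28    67.9    49.7         17.6
       56    66.5    50.3         16.8
       84    66.9    50.4         17.2
      112    66.7    50.5         17.2
```

## Command line

```sh
craniometry simulate  --seed 1 --out run/            # landmark CSV + provenance
craniometry measure   --input run/landmarks.csv --out run/
craniometry summarize --measurements run/measurements.csv --out run/ --plots
craniometry pipeline  --seed 1 --out run/ --plots    # all three chained
```

Runs are deterministic given config + seed; every output CSV is stamped
with the configuration hash and a `manifest.json` records the run.
Input formats: the canonical landmark CSV
(`specimen_id,age_days,sex,landmark_id,side,x,y,z`) and 3D Slicer
fiducials (`.fcsv` and JSON markups, RAS or LPS) via a label→(id, side)
map.

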