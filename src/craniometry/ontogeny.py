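"""Cross-sectional growth analysis of the measurement table.

Specimens are sampled cross-sectionally (each animal measured once, at one
age), so all statistics operate on per-age groups of per-specimen
measurement values:

* growth curves: per-(label, age) mean and standard error (sample SD with
  the n-1 denominator, divided by sqrt(n));
* interval statistics: two-tailed equal-variance (pooled) Student t-tests
  between consecutive ages (P14 vs P7, P21 vs P14, ...), significant at
  p < alpha with alpha = 0.05 and no multiple-testing correction by
  default (a Holm option is available but off by default);
* growth velocity: the difference of consecutive per-age means divided by
  the interval length, in micrometres per day;
* regional antero-posterior proportions: the percentages of total skull
  length occupied by the cranial vault and facial regions, which overlap;
  the identity cranial% + facial% - overlap% = 100 holds by construction;
* ratios: per-specimen measurement ratios (upper/lower jaw, and
  length/width/height shape ratios), summarized as mean +/- SE per age.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05

#: Interpretive defaults for the length/width/height shape-ratio panels.
#: cranial: vault length X against inter-mastoid width D and mid-vault
#: height O; facial: facial length DD against inter-maxillary width K and
#: facial height S.
DEFAULT_RATIO_DEFS = (
    ("X", "D"),   # cranial length/width
    ("X", "O"),   # cranial length/height
    ("DD", "K"),  # facial length/width
    ("DD", "S"),  # facial length/height
    ("KK", "JJ"),  # mandible length/height
)


def _clean(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows without a usable value (missing/degenerate flags)."""
    return table[np.isfinite(table["value"])]


def _pivot(table: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """Per-specimen wide table (specimen_id, age_days, one column per
    label) for ratio and proportion arithmetic."""
    sub = _clean(table[table["label"].isin(labels)])
    wide = sub.pivot_table(index=["specimen_id", "age_days"],
                           columns="label", values="value",
                           aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def growth_curves(table: pd.DataFrame,
                  ages: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-(label, age) n, mean and SE over non-missing values.

    SE is NaN for single-specimen groups.  Rows are ordered by label and
    age; ``ages`` restricts and orders the ages considered.
    """
    sub = _clean(table)
    if ages is not None:
        sub = sub[sub["age_days"].isin(list(ages))]
    grouped = sub.groupby(["label", "age_days"])["value"]
    out = grouped.agg(n="count", mean="mean",
                      se=lambda v: v.std(ddof=1) / math.sqrt(len(v))
                      if len(v) > 1 else math.nan).reset_index()
    return out.sort_values(["label", "age_days"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# consecutive-age t-tests
# ---------------------------------------------------------------------------

def pooled_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sample equal-variance Student t-test (two-tailed).

    Returns (t, p, df) with the pooled-variance statistic
    t = (mean(x) - mean(y)) / sqrt(sp^2 (1/n1 + 1/n2)), df = n1 + n2 - 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        t = 0.0 if abs(x.mean() - y.mean()) == 0 else math.inf
    else:
        t = (x.mean() - y.mean()) / denom
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), int(df)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def consecutive_ttests(table: pd.DataFrame,
                       ages: Sequence[int] | None = None,
                       alpha: float = DEFAULT_ALPHA,
                       correction: str | None = None) -> pd.DataFrame:
    """Interval statistics for every label over consecutive age pairs.

    Each interval row carries the mean change (delta_mean, later minus
    earlier), the pooled-variance t statistic (earlier minus later group
    order, matching pooled_ttest(x=earlier, y=later)), two-tailed p, df,
    the significance call at ``alpha``, and the growth velocity in
    micrometres/day.  Intervals with a group of n < 2 are flagged
    untestable.  ``correction="holm"`` applies a Holm adjustment within
    each label (off by default).
    """
    sub = _clean(table)
    if ages is None:
        ages = sorted(sub["age_days"].unique())
    rows = []
    for label, grp in sub.groupby("label"):
        for a1, a2 in zip(ages[:-1], ages[1:]):
            x = grp.loc[grp["age_days"] == a1, "value"].to_numpy()
            y = grp.loc[grp["age_days"] == a2, "value"].to_numpy()
            row = {"label": label, "age1": a1, "age2": a2,
                   "n1": len(x), "n2": len(y)}
            if len(x) >= 2 and len(y) >= 2:
                t, p, df = pooled_ttest(x, y)
                delta = float(y.mean() - x.mean())
                row.update(delta_mean=delta, t=t, p=p, df=df,
                           velocity_um_per_day=1000.0 * delta / (a2 - a1),
                           untestable=False)
            elif len(x) >= 1 and len(y) >= 1:
                delta = float(y.mean() - x.mean())
                row.update(delta_mean=delta, t=math.nan, p=math.nan,
                           df=0,
                           velocity_um_per_day=1000.0 * delta / (a2 - a1),
                           untestable=True)
            else:
                row.update(delta_mean=math.nan, t=math.nan, p=math.nan,
                           df=0, velocity_um_per_day=math.nan,
                           untestable=True)
            rows.append(row)
    out = pd.DataFrame(rows)
    if correction == "holm" and len(out):
        out["p_adjusted"] = np.nan
        for label, grp in out.groupby("label"):
            ok = grp["p"].notna()
            if ok.any():
                out.loc[grp.index[ok], "p_adjusted"] = _holm(
                    grp.loc[ok, "p"].to_numpy())
        pcol = "p_adjusted"
    elif correction not in (None, "none"):
        raise ValueError(f"unknown correction {correction!r}")
    else:
        pcol = "p"
    out["significant"] = (out[pcol] < alpha).fillna(False)
    return out


def growth_velocity(summary: pd.DataFrame) -> pd.DataFrame:
    """Growth velocity per consecutive-age interval from a growth_curves
    summary: (mean(age2) - mean(age1)) / (age2 - age1) * 1000, in um/day.
    """
    rows = []
    for label, grp in summary.groupby("label"):
        grp = grp.sort_values("age_days")
        ages = grp["age_days"].to_numpy()
        means = grp["mean"].to_numpy()
        for a1, a2, m1, m2 in zip(ages[:-1], ages[1:], means[:-1], means[1:]):
            if a2 == a1:
                raise ValueError(f"zero-length age interval at {a1}")
            rows.append({"label": label, "age1": int(a1), "age2": int(a2),
                         "velocity_um_per_day": 1000.0 * (m2 - m1) / (a2 - a1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regional antero-posterior proportions
# ---------------------------------------------------------------------------

def overlap_percent(cv_pct: float, fr_pct: float) -> float:
    """Overlap between the cranial-vault and facial spans, as % of total
    antero-posterior length: both regions' percentages count the shared
    span, so overlap% = cranial% + facial% - 100."""
    return cv_pct + fr_pct - 100.0


def regional_proportions(table: pd.DataFrame,
                         total_label: str = "W",
                         cranial_label: str = "X",
                         facial_label: str = "DD",
                         per_specimen: bool = True) -> pd.DataFrame:
    """Percentages of the total A-P skull length occupied by the cranial
    vault and facial regions, and their overlap, per age.

    By default computed per specimen and then averaged within each age;
    ``per_specimen=False`` instead forms the percentages from the per-age
    mean measurements.  Negative overlap (regions failing to tile the
    skull) is flagged, not raised.
    """
    labels = (total_label, cranial_label, facial_label)
    wide = _pivot(table, labels).dropna(subset=list(labels))
    if (wide[total_label] <= 0).any():
        raise ValueError("total A-P length must be positive")
    if not per_specimen:
        wide = wide.groupby("age_days", as_index=False)[list(labels)].mean()
    cv = 100.0 * wide[cranial_label] / wide[total_label]
    fr = 100.0 * wide[facial_label] / wide[total_label]
    ov = cv + fr - 100.0
    frame = pd.DataFrame({"age_days": wide["age_days"], "cv_pct": cv,
                          "fr_pct": fr, "overlap_pct": ov})
    out = frame.groupby("age_days", as_index=False).mean()
    out["cv_only_pct"] = out["cv_pct"] - out["overlap_pct"]
    out["fr_only_pct"] = out["fr_pct"] - out["overlap_pct"]
    out["negative_overlap"] = out["overlap_pct"] < 0
    return out


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def jaw_ratio(table: pd.DataFrame, lower_label: str = "KK",
              upper_label: str = "MM") -> pd.DataFrame:
    """Upper/lower jaw ratio per specimen (default MM / KK)."""
    wide = _pivot(table, (upper_label, lower_label)).dropna(
        subset=[upper_label, lower_label])
    if (wide[lower_label] == 0).any():
        raise ValueError("lower jaw length of zero")
    wide["ratio"] = wide[upper_label] / wide[lower_label]
    return wide[["specimen_id", "age_days", "ratio"]]


def shape_ratios(table: pd.DataFrame,
                 ratio_defs: Sequence[tuple[str, str]] = DEFAULT_RATIO_DEFS
                 ) -> pd.DataFrame:
    """Per-specimen ratios for each (numerator, denominator) label pair."""
    frames = []
    for num, den in ratio_defs:
        wide = _pivot(table, (num, den)).dropna(subset=[num, den])
        if (wide[den] == 0).any():
            raise ValueError(f"zero denominator in ratio {num}/{den}")
        frames.append(pd.DataFrame({
            "specimen_id": wide["specimen_id"],
            "age_days": wide["age_days"],
            "ratio_name": f"{num}/{den}",
            "ratio": wide[num] / wide[den]}))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["specimen_id", "age_days",
                                       "ratio_name", "ratio"]))


def summarize_ratios(ratios: pd.DataFrame,
                     by: str = "ratio_name") -> pd.DataFrame:
    """Mean +/- SE of per-specimen ratios within each age group."""
    keys = ["age_days"] if by == "age_days" or by not in ratios.columns \
        else [by, "age_days"]
    grouped = ratios.groupby(keys)["ratio"]
    out = grouped.agg(n="count", mean="mean",
                      se=lambda v: v.std(ddof=1) / math.sqrt(len(v))
                      if len(v) > 1 else math.nan).reset_index()
    return out.sort_values(keys).reset_index(drop=True)
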