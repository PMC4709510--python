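"""Growth-curve plotting.

Reproduces the conventional growth-curve layout: per-age mean +/- SE with
consecutive-age segments drawn solid where the interval change is
statistically significant and dashed where it is not.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def growth_curve_figure(summary: pd.DataFrame, intervals: pd.DataFrame,
                        labels: list[str], title: str = "",
                        ylabel: str = "mm"):
    """One panel of growth curves (mean +/- SE vs age) for the given
    measurement labels, with solid/dashed significance encoding."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label in labels:
        grp = summary[summary["label"] == label].sort_values("age_days")
        if grp.empty:
            continue
        ax.errorbar(grp["age_days"], grp["mean"], yerr=grp["se"],
                    fmt="o", ms=4, capsize=2, label=label)
        color = ax.lines[-1].get_color()
        iv = intervals[intervals["label"] == label]
        means = dict(zip(grp["age_days"], grp["mean"]))
        for _, row in iv.iterrows():
            a1, a2 = row["age1"], row["age2"]
            if a1 not in means or a2 not in means:
                continue
            style = "-" if row.get("significant", False) else "--"
            ax.plot([a1, a2], [means[a1], means[a2]], style, color=color,
                    lw=1.2)
    ax.set_xlabel("postnatal day")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return fig


def save_growth_plots(summary: pd.DataFrame, intervals: pd.DataFrame,
                      registry_by_kind: dict[str, list[str]],
                      out_dir, fmt: str = "png") -> list[str]:
    """One figure per measurement kind; returns the written file paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, labels in registry_by_kind.items():
        present = [l for l in labels
                   if (summary["label"] == l).any()]
        if not present:
            continue
        ylabel = "degrees" if kind == "angle" else "mm"
        fig = growth_curve_figure(summary, intervals, present,
                                  title=kind, ylabel=ylabel)
        path = out_dir / f"growth_{kind}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))
    return written
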