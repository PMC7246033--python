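"""Data reductions and figures for a finished cohort analysis.

Three views of the per-antibody percent changes:

* line-graph series per functional category across 12/24/48 h;
* star (radar) plots, one ring per timepoint, antibody order fixed by the
  panel so rings are comparable;
* dot plots of the highly up/down-regulated antibodies (|Δ%| above a
  threshold, default 10), split into up and down panels.

Builders are pure — they select and order `ExpressionChange` values without
modifying them — and every antibody they emit exists in the catalog.
CSV exports are byte-deterministic for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import PanelCatalog, PanelError
from .pipeline import ExpressionChange, changes_to_frame, filter_high_changes

TIMEPOINT_ORDER = (12, 24, 48)
# timepoint colour convention: blue / yellow / red for 12 / 24 / 48 h
TIMEPOINT_COLORS = {12: "tab:blue", 24: "gold", 48: "tab:red"}


@dataclass(frozen=True)
class GroupSeries:
    """Per-category Δ% series over the ordered timepoints (None = missing)."""

    category: str
    antibodies: tuple[str, ...]
    timepoints_h: tuple[int, ...]
    deltas: dict[str, dict[int, float | None]]


@dataclass(frozen=True)
class StarPlotData:
    """One timepoint ring: (antibody, Δ%) pairs in fixed panel order."""

    category: str
    timepoint_h: int
    points: tuple[tuple[str, float | None], ...]


def _index_changes(
    changes: Sequence[ExpressionChange],
) -> dict[tuple[str, int], ExpressionChange]:
    return {(c.antibody, c.timepoint_h): c for c in changes}


def build_group_series(
    changes: Sequence[ExpressionChange],
    catalog: PanelCatalog,
    category: str,
    timepoints_h: Sequence[int] = TIMEPOINT_ORDER,
) -> GroupSeries:
    """Series for a category's primaries plus its resolved overlap references.

    An empty change list yields all-missing series, not an error.
    """
    members = catalog.category_members(category)  # raises on unknown category
    by_key = _index_changes(changes)
    names: list[str] = []
    for m in members:
        if m.name not in names:
            names.append(m.name)
    deltas: dict[str, dict[int, float | None]] = {}
    for name in names:
        deltas[name] = {
            tp: (by_key[(name, tp)].delta_pct if (name, tp) in by_key else None)
            for tp in sorted(timepoints_h)
        }
    return GroupSeries(
        category=category,
        antibodies=tuple(names),
        timepoints_h=tuple(sorted(timepoints_h)),
        deltas=deltas,
    )


def build_star_plot_data(
    changes: Sequence[ExpressionChange],
    catalog: PanelCatalog,
    category: str,
    timepoint_h: int,
) -> StarPlotData:
    series = build_group_series(changes, catalog, category, (timepoint_h,))
    return StarPlotData(
        category=category,
        timepoint_h=timepoint_h,
        points=tuple(
            (name, series.deltas[name][timepoint_h]) for name in series.antibodies
        ),
    )


def build_dot_plot_data(
    changes: Sequence[ExpressionChange],
    threshold_pct: float = 10.0,
    subset: Sequence[str] | None = None,
) -> list[tuple[str, int, float]]:
    """(antibody, timepoint, Δ%) triples above the threshold, grouped by
    category/theme in input (panel) order, up-regulated before down."""
    kept = filter_high_changes(changes, threshold_pct)
    if subset is not None:
        wanted = set(subset)
        kept = [c for c in kept if c.antibody in wanted]
    ups = [
        (c.antibody, c.timepoint_h, c.delta_pct)
        for c in kept
        if c.delta_pct > 0
    ]
    downs = [
        (c.antibody, c.timepoint_h, c.delta_pct)
        for c in kept
        if c.delta_pct <= 0
    ]
    return ups + downs


# ---------------------------------------------------------------------------
# figures


def plot_line_graph(series: GroupSeries, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in series.antibodies:
        tps = [tp for tp in series.timepoints_h if series.deltas[name][tp] is not None]
        vals = [series.deltas[name][tp] for tp in tps]
        if tps:
            ax.plot(tps, vals, marker="o", linewidth=1, label=name)
    ax.axhline(0.0, color="0.6", linewidth=0.8)
    ax.set_xlabel("culture time (h)")
    ax.set_ylabel("expression change vs. control (%)")
    ax.set_title(series.category)
    if len(series.antibodies) <= 12:
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_star(
    stars: Sequence[StarPlotData], path: str | Path
) -> Path:
    """Radar plot with one ring per timepoint (shared antibody order)."""
    if not stars:
        raise ValidationError("need at least one timepoint ring")
    names = [n for n, _ in stars[0].points]
    n = len(names)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"polar": True})
    for star in stars:
        vals = np.array(
            [100.0 + (d if d is not None else 0.0) for _, d in star.points]
        )
        closed_angles = np.concatenate([angles, angles[:1]])
        closed_vals = np.concatenate([vals, vals[:1]])
        ax.plot(
            closed_angles,
            closed_vals,
            color=TIMEPOINT_COLORS.get(star.timepoint_h, "0.3"),
            linewidth=1,
            label=f"{star.timepoint_h} h",
        )
    ax.plot(
        np.linspace(0, 2 * np.pi, 200),
        np.full(200, 100.0),
        color="0.6",
        linewidth=0.8,
        linestyle="--",
    )
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=6)
    ax.set_title(stars[0].category)
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_dots(
    dots: Sequence[tuple[str, int, float]], path: str | Path, threshold_pct: float = 10.0
) -> Path:
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.16 * len({d[0] for d in dots}))))
    order: list[str] = []
    for name, _, _ in dots:
        if name not in order:
            order.append(name)
    ypos = {name: i for i, name in enumerate(order)}
    for name, tp, delta in dots:
        ax.plot(
            delta,
            ypos[name],
            "o",
            color=TIMEPOINT_COLORS.get(tp, "0.3"),
            markersize=4,
        )
    for edge in (threshold_pct, -threshold_pct):
        ax.axvline(edge, color="0.7", linewidth=0.8, linestyle=":")
    ax.axvline(0, color="0.5", linewidth=0.8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("expression change vs. control (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# exports


def group_series_frame(
    changes: Sequence[ExpressionChange], catalog: PanelCatalog
) -> pd.DataFrame:
    rows = []
    for category in catalog.categories:
        series = build_group_series(changes, catalog, category)
        for name in series.antibodies:
            d = series.deltas[name]
            rows.append(
                {
                    "category": category,
                    "antibody": name,
                    "t12": d.get(12),
                    "t24": d.get(24),
                    "t48": d.get(48),
                }
            )
    return pd.DataFrame(rows, columns=["category", "antibody", "t12", "t24", "t48"])


def export_results(
    changes: Sequence[ExpressionChange],
    catalog: PanelCatalog,
    out_dir: str | Path,
    threshold_pct: float = 10.0,
    categories: Sequence[str] | None = None,
    subset: Sequence[str] | None = None,
    figures: bool = True,
) -> dict[str, Path]:
    """Write the results CSV, group-series CSV and figures.

    CSV re-exports are byte-identical for identical inputs; figures are
    deterministic in content but excluded from the byte-identity claim.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    results = changes_to_frame(changes)
    paths["results"] = out / "results.csv"
    results.to_csv(paths["results"], index=False)

    series_df = group_series_frame(changes, catalog)
    paths["group_series"] = out / "group_series.csv"
    series_df.to_csv(paths["group_series"], index=False)

    if figures:
        wanted = list(categories) if categories else list(catalog.categories)
        for category in wanted:
            if category not in catalog.categories:
                raise PanelError(f"unknown category {category!r}")
            safe = "".join(c if c.isalnum() else "_" for c in category)
            series = build_group_series(changes, catalog, category)
            paths[f"line:{category}"] = plot_line_graph(
                series, out / f"line_{safe}.png"
            )
            stars = [
                build_star_plot_data(changes, catalog, category, tp)
                for tp in TIMEPOINT_ORDER
            ]
            paths[f"star:{category}"] = plot_star(stars, out / f"star_{safe}.png")
        dots = build_dot_plot_data(changes, threshold_pct, subset=subset)
        if dots:
            paths["dots"] = plot_dots(dots, out / "dot_plot.png", threshold_pct)
    return paths
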