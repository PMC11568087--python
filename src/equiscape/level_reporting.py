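"""Relative-level reporting: septile binning, change classes, summaries.

Continuous aspect values (per-capita provision of each ES, specialization,
value-type importance) are pooled per aspect across the baseline and all
scenarios and split into seven equal-frequency groups, giving each
(unit, state) an ordinal relative level from 1 "extremely low" to 7
"extremely high". Stakeholder aspects use three levels. Changes from the
baseline are classified by the level shift, and archetype cells (level of
the mean of member kebeles, mapped into the kebele-pooled septile
boundaries) are summarized as mean +/- sd over ES and value-type levels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .archetype_clustering import ArchetypeAssignment
from .es_provision import STUDY_AREA
from .landscape_io import write_long_table

LEVEL_LABELS_7 = [
    "extremely low",
    "very low",
    "low",
    "moderate",
    "high",
    "very high",
    "extremely high",
]
LEVEL_LABELS_3 = ["low", "moderate", "high"]

CHANGE_CLASSES = [
    "decrease",
    "moderate_decrease",
    "no_change",
    "moderate_increase",
    "increase",
]


def level_labels(n_bins: int) -> list[str]:
    if n_bins == 7:
        return LEVEL_LABELS_7
    if n_bins == 3:
        return LEVEL_LABELS_3
    return [f"level_{i}" for i in range(1, n_bins + 1)]


# ---------------------------------------------------------------------------
# Equal-frequency binning
# ---------------------------------------------------------------------------

def pooled_levels(
    values: pd.DataFrame,
    n_bins: int = 7,
    state_order: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Equal-frequency levels per aspect over the pooled (unit, state) values.

    *values* is long-format with columns (unit, aspect, state, value). Per
    aspect, all non-missing values across states are ranked (ties broken
    deterministically by unit id, then state order) and split into n_bins
    groups whose sizes differ by at most one (larger groups at the low end);
    level 1 holds the lowest values. Rows with missing values keep a
    missing level.

    Returns the level table (value, level, label columns) and, per aspect,
    the bin upper edges (max value per bin) used later to place aggregate
    cells on the same scale.
    """
    required = {"unit", "aspect", "state", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"values table missing columns: {sorted(missing)}")
    states = state_order or sorted(values["state"].unique())
    state_idx = {s: i for i, s in enumerate(states)}
    labels = level_labels(n_bins)

    out = values.copy().reset_index(drop=True)
    out["level"] = pd.Series(pd.NA, index=out.index, dtype="Int64")
    out["label"] = pd.Series(pd.NA, index=out.index, dtype="string")
    boundaries: dict[str, np.ndarray] = {}

    for aspect, group in out.groupby("aspect", sort=False):
        ok = group["value"].notna()
        pooled = group[ok]
        n = len(pooled)
        if n_bins > n:
            raise ValueError(
                f"aspect {aspect!r}: n_bins={n_bins} exceeds pooled count {n}"
            )
        order = sorted(
            pooled.index,
            key=lambda i: (
                out.at[i, "value"],
                str(out.at[i, "unit"]),
                state_idx.get(out.at[i, "state"], len(states)),
            ),
        )
        sizes = [n // n_bins + (1 if b < n % n_bins else 0) for b in range(n_bins)]
        edges = np.empty(n_bins)
        pos = 0
        for b, size in enumerate(sizes):
            chunk = order[pos : pos + size]
            for i in chunk:
                out.at[i, "level"] = b + 1
                out.at[i, "label"] = labels[b]
            edges[b] = out.loc[chunk, "value"].max()
            pos += size
        boundaries[aspect] = edges
    return out, boundaries


# ---------------------------------------------------------------------------
# Change classification
# ---------------------------------------------------------------------------

def change_class(level_state: int, level_baseline: int, n_bins: int = 7) -> str:
    """Classify the level shift from baseline to a scenario state.

    Seven-level aspects: +4..+6 increase, +1..+3 moderate increase, 0 no
    change, -1..-2 moderate decrease, -3..-6 decrease. Three-level aspects
    use +/-1 moderate and +/-2 strong.
    """
    for lvl, name in ((level_state, "level_state"), (level_baseline, "level_baseline")):
        if not 1 <= lvl <= n_bins:
            raise ValueError(f"{name}={lvl} outside 1..{n_bins}")
    delta = level_state - level_baseline
    if n_bins == 3:
        up, strong_up = 1, 2
        down, strong_down = -1, -2
    else:
        up, strong_up = 1, 4
        down, strong_down = -1, -3
    if delta >= strong_up:
        return "increase"
    if delta >= up:
        return "moderate_increase"
    if delta == 0:
        return "no_change"
    if delta > strong_down:
        return "moderate_decrease"
    return "decrease"


def add_change_classes(
    levels: pd.DataFrame, baseline_state: str = "baseline", n_bins: int = 7
) -> pd.DataFrame:
    """Append a change_class column comparing each state to the baseline
    within (unit, aspect)."""
    out = levels.copy()
    base = (
        out[out["state"] == baseline_state]
        .set_index(["unit", "aspect"])["level"]
    )
    if base.empty:
        raise ValueError(f"no rows for baseline state {baseline_state!r}")

    def classify(row):
        if pd.isna(row["level"]):
            return pd.NA
        b = base.get((row["unit"], row["aspect"]), pd.NA)
        if pd.isna(b):
            return pd.NA
        return change_class(int(row["level"]), int(b), n_bins=n_bins)

    out["change_class"] = out.apply(classify, axis=1).astype("string")
    return out


# ---------------------------------------------------------------------------
# Aggregate cells and summaries
# ---------------------------------------------------------------------------

def unit_levels_to_cells(
    values: pd.DataFrame,
    assignment: ArchetypeAssignment,
    boundaries: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Aggregate unit values to archetype / study-area cells on the kebele
    septile scale.

    Cell value = unweighted mean of member-kebele values; cell level = the
    septile interval (from the kebele-pooled boundaries) containing that
    mean, with boundary ties resolving to the lower level. Returns a long
    table with unit = archetype label or 'study_area'.
    """
    groups: dict[str, list[str]] = {
        label: assignment.members(label) for label in assignment.labels
    }
    empty = [lab for lab, mem in groups.items() if not mem]
    if empty:
        raise ValueError(f"empty archetypes: {empty}")
    groups[STUDY_AREA] = list(assignment.assignment)

    rows = []
    for (aspect, state), chunk in values.groupby(["aspect", "state"], sort=False):
        edges = boundaries[aspect]
        n_bins = len(edges)
        labels = level_labels(n_bins)
        per_unit = chunk.set_index("unit")["value"]
        for agg, members in groups.items():
            vals = per_unit.reindex([m for m in members if m in per_unit.index]).dropna()
            if vals.empty:
                continue
            mean = float(vals.mean())
            level = int(np.searchsorted(edges, mean, side="left")) + 1
            level = min(level, n_bins)
            rows.append(
                {
                    "unit": agg,
                    "aspect": aspect,
                    "state": state,
                    "value": mean,
                    "level": level,
                    "label": labels[level - 1],
                }
            )
    out = pd.DataFrame(rows)
    out["level"] = out["level"].astype("Int64")
    out["label"] = out["label"].astype("string")
    return out


def archetype_summary(cells: pd.DataFrame, aspects: list[str]) -> pd.DataFrame:
    """Mean and population sd of cell levels over *aspects* per
    (aggregate, state) — the bar-plot table (default: 11 ES + 4 value
    types, 15 aspects)."""
    sub = cells[cells["aspect"].isin(aspects)]
    rows = []
    for (agg, state), chunk in sub.groupby(["unit", "state"], sort=True):
        present = set(chunk["aspect"])
        missing = [a for a in aspects if a not in present]
        if missing:
            raise ValueError(
                f"aggregate {agg!r}, state {state!r}: missing aspects {missing}"
            )
        lv = chunk["level"].astype(float).to_numpy()
        rows.append(
            {
                "unit": agg,
                "state": state,
                "mean_level": float(lv.mean()),
                "sd_level": float(lv.std(ddof=0)),
                "n_aspects": len(aspects),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def plot_summary(summary: pd.DataFrame, path: str | Path, state_order: list[str]) -> None:
    """Bar chart of mean relative levels with sd error bars, grouped by
    aggregate and state."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    aggs = sorted(summary["unit"].unique(), key=lambda a: (a != STUDY_AREA, a))
    states = [s for s in state_order if s in set(summary["state"])]
    width = 0.8 / len(states)
    fig, ax = plt.subplots(figsize=(10, 4.5))
    x = np.arange(len(aggs))
    for si, state in enumerate(states):
        sub = summary[summary["state"] == state].set_index("unit")
        means = [sub.at[a, "mean_level"] if a in sub.index else np.nan for a in aggs]
        sds = [sub.at[a, "sd_level"] if a in sub.index else 0.0 for a in aggs]
        ax.bar(x + si * width, means, width, yerr=sds, capsize=2, label=state)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(aggs, rotation=20, ha="right")
    ax.set_ylabel("mean relative level (1-7)")
    ax.set_ylim(0, 7.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_report(
    out_dir: str | Path,
    levels: pd.DataFrame,
    cells: pd.DataFrame,
    summary: pd.DataFrame,
    state_order: list[str],
    grid=None,
    assignment: ArchetypeAssignment | None = None,
    stakeholder_levels: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the report bundle: long CSVs, optional GeoJSON choropleth and
    the summary bar chart. Deterministic for fixed inputs."""
    required = {"levels": levels, "cells": cells, "summary": summary}
    empty = [name for name, tab in required.items() if tab is None or len(tab) == 0]
    if empty:
        raise ValueError(f"missing report tables: {empty}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    for name, table in [
        ("levels.csv", levels),
        ("cells.csv", cells),
        ("summary.csv", summary.sort_values(["unit", "state"], kind="mergesort")),
    ]:
        path = out_dir / name
        write_long_table(table, path)
        written.append(path)
    if stakeholder_levels is not None and len(stakeholder_levels):
        path = out_dir / "stakeholder_levels.csv"
        write_long_table(stakeholder_levels, path)
        written.append(path)

    if grid is not None and assignment is not None:
        from .landscape_io import write_zones_geojson

        base = levels[levels["state"] == state_order[0]]
        props: dict[str, dict] = {}
        for kebele_id, label in assignment.assignment.items():
            props[kebele_id] = {"archetype": label}
        for _, row in base.iterrows():
            if row["unit"] in props and not pd.isna(row["level"]):
                props[row["unit"]][f"level_{row['aspect']}"] = int(row["level"])
        path = out_dir / "kebeles.geojson"
        write_zones_geojson(grid, path, properties=props)
        written.append(path)

    fig_path = out_dir / "summary_levels.png"
    plot_summary(summary, fig_path, state_order)
    written.append(fig_path)
    return written
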