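import itertools

import numpy as np
import pandas as pd
import pytest

from equiscape.archetype_clustering import cluster_kebeles
from equiscape.level_reporting import (
    CHANGE_CLASSES,
    LEVEL_LABELS_7,
    add_change_classes,
    archetype_summary,
    change_class,
    export_report,
    pooled_levels,
    unit_levels_to_cells,
)


def _long(values_by_unit_state, aspect="honey"):
    rows = [
        {"unit": u, "aspect": aspect, "state": s, "value": v}
        for (u, s), v in values_by_unit_state.items()
    ]
    return pd.DataFrame(rows)


def _assignment(units, labels):
    df = pd.DataFrame({"x": np.arange(len(units), dtype=float), "y": 0.0}, index=units)
    out = cluster_kebeles(df, k=len(set(labels)))
    out.assignment = dict(zip(units, labels))
    out.profiles = df.groupby(labels).mean().rename_axis("archetype")
    return out


# ---------------------------------------------------------------------------
# Pooled binning
# ---------------------------------------------------------------------------

def test_seven_values_one_per_bin():
    values = _long({(f"K{i:02d}", "baseline"): float(i) for i in range(1, 8)})
    levels, _ = pooled_levels(values, n_bins=7)
    ordered = levels.sort_values("value")
    assert ordered["level"].tolist() == [1, 2, 3, 4, 5, 6, 7]
    assert ordered["label"].tolist() == LEVEL_LABELS_7


def test_fourteen_values_two_per_bin():
    values = _long({(f"K{i:02d}", "baseline"): float(i) for i in range(14)})
    levels, _ = pooled_levels(values, n_bins=7)
    assert levels["level"].value_counts().tolist() == [2] * 7


def test_binning_matches_sort_and_slice_oracle(rng):
    units = [f"K{i:02d}" for i in range(1, 67)]
    states = ["baseline", "s1", "s2", "s3", "s4"]
    values = _long(
        {(u, s): float(rng.normal()) for u in units for s in states}
    )
    levels, _ = pooled_levels(values, n_bins=7, state_order=states)
    ranked = values.sort_values(
        ["value", "unit", "state"],
        key=lambda col: col.map({s: i for i, s in enumerate(states)})
        if col.name == "state"
        else col,
    )
    n = len(ranked)
    sizes = [n // 7 + (1 if b < n % 7 else 0) for b in range(7)]
    expected = np.repeat(np.arange(1, 8), sizes)
    got = levels.set_index(["unit", "state"]).loc[
        list(zip(ranked["unit"], ranked["state"]))
    ]["level"]
    np.testing.assert_array_equal(got.to_numpy(dtype=int), expected)
    assert max(sizes) - min(sizes) <= 1


def test_rank_preservation_with_ties(rng):
    """value(a) < value(b) implies level(a) <= level(b): the max level of a
    lower value never exceeds the min level of any higher value."""
    vals = np.round(rng.normal(size=120), 1)  # inject ties
    values = _long({(f"K{i:03d}", "baseline"): float(v) for i, v in enumerate(vals)})
    levels, _ = pooled_levels(values, n_bins=7)
    by_value = levels.groupby("value")["level"].agg(["min", "max"]).sort_index()
    running_max = by_value["max"].cummax().shift(1)
    ok = running_max.isna() | (by_value["min"] >= running_max)
    assert ok.all()


def test_n_bins_exceeding_pool_rejected():
    values = _long({("K01", "baseline"): 1.0, ("K02", "baseline"): 2.0})
    with pytest.raises(ValueError, match="n_bins"):
        pooled_levels(values, n_bins=7)


def test_missing_values_excluded_not_binned():
    mapping = {(f"K{i:02d}", "baseline"): float(i) for i in range(1, 8)}
    values = _long(mapping)
    values.loc[len(values)] = ["K99", "honey", "baseline", np.nan]
    levels, _ = pooled_levels(values, n_bins=7)
    assert pd.isna(levels.loc[levels["unit"] == "K99", "level"]).all()
    assert levels["level"].notna().sum() == 7


# ---------------------------------------------------------------------------
# Change classes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "state, base, expected",
    [
        (4, 4, "no_change"),
        (2, 6, "decrease"),        # delta -4
        (5, 2, "moderate_increase"),  # delta +3
        (7, 1, "increase"),        # delta +6
        (5, 6, "moderate_decrease"),
        (1, 7, "decrease"),        # delta -6, declared extension
    ],
)
def test_change_class_seven_levels(state, base, expected):
    assert change_class(state, base) == expected


def test_change_class_three_levels():
    assert change_class(3, 1, n_bins=3) == "increase"
    assert change_class(2, 1, n_bins=3) == "moderate_increase"
    assert change_class(1, 3, n_bins=3) == "decrease"
    assert change_class(2, 3, n_bins=3) == "moderate_decrease"
    assert change_class(2, 2, n_bins=3) == "no_change"


def test_change_classes_partition_all_deltas():
    """Exactly one class per delta in -6..6, and the mapping is monotone."""
    seen = []
    for delta in range(-6, 7):
        base = 7 if delta <= 0 else 1
        seen.append(change_class(base + delta, base))
    assert set(seen) <= set(CHANGE_CLASSES)
    order = [CHANGE_CLASSES.index(c) for c in seen]
    assert (np.diff(order) >= 0).all()
    assert seen[6] == "no_change"


def test_change_class_rejects_out_of_range():
    with pytest.raises(ValueError, match="level_state"):
        change_class(8, 1)
    with pytest.raises(ValueError, match="level_baseline"):
        change_class(1, 0)


def test_add_change_classes_joins_on_baseline():
    values = _long(
        {("K01", "baseline"): 1.0, ("K01", "s1"): 7.0, ("K02", "baseline"): 3.0,
         ("K02", "s1"): 2.0, ("K03", "baseline"): 5.0, ("K03", "s1"): 6.0,
         ("K04", "baseline"): 4.0}
    )
    levels, _ = pooled_levels(values, n_bins=7, state_order=["baseline", "s1"])
    out = add_change_classes(levels)
    base_rows = out[out["state"] == "baseline"]
    assert (base_rows["change_class"] == "no_change").all()


# ---------------------------------------------------------------------------
# Aggregate cells
# ---------------------------------------------------------------------------

def test_single_kebele_archetype_cell_level_equals_member(rng):
    units = [f"K{i:02d}" for i in range(1, 9)]
    values = _long({(u, "baseline"): float(i) for i, u in enumerate(units)})
    levels, boundaries = pooled_levels(values, n_bins=7)
    assignment = _assignment(units, ["solo"] + ["rest"] * 7)
    cells = unit_levels_to_cells(values, assignment, boundaries)
    solo = cells[(cells["unit"] == "solo")].iloc[0]
    member_level = levels[levels["unit"] == "K01"]["level"].iloc[0]
    assert solo["level"] == member_level


def test_cells_match_mean_then_interval_oracle(rng):
    units = [f"K{i:02d}" for i in range(1, 21)]
    states = ["baseline", "s1"]
    values = _long({(u, s): float(rng.normal()) for u in units for s in states})
    _, boundaries = pooled_levels(values, n_bins=7, state_order=states)
    labels = ["g1"] * 12 + ["g2"] * 8
    assignment = _assignment(units, labels)
    cells = unit_levels_to_cells(values, assignment, boundaries)
    per_unit = values.set_index(["unit", "state"])["value"]
    for _, row in cells.iterrows():
        members = (
            units
            if row["unit"] == "study_area"
            else [u for u, l in zip(units, labels) if l == row["unit"]]
        )
        mean = np.mean([per_unit[(u, row["state"])] for u in members])
        assert row["value"] == pytest.approx(mean, abs=1e-12)
        edges = boundaries["honey"]
        expect_level = min(int(np.searchsorted(edges, mean, side="left")) + 1, 7)
        assert row["level"] == expect_level


def test_cell_mean_stays_within_member_range(rng):
    units = [f"K{i:02d}" for i in range(1, 11)]
    values = _long({(u, "baseline"): float(rng.uniform()) for u in units})
    _, boundaries = pooled_levels(values, n_bins=7)
    assignment = _assignment(units, ["g1"] * 5 + ["g2"] * 5)
    cells = unit_levels_to_cells(values, assignment, boundaries)
    pooled_min, pooled_max = values["value"].min(), values["value"].max()
    assert cells["value"].between(pooled_min, pooled_max).all()


def test_empty_archetype_rejected(rng):
    units = ["K01", "K02", "K03"]
    values = _long({(u, "baseline"): 1.0 * i for i, u in enumerate(units)})
    _, boundaries = pooled_levels(values, n_bins=3)
    assignment = _assignment(units, ["g1", "g1", "g2"])
    assignment.assignment = {"K01": "g1", "K02": "g1", "K03": "g1"}  # g2 emptied
    with pytest.raises(ValueError, match="empty"):
        unit_levels_to_cells(values, assignment, boundaries)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _cells(levels_by_aspect, unit="g1", state="baseline"):
    return pd.DataFrame(
        [
            {"unit": unit, "aspect": a, "state": state, "value": float(l),
             "level": l, "label": "x"}
            for a, l in levels_by_aspect.items()
        ]
    )


def test_summary_constant_levels():
    cells = _cells({f"a{i}": 4 for i in range(15)})
    out = archetype_summary(cells, [f"a{i}" for i in range(15)])
    assert out.iloc[0]["mean_level"] == pytest.approx(4.0)
    assert out.iloc[0]["sd_level"] == pytest.approx(0.0)
    assert out.iloc[0]["n_aspects"] == 15


def test_summary_matches_direct_mean_sd(rng):
    aspects = [f"a{i}" for i in range(15)]
    lv = rng.integers(1, 8, size=15)
    out = archetype_summary(_cells(dict(zip(aspects, lv))), aspects)
    assert out.iloc[0]["mean_level"] == pytest.approx(lv.mean(), abs=1e-12)
    assert out.iloc[0]["sd_level"] == pytest.approx(lv.std(ddof=0), abs=1e-12)


def test_summary_dominance_implies_mean_order(rng):
    aspects = [f"a{i}" for i in range(15)]
    lv = rng.integers(1, 7, size=15)
    cells = pd.concat(
        [_cells(dict(zip(aspects, lv)), unit="lo"),
         _cells(dict(zip(aspects, lv + 1)), unit="hi")]
    )
    out = archetype_summary(cells, aspects).set_index("unit")
    assert out.at["hi", "mean_level"] >= out.at["lo", "mean_level"]


def test_summary_missing_aspect_named():
    cells = _cells({"a0": 3, "a1": 4})
    with pytest.raises(ValueError, match="a2"):
        archetype_summary(cells, ["a0", "a1", "a2"])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def test_export_report_deterministic(tmp_path, rng):
    units = [f"K{i:02d}" for i in range(1, 9)]
    states = ["baseline", "s1"]
    values = _long({(u, s): float(rng.normal()) for u in units for s in states})
    levels, boundaries = pooled_levels(values, n_bins=7, state_order=states)
    levels = add_change_classes(levels)
    assignment = _assignment(units, ["g1"] * 4 + ["g2"] * 4)
    cells = unit_levels_to_cells(values, assignment, boundaries)
    summary = archetype_summary(cells, ["honey"])

    export_report(tmp_path / "r1", levels, cells, summary, states)
    export_report(tmp_path / "r2", levels, cells, summary, states)
    for name in ("levels.csv", "cells.csv", "summary.csv"):
        assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()


def test_export_report_rejects_missing_tables(tmp_path):
    with pytest.raises(ValueError, match="levels"):
        export_report(tmp_path, pd.DataFrame(), _cells({"a": 1}), _cells({"a": 1}), ["baseline"])
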