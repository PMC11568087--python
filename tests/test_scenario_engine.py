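import math

import numpy as np
import pandas as pd
import pytest

from equiscape.scenario_engine import (
    Scenario,
    ScenarioRule,
    apply_rule,
    apply_scenario,
    composition_by_zone,
    distance_to_class,
    read_scenarios,
)

from conftest import make_grid


def brute_force_distance(classes, code, cell_size):
    focal = np.argwhere(classes == code)
    out = np.full(classes.shape, np.inf)
    for r in range(classes.shape[0]):
        for c in range(classes.shape[1]):
            if focal.size:
                out[r, c] = min(
                    math.hypot(r - f[0], c - f[1]) * cell_size for f in focal
                )
    return out


def brute_force_rule(grid, rule):
    """Expected converted cell set by explicit distance ranking."""
    dist = brute_force_distance(grid.classes, rule.focal_class, grid.cell_size_m)
    cand = [
        (r, c)
        for r in range(grid.shape[0])
        for c in range(grid.shape[1])
        if grid.classes[r, c] in rule.convertible_classes
    ]
    n_req = math.ceil(rule.area_ha * 1e4 / grid.cell_size_m**2 - 1e-9)
    sign = 1 if rule.mode == "nearest_to_focal" else -1
    ranked = sorted(cand, key=lambda rc: (sign * dist[rc], rc))
    return set(ranked[: min(n_req, len(cand))])


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def test_distance_trivial_cases():
    classes = np.full((3, 3), 2, np.int32)
    classes[1, 1] = 1
    grid = make_grid(classes, cell_size_m=100.0)
    d = distance_to_class(grid, 1)
    assert d[1, 1] == 0.0
    assert d[0, 1] == pytest.approx(100.0)
    assert d[0, 0] == pytest.approx(100.0 * math.sqrt(2))


def test_distance_absent_class_warns_all_infinite():
    grid = make_grid(np.ones((4, 4), np.int32))
    with pytest.warns(UserWarning, match="absent"):
        d = distance_to_class(grid, 7)
    assert np.isinf(d).all()


def test_distance_matches_brute_force(rng):
    for _ in range(5):
        classes = rng.integers(1, 4, size=(8, 8)).astype(np.int32)
        grid = make_grid(classes, cell_size_m=30.0)
        got = distance_to_class(grid, 2)
        want = brute_force_distance(classes, 2, 30.0)
        np.testing.assert_allclose(got, want, atol=1e-9)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def test_rule_validation():
    with pytest.raises(ValueError, match="target_class"):
        ScenarioRule(1, frozenset({2, 3}), 3, 10.0)
    with pytest.raises(ValueError, match="area_ha"):
        ScenarioRule(1, frozenset({2}), 3, 0.0)
    with pytest.raises(ValueError, match="mode"):
        ScenarioRule(1, frozenset({2}), 3, 1.0, mode="sideways")


def test_toy_grid_converts_nearest_column():
    """Forest in column 0, cropland elsewhere: converting 3 cells nearest to
    forest takes the column-1 cells with smallest row indices."""
    classes = np.full((5, 5), 2, np.int32)
    classes[:, 0] = 1
    grid = make_grid(classes, cell_size_m=100.0, legend={1: "forest", 2: "cropland", 3: "coffee"})
    rule = ScenarioRule(1, frozenset({2}), 3, area_ha=3.0)  # 3 cells at 1 ha/cell
    out, report = apply_rule(grid, rule)
    converted = set(map(tuple, np.argwhere(out.classes == 3)))
    assert converted == {(0, 1), (1, 1), (2, 1)}
    assert report.converted_cells == 3 and not report.exhausted


def test_budget_capped_at_available():
    classes = np.full((10, 10), 2, np.int32)
    classes[0, :4] = 1
    classes[5:, :] = 4  # only 40-ish convertible left
    grid = make_grid(
        classes, cell_size_m=100.0, legend={1: "f", 2: "c", 3: "t", 4: "p"}
    )
    available = int((classes == 2).sum())
    rule = ScenarioRule(1, frozenset({2}), 3, area_ha=100.0)  # wants 100 cells
    out, report = apply_rule(grid, rule)
    assert report.available_cells == available
    assert report.converted_cells == available
    assert report.exhausted


def test_zero_candidates_warns_not_errors():
    grid = make_grid(np.ones((4, 4), np.int32), legend={1: "a", 2: "b", 3: "c"})
    rule = ScenarioRule(1, frozenset({2}), 3, area_ha=1.0)
    with pytest.warns(UserWarning, match="no candidate"):
        out, report = apply_rule(grid, rule)
    assert report.converted_cells == 0 and report.exhausted
    np.testing.assert_array_equal(out.classes, grid.classes)


def test_unknown_code_rejected_with_rule_index():
    grid = make_grid(np.ones((4, 4), np.int32), legend={1: "a"})
    scenario = Scenario("s", [ScenarioRule(1, frozenset({2}), 9, 1.0)])
    with pytest.raises(ValueError, match="rule 0"):
        apply_scenario(grid, scenario)


def test_rule_matches_brute_force_both_modes(rng):
    for trial in range(20):
        classes = rng.integers(1, 5, size=(15, 15)).astype(np.int32)
        grid = make_grid(classes, cell_size_m=100.0)
        mode = "nearest_to_focal" if trial % 2 == 0 else "farthest_from_focal"
        rule = ScenarioRule(1, frozenset({2, 3}), 5, area_ha=float(rng.integers(1, 40)),
                            mode=mode)
        grid.legend[5] = "target"
        out, report = apply_rule(grid, rule)
        got = set(map(tuple, np.argwhere((out.classes == 5) & (classes != 5))))
        assert got == brute_force_rule(grid, rule)


def test_scope_restricts_candidates(rng):
    classes = np.full((4, 4), 2, np.int32)
    classes[0, 0] = 1
    zones = np.ones((4, 4), np.int32)
    zones[:, 2:] = 2
    grid = make_grid(classes, zones)
    grid.legend[3] = "t"
    rule = ScenarioRule(1, frozenset({2}), 3, area_ha=100.0, scope=frozenset({"K02"}))
    out, report = apply_rule(grid, rule)
    rows, cols = np.nonzero(out.classes == 3)
    assert (cols >= 2).all()
    assert report.available_cells == 8


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def test_empty_scenario_is_identity(study_area):
    out, reports = apply_scenario(study_area.grid, Scenario("idle", []))
    np.testing.assert_array_equal(out.classes, study_area.grid.classes)
    assert reports == []


def test_scenario_conserves_cells_and_nodata(study_area, rng):
    legend = study_area.grid.legend
    rule = ScenarioRule(1, frozenset({3, 4}), 7, area_ha=2000.0)
    out, _ = apply_scenario(study_area.grid, Scenario("s", [rule]))
    assert out.shape == study_area.grid.shape
    np.testing.assert_array_equal(
        out.classes == out.nodata, study_area.grid.classes == study_area.grid.nodata
    )
    # total area conserved class-sum-wise
    before = composition_by_zone(study_area.grid).to_numpy().sum()
    after = composition_by_zone(out).to_numpy().sum()
    assert after == pytest.approx(before)


def test_disjoint_rules_commute():
    classes = np.full((6, 6), 2, np.int32)
    classes[:, 0] = 1
    classes[:, 5] = 4
    legend = {1: "f", 2: "c", 4: "p", 7: "t1", 8: "t2"}
    grid = make_grid(classes, legend=legend)
    r1 = ScenarioRule(1, frozenset({2}), 7, area_ha=2.0)
    r2 = ScenarioRule(1, frozenset({4}), 8, area_ha=2.0)
    a, _ = apply_scenario(grid, Scenario("ab", [r1, r2]))
    b, _ = apply_scenario(grid, Scenario("ba", [r2, r1]))
    np.testing.assert_array_equal(a.classes, b.classes)


def test_monotone_budget(rng):
    classes = rng.integers(1, 4, size=(12, 12)).astype(np.int32)
    grid = make_grid(classes)
    grid.legend[9] = "t"
    prev = -1
    for ha in [1.0, 3.0, 6.0, 500.0]:
        _, report = apply_rule(grid, ScenarioRule(1, frozenset({2}), 9, ha))
        assert report.converted_cells >= prev
        assert report.converted_cells <= report.available_cells
        prev = report.converted_cells


# ---------------------------------------------------------------------------
# Zonal composition
# ---------------------------------------------------------------------------

def test_uniform_zone_composition():
    grid = make_grid(np.ones((10, 10), np.int32), cell_size_m=100.0)
    comp = composition_by_zone(grid)
    assert comp.loc["K01", "class_1"] == pytest.approx(100.0)  # 100 cells x 1 ha


def test_composition_matches_cell_loop_oracle(rng):
    classes = rng.integers(1, 5, size=(20, 20)).astype(np.int32)
    zones = rng.integers(1, 4, size=(20, 20)).astype(np.int32)
    grid = make_grid(classes, zones, cell_size_m=50.0)
    comp = composition_by_zone(grid)
    for z in (1, 2, 3):
        for c in (1, 2, 3, 4):
            n = int(((classes == c) & (zones == z)).sum())
            assert comp.loc[f"K{z:02d}", f"class_{c}"] == pytest.approx(n * 0.25)


def test_composition_zero_row_for_missing_kebele():
    grid = make_grid(np.ones((4, 4), np.int32))
    with pytest.warns(UserWarning, match="no raster cells"):
        comp = composition_by_zone(grid, ["K01", "K09"])
    assert comp.loc["K09"].sum() == 0.0


def test_conversion_moves_area_between_classes(study_area):
    rule = ScenarioRule(1, frozenset({3}), 7, area_ha=1000.0)
    out, reports = apply_scenario(study_area.grid, Scenario("s", [rule]))
    before = composition_by_zone(study_area.grid).sum()
    after = composition_by_zone(out).sum()
    delta = after - before
    assert delta["plantation_coffee"] == pytest.approx(-delta["cropland"])
    assert delta["plantation_coffee"] == pytest.approx(
        reports[0].converted_cells * study_area.grid.cell_area_ha
    )


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def test_read_scenarios_yaml(tmp_path):
    (tmp_path / "rules.yaml").write_text(
        """
- name: demo
  description: expand coffee near forest
  rules:
    - focal: forest
      convertible: [cropland]
      target: plantation_coffee
      area_ha: 50
      mode: nearest_to_focal
      scope: [K01]
"""
    )
    legend = {1: "forest", 3: "cropland", 7: "plantation_coffee"}
    scenarios = read_scenarios(tmp_path / "rules.yaml", legend)
    assert scenarios[0].name == "demo"
    rule = scenarios[0].rules[0]
    assert rule.focal_class == 1 and rule.target_class == 7
    assert rule.convertible_classes == frozenset({3})
    assert rule.scope == frozenset({"K01"})
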