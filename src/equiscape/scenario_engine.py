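"""Proximity-based translation of narrative scenario rules into LULC maps.

A scenario is an ordered list of conversion rules. Each rule converts a
hectare budget of candidate cells (the convertible classes, optionally
restricted to a set of kebeles) to a target class, picking candidates by
their Euclidean distance to the nearest cell of a focal class — either the
nearest candidates first (e.g. "expand plantation coffee next to forest") or
the farthest first (e.g. "intensify cropland away from forest cores").
Rules are applied sequentially and greedily with a deterministic (row, col)
tie-break, so results are reproducible and the total cell count, shape and
nodata mask are conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape_io import LandscapeGrid, warn_data

MODES = ("nearest_to_focal", "farthest_from_focal")


# ---------------------------------------------------------------------------
# Rule types
# ---------------------------------------------------------------------------

@dataclass
class ScenarioRule:
    """One proximity-based conversion.

    focal_class: LULC code distances are measured to.
    convertible_classes: codes eligible for conversion.
    target_class: code the converted cells receive (not itself convertible).
    area_ha: hectare budget of the conversion.
    mode: nearest_to_focal or farthest_from_focal.
    scope: optional set of kebele ids restricting the candidates.
    """

    focal_class: int
    convertible_classes: frozenset[int]
    target_class: int
    area_ha: float
    mode: str = "nearest_to_focal"
    scope: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.convertible_classes = frozenset(int(c) for c in self.convertible_classes)
        if self.scope is not None:
            self.scope = frozenset(str(s) for s in self.scope)
        if self.target_class in self.convertible_classes:
            raise ValueError("target_class must not be in convertible_classes")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")


@dataclass
class Scenario:
    """Named, ordered list of conversion rules."""

    name: str
    rules: list[ScenarioRule]
    description: str = ""


@dataclass
class ConversionReport:
    """Outcome of applying one rule."""

    rule_index: int
    requested_cells: int
    available_cells: int
    converted_cells: int
    exhausted: bool


# ---------------------------------------------------------------------------
# Distance primitive
# ---------------------------------------------------------------------------

def distance_to_class(grid: LandscapeGrid, class_code: int) -> np.ndarray:
    """Per-cell Euclidean distance (meters, cell centers) to the nearest
    cell of *class_code*; focal cells have distance 0. If the class is
    absent the matrix is all-infinite and a warning is emitted."""
    mask = grid.classes == class_code
    if not mask.any():
        warn_data(f"class code {class_code} absent from grid; distances are infinite")
        return np.full(grid.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=grid.cell_size_m)


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

def _check_codes(grid: LandscapeGrid, rule: ScenarioRule) -> None:
    known = set(grid.legend)
    for code in [rule.focal_class, rule.target_class, *rule.convertible_classes]:
        if code not in known:
            raise ValueError(f"unknown class code {code} (legend has {sorted(known)})")


def requested_cell_count(rule: ScenarioRule, grid: LandscapeGrid) -> int:
    """Hectare budget translated to whole cells (ceil)."""
    return math.ceil(rule.area_ha * 1e4 / grid.cell_size_m**2 - 1e-9)


def apply_rule(
    grid: LandscapeGrid, rule: ScenarioRule, rule_index: int = 0
) -> tuple[LandscapeGrid, ConversionReport]:
    """Apply one conversion rule, returning the new grid and a report.

    Candidates are ranked by distance to the focal class (ascending for
    nearest_to_focal, descending for farthest_from_focal) with ties broken
    by (row, col); the first min(requested, available) candidates convert.
    Zero candidates is reported (exhausted=True), not an error.
    """
    _check_codes(grid, rule)
    n_req = requested_cell_count(rule, grid)

    candidate = np.isin(grid.classes, list(rule.convertible_classes))
    candidate &= grid.classes != grid.nodata
    if rule.scope is not None:
        code_of = {kid: code for code, kid in grid.zone_legend.items()}
        scope_codes = [code_of[k] for k in rule.scope if k in code_of]
        candidate &= np.isin(grid.zones, scope_codes)

    rows, cols = np.nonzero(candidate)
    available = rows.size
    if available == 0:
        warn_data(f"rule {rule_index}: no candidate cells for conversion")
        return grid.copy(), ConversionReport(rule_index, n_req, 0, 0, True)

    dist = distance_to_class(grid, rule.focal_class)[rows, cols]
    key = dist if rule.mode == "nearest_to_focal" else -dist
    # np.lexsort: last key is primary
    order = np.lexsort((cols, rows, key))
    n_conv = min(n_req, available)
    take = order[:n_conv]

    out = grid.copy()
    out.classes[rows[take], cols[take]] = rule.target_class
    report = ConversionReport(
        rule_index=rule_index,
        requested_cells=n_req,
        available_cells=available,
        converted_cells=n_conv,
        exhausted=n_conv < n_req,
    )
    return out, report


def apply_scenario(
    grid: LandscapeGrid, scenario: Scenario
) -> tuple[LandscapeGrid, list[ConversionReport]]:
    """Apply a scenario's rules sequentially, each on the previous output."""
    current = grid
    reports: list[ConversionReport] = []
    for i, rule in enumerate(scenario.rules):
        try:
            current, report = apply_rule(current, rule, rule_index=i)
        except ValueError as exc:
            raise ValueError(f"scenario {scenario.name!r}, rule {i}: {exc}") from exc
        reports.append(report)
    return current, reports


# ---------------------------------------------------------------------------
# Zonal composition
# ---------------------------------------------------------------------------

def composition_by_zone(
    grid: LandscapeGrid, kebele_ids: list[str] | None = None
) -> pd.DataFrame:
    """Kebele x class-name area table in hectares from zonal tabulation.

    Rows cover *kebele_ids* if given (zero rows, with a warning, for kebeles
    without raster cells), else all kebeles present in the zone legend.
    """
    valid = (grid.classes != grid.nodata) & (grid.zones != grid.nodata)
    zones = grid.zones[valid]
    classes = grid.classes[valid]

    counts = pd.crosstab(zones, classes)
    counts = counts.reindex(columns=sorted(grid.legend), fill_value=0)
    counts.columns = [grid.legend[c] for c in counts.columns]
    counts.index = [grid.zone_legend.get(z, str(z)) for z in counts.index]
    area = counts.astype(float) * grid.cell_area_ha
    area.index.name = "kebele_id"

    if kebele_ids is not None:
        missing = [k for k in kebele_ids if k not in area.index]
        if missing:
            warn_data(f"kebeles with no raster cells (zero areas): {missing}")
        area = area.reindex(list(kebele_ids), fill_value=0.0)
        area.index.name = "kebele_id"
    return area


# ---------------------------------------------------------------------------
# Scenario configs
# ---------------------------------------------------------------------------

def _codes(legend: dict[int, str], *names: str) -> list[int]:
    by_name = {name: code for code, name in legend.items()}
    out = []
    for name in names:
        if name not in by_name:
            raise ValueError(f"class name {name!r} not in legend {sorted(by_name)}")
        out.append(by_name[name])
    return out


def read_scenarios(path: str | Path, legend: dict[int, str]) -> list[Scenario]:
    """Load scenarios from a YAML rule file; class names resolve via legend.

    Format::

        - name: my_scenario
          description: ...
          rules:
            - focal: forest
              convertible: [cropland, pasture]
              target: plantation_coffee
              area_ha: 2000
              mode: nearest_to_focal
              scope: [K01, K02]   # optional
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    scenarios = []
    for entry in raw:
        rules = []
        for r in entry.get("rules", []):
            (focal,) = _codes(legend, r["focal"])
            (target,) = _codes(legend, r["target"])
            convertible = _codes(legend, *r["convertible"])
            rules.append(
                ScenarioRule(
                    focal_class=focal,
                    convertible_classes=frozenset(convertible),
                    target_class=target,
                    area_ha=float(r["area_ha"]),
                    mode=r.get("mode", "nearest_to_focal"),
                    scope=frozenset(r["scope"]) if "scope" in r else None,
                )
            )
        scenarios.append(
            Scenario(name=entry["name"], rules=rules, description=entry.get("description", ""))
        )
    return scenarios


def example_scenarios(legend: dict[int, str], landscape_ha: float = 200_000.0) -> list[Scenario]:
    """Four qualitative narrative scenarios over the default legend.

    Budgets scale with the landscape size (about 2000 km^2 by default):

    - gain_over_grain: cash crops — khat and plantation coffee expand into
      cropland and pasture near existing khat / forest.
    - coffee_conservation: a biosphere-reserve mosaic — modest woody
      regeneration of cropland next to forest.
    - mining_green_gold: coffee investors — large plantation-coffee blocks
      replace forest-adjacent cropland, pasture and woody vegetation.
    - food_first: intensive farming — cropland expands into pasture and
      woody vegetation far from the protected forest cores.
    """
    (forest,) = _codes(legend, "forest")
    (woody,) = _codes(legend, "woody_vegetation")
    (cropland,) = _codes(legend, "cropland")
    (pasture,) = _codes(legend, "pasture")
    (khat,) = _codes(legend, "khat")
    (coffee,) = _codes(legend, "plantation_coffee")

    pct = landscape_ha / 100.0  # 1% of the landscape, in ha
    return [
        Scenario(
            name="gain_over_grain",
            description="Local cash crops: khat and plantation coffee expand",
            rules=[
                ScenarioRule(khat, frozenset({cropland}), khat, 2.0 * pct),
                ScenarioRule(forest, frozenset({cropland, pasture}), coffee, 3.0 * pct),
            ],
        ),
        Scenario(
            name="coffee_conservation",
            description="Biosphere reserve: gentle woody regeneration near forest",
            rules=[
                ScenarioRule(forest, frozenset({cropland}), woody, 1.0 * pct),
            ],
        ),
        Scenario(
            name="mining_green_gold",
            description="Coffee investors: large forest-adjacent coffee blocks",
            rules=[
                ScenarioRule(
                    forest, frozenset({cropland, pasture, woody}), coffee, 6.0 * pct
                ),
            ],
        ),
        Scenario(
            name="food_first",
            description="Intensive farming far from protected forest cores",
            rules=[
                ScenarioRule(
                    forest,
                    frozenset({pasture, woody}),
                    cropland,
                    4.0 * pct,
                    mode="farthest_from_focal",
                ),
            ],
        ),
    ]
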