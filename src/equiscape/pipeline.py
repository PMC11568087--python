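"""End-to-end orchestration of the six-step analysis.

simulate -> cluster -> scenarios -> provision -> socio -> report, from a
single config with one global seed. Each step's outputs are written under
the run directory and hashed into a manifest, so a rerun with the same
config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import archetype_clustering as ac
from . import es_provision as esp
from . import level_reporting as lr
from . import scenario_engine as se
from . import socio_valuation as sv
from . import synthetic_landscape as sl
from .landscape_io import read_kebele_table, write_grid, write_kebele_table

logger = logging.getLogger(__name__)

STEPS = ("simulate", "cluster", "scenarios", "provision", "socio", "report")

#: global-seed offsets per step (only simulate consumes randomness today,
#: but every step owns a stable sub-seed for forward compatibility)
SEED_OFFSETS = {name: i * 1009 for i, name in enumerate(STEPS)}

SPECIALIZATION_ASPECT = "specialization"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    steps: tuple[str, ...] = STEPS
    force: bool = False
    k: int = 4
    scaling: str = "minmax"
    linkage: str = "ward"
    noise_sd: float = 0.05
    grid_cell_m: float = 100.0
    n_respondents: int = 164
    scenarios_path: Path | None = None
    kebeles_path: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.steps if s not in STEPS]
        if unknown:
            raise ValueError(f"unknown steps: {unknown}")
        self.steps = tuple(s for s in STEPS if s in self.steps)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        for key in ("scenarios_path", "kebeles_path"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        return cls(**raw)

    def step_seed(self, step: str) -> int:
        return (self.seed + SEED_OFFSETS[step]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def assemble_long_values(
    percap: dict[str, esp.ProvisionTable],
    specialization: dict[str, pd.Series],
    importance: dict[str, pd.DataFrame],
    state_order: list[str],
) -> pd.DataFrame:
    """Stack per-capita ES provision, specialization and value importance
    into one long (unit, aspect, state, value) table — 16 aspects for the
    default registry."""
    rows = []
    for state in state_order:
        pc = percap[state].values
        for es in pc.columns:
            for unit, val in pc[es].items():
                rows.append((unit, es, state, float(val)))
        for unit, val in specialization[state].items():
            rows.append(
                (unit, SPECIALIZATION_ASPECT, state, float(val) if pd.notna(val) else None)
            )
        imp = importance[state]
        for vt in imp.columns:
            for unit, val in imp[vt].items():
                rows.append((unit, vt, state, float(val)))
    return pd.DataFrame(rows, columns=["unit", "aspect", "state", "value"])


def stakeholder_long_values(
    proportions: pd.DataFrame, state_order: list[str]
) -> pd.DataFrame:
    """Stakeholder proportions as a study-area-level long table (aspect =
    stakeholder_<org>)."""
    rows = []
    for state in state_order:
        for org in proportions.columns:
            rows.append(
                (esp.STUDY_AREA, f"stakeholder_{org}", state, float(proportions.at[state, org]))
            )
    return pd.DataFrame(rows, columns=["unit", "aspect", "state", "value"])


def run_all(config: RunConfig) -> dict:
    """Execute the enabled steps and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    partial = out / ".partial"
    partial.write_text("run in progress")

    manifest: dict = {"seed": config.seed, "steps": {}, "files": {}}
    artifacts: dict = {}
    current = None
    try:
        for step in config.steps:
            current = step
            manifest["steps"][step] = {"seed": config.step_seed(step)}
            _STEP_FUNCS[step](config, artifacts, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline step {current!r} failed: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != ".partial":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    partial.unlink()
    return manifest


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def _step_simulate(config: RunConfig, art: dict, out: Path) -> None:
    gen = sl.GeneratorConfig(
        noise_sd=config.noise_sd,
        grid_cell_m=config.grid_cell_m,
        n_respondents=config.n_respondents,
        seed=config.step_seed("simulate"),
    )
    area = sl.generate_study_area(gen)
    art["study_area"] = area
    art["kebeles"] = area.kebeles
    art["grid"] = area.grid
    art["models"] = area.es_models
    art["weights"] = area.value_weights
    art["stakeholder_counts"] = area.stakeholders

    write_kebele_table(area.kebeles, out / "kebeles.csv")
    write_grid(area.grid, out / "grid")
    pd.Series(area.truth_assignment, name="archetype").rename_axis("kebele_id").to_csv(
        out / "truth_assignment.csv"
    )
    area.value_weights.to_csv(out / "value_weights.csv")
    area.stakeholders.to_csv(out / "stakeholder_counts.csv")


def _require(art: dict, keys: list[str], step: str) -> None:
    missing = [k for k in keys if k not in art]
    if missing:
        raise ValueError(
            f"step {step!r} requires inputs {missing}; enable the producing "
            f"step or provide them via config paths"
        )


def _step_cluster(config: RunConfig, art: dict, out: Path) -> None:
    if "kebeles" not in art and config.kebeles_path is not None:
        art["kebeles"] = read_kebele_table(config.kebeles_path)
    _require(art, ["kebeles"], "cluster")
    features = ac.features_from_kebeles(art["kebeles"], sl.CLUSTERING_VARIABLES)
    standardized = ac.standardize(features, config.scaling)
    assignment = ac.cluster_kebeles(standardized, k=config.k, linkage=config.linkage)
    art["assignment"] = assignment
    pd.Series(assignment.assignment, name="archetype").rename_axis("kebele_id").to_csv(
        out / "assignment.csv"
    )
    assignment.profiles.to_csv(out / "archetype_profiles.csv")


def _step_scenarios(config: RunConfig, art: dict, out: Path) -> None:
    _require(art, ["grid", "kebeles"], "scenarios")
    grid = art["grid"]
    if config.scenarios_path is not None:
        scenarios = se.read_scenarios(config.scenarios_path, grid.legend)
    else:
        landscape_ha = float(
            (grid.classes != grid.nodata).sum() * grid.cell_area_ha
        )
        scenarios = se.example_scenarios(grid.legend, landscape_ha=landscape_ha)
    kebele_ids = list(art["kebeles"]["kebele_id"])

    grids = {sl.BASELINE: grid}
    compositions = {sl.BASELINE: se.composition_by_zone(grid, kebele_ids)}
    reports = {}
    for scenario in scenarios:
        g, rep = se.apply_scenario(grid, scenario)
        grids[scenario.name] = g
        compositions[scenario.name] = se.composition_by_zone(g, kebele_ids)
        reports[scenario.name] = [vars(r) for r in rep]
    art["state_order"] = [sl.BASELINE] + [s.name for s in scenarios]
    art["grids"] = grids
    art["compositions"] = compositions

    # stakeholder counts follow the actual scenario names: configured shifts
    # apply where names match, otherwise a scenario keeps baseline counts
    art["stakeholder_counts"] = sl.generate_stakeholder_presence(
        sl.GeneratorConfig(seed=config.step_seed("simulate")), art["state_order"]
    )
    art["stakeholder_counts"].to_csv(out / "stakeholder_counts.csv")

    (out / "conversion_reports.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    for state, comp in compositions.items():
        comp.to_csv(out / f"composition_{state}.csv")


def _step_provision(config: RunConfig, art: dict, out: Path) -> None:
    _require(art, ["compositions", "kebeles", "models"], "provision")
    totals, percap, perarea = {}, {}, {}
    for state, comp in art["compositions"].items():
        t = esp.provision_totals(comp, art["kebeles"], art["models"], state=state)
        totals[state] = t
        percap[state] = esp.normalize(t, art["kebeles"], "per_capita")
        perarea[state] = esp.normalize(t, art["kebeles"], "per_area")
        t.values.to_csv(out / f"provision_total_{state}.csv")
        percap[state].values.to_csv(out / f"provision_per_capita_{state}.csv")
    art["totals"] = totals
    art["percap"] = percap
    art["perarea"] = perarea


def _step_socio(config: RunConfig, art: dict, out: Path) -> None:
    _require(art, ["totals", "percap", "kebeles", "weights", "stakeholder_counts"], "socio")
    adjusted = sv.adjusted_provision(art["totals"], art["kebeles"])
    specialization = {
        state: sv.simpson_specialization(adj, state) for state, adj in adjusted.items()
    }
    importance = sv.value_importance(art["percap"], art["weights"])
    proportions = sv.stakeholder_proportions(art["stakeholder_counts"])
    art["specialization"] = specialization
    art["importance"] = importance
    art["stakeholder_proportions"] = proportions

    pd.DataFrame(specialization).rename_axis("kebele_id").to_csv(out / "specialization.csv")
    proportions.to_csv(out / "stakeholder_proportions.csv")


def _step_report(config: RunConfig, art: dict, out: Path) -> None:
    _require(
        art,
        ["percap", "specialization", "importance", "assignment", "stakeholder_proportions"],
        "report",
    )
    state_order = art.get("state_order") or sorted(art["percap"])
    values = assemble_long_values(
        art["percap"], art["specialization"], art["importance"], state_order
    )
    levels, boundaries = lr.pooled_levels(values, n_bins=7, state_order=state_order)
    levels = lr.add_change_classes(levels, baseline_state=state_order[0], n_bins=7)

    sh_values = stakeholder_long_values(art["stakeholder_proportions"], state_order)
    sh_levels, _ = lr.pooled_levels(sh_values, n_bins=3, state_order=state_order)
    sh_levels = lr.add_change_classes(sh_levels, baseline_state=state_order[0], n_bins=3)

    cells = lr.unit_levels_to_cells(values, art["assignment"], boundaries)
    cells = lr.add_change_classes(cells, baseline_state=state_order[0], n_bins=7)

    es_names = [m.es_name for m in art["models"]] if "models" in art else list(
        art["percap"][state_order[0]].values.columns
    )
    summary_aspects = es_names + sl.VALUE_TYPES
    summary = lr.archetype_summary(cells, summary_aspects)

    art["levels"] = levels
    art["cells"] = cells
    art["summary"] = summary
    art["stakeholder_levels"] = sh_levels

    lr.export_report(
        out / "report",
        levels,
        cells,
        summary,
        state_order,
        grid=art.get("grid"),
        assignment=art["assignment"],
        stakeholder_levels=sh_levels,
    )


_STEP_FUNCS = {
    "simulate": _step_simulate,
    "cluster": _step_cluster,
    "scenarios": _step_scenarios,
    "provision": _step_provision,
    "socio": _step_socio,
    "report": _step_report,
}
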