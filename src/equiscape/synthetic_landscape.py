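"""Synthetic study-area generator with known ground truth.

Emulates the structure of a southwest-Ethiopian smallholder landscape: 66
kebeles (average 30 km^2, average population 4000) drawn from four
social-ecological archetype templates, a categorical LULC raster with about
half the landscape under moist Afromontane forest, nine social-ecological
clustering variables, eleven locally relevant ecosystem services, a
164-respondent plural-value survey and four organisational types of
stakeholders. Every downstream stage of the pipeline can therefore be tested
against a known archetype partition and known coefficients, without any
external data.

Spatial pattern inside each kebele comes from seeded-patch growth (random
seeds per class, region growing to the template's target areal fraction), so
proximity-based conversion rules act on contiguous patches rather than
salt-and-pepper noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape_io import LandscapeGrid, validate_kebele_table, warn_data

# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

#: the nine social-ecological clustering variables, all scaled to [0, 1]
CLUSTERING_VARIABLES = [
    "woody_vegetation_cover",
    "coffee_forest_availability",
    "khat_area",
    "arable_area",
    "pasture_area",
    "eucalyptus_area",
    "wealth_index",
    "accessibility",
    "honey_importance",
]

#: LULC codes for the default legend
DEFAULT_LEGEND = {
    1: "forest",
    2: "woody_vegetation",
    3: "cropland",
    4: "pasture",
    5: "khat",
    6: "eucalyptus",
    7: "plantation_coffee",
}

#: state names: baseline plus the four narrative scenarios
BASELINE = "baseline"
SCENARIO_NAMES = [
    "gain_over_grain",
    "coffee_conservation",
    "mining_green_gold",
    "food_first",
]
ALL_STATES = [BASELINE] + SCENARIO_NAMES

ORG_TYPES = ["GO", "PO", "CBO", "NGO"]
VALUE_TYPES = ["direct_use", "exchange", "relational", "intrinsic"]

ES_NAMES = [
    "beef",
    "biodiversity",
    "cattle",
    "firewood",
    "honey",
    "khat",
    "maize",
    "plantation_coffee",
    "semi_forest_coffee",
    "sorghum",
    "teff",
]

SURVEY_MAX_SCORE = 4  # ordinal 0..4 scale


# ---------------------------------------------------------------------------
# Config types
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeTemplate:
    """Blueprint of one social-ecological archetype.

    centroid: per-variable mean in [0, 1] for the nine clustering variables.
    lulc_mixture: expected areal fraction per LULC class name (sums to 1).
    n_kebeles: how many kebeles this archetype contributes.
    """

    name: str
    centroid: dict[str, float]
    lulc_mixture: dict[str, float]
    n_kebeles: int

    def __post_init__(self) -> None:
        if self.n_kebeles < 1:
            raise ValueError(f"template {self.name!r}: n_kebeles must be >= 1")
        if set(self.centroid) != set(CLUSTERING_VARIABLES):
            raise ValueError(
                f"template {self.name!r}: centroid must cover exactly the "
                f"nine clustering variables"
            )
        vals = np.array(list(self.centroid.values()))
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError(f"template {self.name!r}: centroid values must lie in [0,1]")
        fracs = np.array(list(self.lulc_mixture.values()))
        if np.any(fracs < 0):
            raise ValueError(f"template {self.name!r}: mixture fractions must be >= 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"template {self.name!r}: mixture fractions sum to {fracs.sum()}, not 1"
            )


def default_templates() -> list[ArchetypeTemplate]:
    """The four archetype templates: 12 accessible-wealthy, 19 khat-cropland,
    17 pasture-cropland and 18 woody-vegetation kebeles (66 total).

    Centroids encode the qualitative orderings of the archetypes: the
    khat-cropland archetype has the highest khat and the lowest wealth, the
    woody-vegetation archetype the highest woody cover, coffee-forest
    availability and honey importance while being the least accessible, the
    accessible-wealthy archetype the most eucalyptus, wealth and access, and
    the pasture-cropland archetype the most pasture and least woody cover.
    """
    return [
        ArchetypeTemplate(
            name="accessible_wealthy",
            n_kebeles=12,
            centroid={
                "woody_vegetation_cover": 0.35,
                "coffee_forest_availability": 0.45,
                "khat_area": 0.25,
                "arable_area": 0.40,
                "pasture_area": 0.30,
                "eucalyptus_area": 0.80,
                "wealth_index": 0.85,
                "accessibility": 0.85,
                "honey_importance": 0.30,
            },
            lulc_mixture={
                "forest": 0.45,
                "woody_vegetation": 0.10,
                "cropland": 0.15,
                "pasture": 0.08,
                "khat": 0.04,
                "eucalyptus": 0.15,
                "plantation_coffee": 0.03,
            },
        ),
        ArchetypeTemplate(
            name="khat_cropland",
            n_kebeles=19,
            centroid={
                "woody_vegetation_cover": 0.30,
                "coffee_forest_availability": 0.15,
                "khat_area": 0.85,
                "arable_area": 0.80,
                "pasture_area": 0.35,
                "eucalyptus_area": 0.20,
                "wealth_index": 0.15,
                "accessibility": 0.45,
                "honey_importance": 0.20,
            },
            lulc_mixture={
                "forest": 0.40,
                "woody_vegetation": 0.08,
                "cropland": 0.27,
                "pasture": 0.08,
                "khat": 0.13,
                "eucalyptus": 0.02,
                "plantation_coffee": 0.02,
            },
        ),
        ArchetypeTemplate(
            name="pasture_cropland",
            n_kebeles=17,
            centroid={
                "woody_vegetation_cover": 0.10,
                "coffee_forest_availability": 0.20,
                "khat_area": 0.20,
                "arable_area": 0.75,
                "pasture_area": 0.85,
                "eucalyptus_area": 0.15,
                "wealth_index": 0.40,
                "accessibility": 0.55,
                "honey_importance": 0.25,
            },
            lulc_mixture={
                "forest": 0.45,
                "woody_vegetation": 0.04,
                "cropland": 0.26,
                "pasture": 0.18,
                "khat": 0.03,
                "eucalyptus": 0.02,
                "plantation_coffee": 0.02,
            },
        ),
        ArchetypeTemplate(
            name="woody_vegetation",
            n_kebeles=18,
            centroid={
                "woody_vegetation_cover": 0.85,
                "coffee_forest_availability": 0.85,
                "khat_area": 0.15,
                "arable_area": 0.30,
                "pasture_area": 0.20,
                "eucalyptus_area": 0.20,
                "wealth_index": 0.45,
                "accessibility": 0.20,
                "honey_importance": 0.85,
            },
            lulc_mixture={
                "forest": 0.62,
                "woody_vegetation": 0.20,
                "cropland": 0.08,
                "pasture": 0.04,
                "khat": 0.01,
                "eucalyptus": 0.02,
                "plantation_coffee": 0.03,
            },
        ),
    ]


@dataclass
class GeneratorConfig:
    """Study-area generation settings.

    noise_sd is the per-variable Gaussian noise standard deviation expressed
    as a fraction of the variable range (all variables live on [0, 1]).
    Areas and populations are log-normal with the configured means and
    log-scale sigma 0.35, a typical dispersion for administrative units.
    """

    templates: list[ArchetypeTemplate] = field(default_factory=default_templates)
    mean_area_km2: float = 30.0
    mean_population: float = 4000.0
    noise_sd: float = 0.05
    grid_cell_m: float = 100.0
    n_respondents: int = 164
    seed: int = 0
    area_log_sigma: float = 0.35
    population_log_sigma: float = 0.35

    def __post_init__(self) -> None:
        if len(self.templates) < 2:
            raise ValueError("need at least 2 archetype templates")
        if self.total_kebeles < len(self.templates):
            raise ValueError("total kebele count must be >= number of templates")
        if not (0 <= self.noise_sd < 0.5):
            raise ValueError("noise_sd must lie in [0, 0.5)")
        for val, name in [
            (self.mean_area_km2, "mean_area_km2"),
            (self.mean_population, "mean_population"),
            (self.grid_cell_m, "grid_cell_m"),
            (self.n_respondents, "n_respondents"),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_kebeles(self) -> int:
        return sum(t.n_kebeles for t in self.templates)


@dataclass
class SyntheticStudyArea:
    """Ground-truth bundle: tables, raster, coefficients and survey data."""

    kebeles: pd.DataFrame
    grid: LandscapeGrid
    truth_assignment: dict[str, str]
    es_models: list
    value_weights: pd.DataFrame
    value_survey: np.ndarray
    stakeholders: pd.DataFrame


# ---------------------------------------------------------------------------
# Kebele tables and features
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=n)


def _kebele_ids(n: int) -> list[str]:
    return [f"K{i + 1:02d}" for i in range(n)]


def generate_kebele_table(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw the kebele table (demographics + nine social variables) and the
    ground-truth archetype assignment."""
    n = config.total_kebeles
    ids = _kebele_ids(n)
    truth: dict[str, str] = {}
    centroids = []
    for template in config.templates:
        for _ in range(template.n_kebeles):
            truth[ids[len(centroids)]] = template.name
            centroids.append([template.centroid[v] for v in CLUSTERING_VARIABLES])
    centroids = np.array(centroids)

    noise = rng.normal(0.0, config.noise_sd, size=centroids.shape)
    variables = np.clip(centroids + noise, 0.0, 1.0)

    areas = _lognormal(rng, config.mean_area_km2, config.area_log_sigma, n)
    pops = np.maximum(
        1, np.round(_lognormal(rng, config.mean_population, config.population_log_sigma, n))
    ).astype(int)
    woredas = [f"W{(i % 3) + 1}" for i in range(n)]

    table = pd.DataFrame(
        {
            "kebele_id": ids,
            "woreda": woredas,
            "area_km2": areas,
            "population": pops,
        }
    )
    for j, var in enumerate(CLUSTERING_VARIABLES):
        table[var] = variables[:, j]
    return validate_kebele_table(table), truth


# ---------------------------------------------------------------------------
# Raster generation (seeded-patch growth)
# ---------------------------------------------------------------------------

def _class_quotas(mixture: dict[str, float], n_cells: int, code_of: dict[str, int]) -> dict[int, int]:
    """Largest-remainder apportionment of n_cells to classes by mixture."""
    names = list(mixture)
    exact = np.array([mixture[m] for m in names]) * n_cells
    floors = np.floor(exact).astype(int)
    remainder = n_cells - floors.sum()
    order = np.argsort(-(exact - floors), kind="stable")
    for idx in order[:remainder]:
        floors[idx] += 1
    return {code_of[names[i]]: int(floors[i]) for i in range(len(names)) if floors[i] > 0}


def _grow_patches(
    cell_index: dict[tuple[int, int], int],
    cells: list[tuple[int, int]],
    quotas: dict[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill a kebele's cells with contiguous class patches matching quotas.

    One random seed per class, then stochastic region growing: at each step a
    class still under quota is chosen with probability proportional to its
    remaining quota and claims a random unassigned frontier cell; if a class
    runs out of frontier it is re-seeded at a random unassigned cell. Quotas
    are met exactly.
    """
    n = len(cells)
    assigned = np.full(n, -1, dtype=np.int64)
    remaining = dict(quotas)
    codes = list(remaining)
    frontiers: dict[int, list[int]] = {c: [] for c in codes}
    unassigned = set(range(n))

    def neighbors(i: int):
        r, c = cells[i]
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            j = cell_index.get((rr, cc))
            if j is not None:
                yield j

    def claim(code: int, i: int) -> None:
        assigned[i] = code
        unassigned.discard(i)
        remaining[code] -= 1
        for j in neighbors(i):
            if assigned[j] == -1:
                frontiers[code].append(j)

    # initial seeds
    seed_cells = rng.choice(n, size=len(codes), replace=False)
    for code, i in zip(codes, seed_cells):
        if remaining[code] > 0:
            claim(code, int(i))

    active = [c for c in codes if remaining[c] > 0]
    while active:
        weights = np.array([remaining[c] for c in active], dtype=float)
        code = active[int(rng.choice(len(active), p=weights / weights.sum()))]
        frontier = frontiers[code]
        i = -1
        while frontier:
            # pop a random frontier cell
            k = int(rng.integers(len(frontier)))
            frontier[k], frontier[-1] = frontier[-1], frontier[k]
            cand = frontier.pop()
            if assigned[cand] == -1:
                i = cand
                break
        if i == -1:
            # enclosed patch: re-seed in unassigned territory
            pool = sorted(unassigned)
            i = pool[int(rng.integers(len(pool)))]
        claim(code, i)
        if remaining[code] == 0:
            active.remove(code)
    return assigned


def generate_grid(
    config: GeneratorConfig,
    kebeles: pd.DataFrame,
    truth: dict[str, str],
    rng: np.random.Generator,
    legend: dict[int, str] | None = None,
) -> LandscapeGrid:
    """Rasterize the study area: boustrophedon zone strips sized by kebele
    area, then per-kebele seeded-patch growth of LULC classes."""
    legend = dict(legend or DEFAULT_LEGEND)
    code_of = {name: code for code, name in legend.items()}
    templates = {t.name: t for t in config.templates}

    cell_km2 = (config.grid_cell_m / 1000.0) ** 2
    counts = np.maximum(1, np.round(kebeles["area_km2"].to_numpy() / cell_km2)).astype(int)
    total = int(counts.sum())
    ncol = int(math.ceil(math.sqrt(total)))
    nrow = int(math.ceil(total / ncol))

    nodata = -1
    zones = np.full((nrow, ncol), nodata, dtype=np.int32)
    classes = np.full((nrow, ncol), nodata, dtype=np.int32)

    # snake-order linear index -> (row, col): contiguous zone strips
    order = []
    for r in range(nrow):
        cols = range(ncol) if r % 2 == 0 else range(ncol - 1, -1, -1)
        order.extend((r, c) for c in cols)

    zone_legend: dict[int, str] = {}
    pos = 0
    for k, (kebele_id, n_cells) in enumerate(zip(kebeles["kebele_id"], counts)):
        zone_code = k + 1
        zone_legend[zone_code] = kebele_id
        cells = order[pos : pos + n_cells]
        pos += n_cells
        for r, c in cells:
            zones[r, c] = zone_code
        cell_index = {rc: i for i, rc in enumerate(cells)}
        quotas = _class_quotas(
            templates[truth[kebele_id]].lulc_mixture, n_cells, code_of
        )
        filled = _grow_patches(cell_index, cells, quotas, rng)
        for i, (r, c) in enumerate(cells):
            classes[r, c] = filled[i]

    return LandscapeGrid(
        classes=classes,
        zones=zones,
        cell_size_m=config.grid_cell_m,
        legend=legend,
        zone_legend=zone_legend,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Value survey
# ---------------------------------------------------------------------------

def default_value_modes(es_names: list[str]) -> pd.DataFrame:
    """Modal survey scores (0..4) per (ES, value type).

    Provisioning crops score high on direct use and exchange; forest-linked
    services (honey, semi-forest coffee, firewood) carry relational value;
    biodiversity is valued mostly intrinsically.
    """
    base = {
        "beef": (3, 3, 1, 1),
        "biodiversity": (1, 0, 2, 4),
        "cattle": (4, 3, 2, 1),
        "firewood": (4, 2, 2, 1),
        "honey": (3, 3, 4, 2),
        "khat": (2, 4, 1, 0),
        "maize": (4, 2, 1, 1),
        "plantation_coffee": (2, 4, 2, 1),
        "semi_forest_coffee": (3, 4, 4, 2),
        "sorghum": (4, 2, 1, 1),
        "teff": (4, 3, 1, 1),
    }
    rows = {}
    for es in es_names:
        rows[es] = base.get(es, (2, 2, 2, 2))
    return pd.DataFrame.from_dict(rows, orient="index", columns=VALUE_TYPES)


def generate_value_survey(
    config: GeneratorConfig,
    es_names: list[str],
    modes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate the plural-value survey and aggregate it to weights.

    Returns (scores, weights): scores is an integer array of shape
    (n_respondents, n_ES, 4) on the 0..4 scale drawn Binomial(4, mode/4)
    around the ES-specific modes; weights is the ES x value-type matrix of
    mean score / max score, each entry in [0, 1].
    """
    if not es_names:
        raise ValueError("es_names must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if modes is None:
        modes = default_value_modes(es_names)
    modes = modes.loc[es_names, VALUE_TYPES]
    p = modes.to_numpy(dtype=float) / SURVEY_MAX_SCORE
    scores = rng.binomial(
        SURVEY_MAX_SCORE, p[None, :, :], size=(config.n_respondents, len(es_names), len(VALUE_TYPES))
    ).astype(np.int64)
    weights = pd.DataFrame(
        scores.mean(axis=0) / SURVEY_MAX_SCORE, index=list(es_names), columns=VALUE_TYPES
    )
    weights.index.name = "es_name"
    return scores, weights


# ---------------------------------------------------------------------------
# Stakeholder presence
# ---------------------------------------------------------------------------

#: baseline org counts: government-dominated governance
DEFAULT_BASELINE_ORG_COUNTS = {"GO": 18, "PO": 6, "CBO": 10, "NGO": 6}

#: multiplicative count shifts per scenario: private orgs expand under the
#: two extraction/intensification-leaning cash economies, community-based and
#: non-governmental orgs under the conservation-leaning futures
DEFAULT_ORG_SHIFTS: dict[str, dict[str, float]] = {
    "gain_over_grain": {"PO": 0.8, "CBO": -0.2},
    "coffee_conservation": {"CBO": 0.5, "NGO": 0.6},
    "mining_green_gold": {"PO": 1.2, "CBO": -0.3, "NGO": -0.2},
    "food_first": {"GO": 0.2, "CBO": 0.3, "NGO": 0.4},
}


def generate_stakeholder_presence(
    config: GeneratorConfig,
    states: list[str],
    baseline_counts: dict[str, int] | None = None,
    shifts: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Stakeholder counts per state for the four org types GO/PO/CBO/NGO.

    Scenario counts are the baseline counts scaled by the configured relative
    shifts and rounded (minimum 0). Deterministic given the config.
    """
    if BASELINE not in states:
        raise ValueError("states must include 'baseline'")
    counts = dict(baseline_counts or DEFAULT_BASELINE_ORG_COUNTS)
    unknown = sorted(set(counts) - set(ORG_TYPES))
    if unknown:
        raise ValueError(f"unknown org types in baseline counts: {unknown}")
    shifts = shifts if shifts is not None else DEFAULT_ORG_SHIFTS
    for state, shift in shifts.items():
        unknown = sorted(set(shift) - set(ORG_TYPES))
        if unknown:
            raise ValueError(f"unknown org types in shifts[{state!r}]: {unknown}")

    rows = []
    for state in states:
        shift = shifts.get(state, {}) if state != BASELINE else {}
        row = {"state": state}
        for org in ORG_TYPES:
            base = counts.get(org, 0)
            row[org] = max(0, int(round(base * (1.0 + shift.get(org, 0.0)))))
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# Full study area
# ---------------------------------------------------------------------------

def generate_study_area(config: GeneratorConfig) -> SyntheticStudyArea:
    """Generate the complete synthetic study area; deterministic per seed."""
    from .es_provision import default_models

    rng = np.random.default_rng(config.seed)
    kebeles, truth = generate_kebele_table(config, rng)
    grid = generate_grid(config, kebeles, truth, rng)
    scores, weights = generate_value_survey(config, ES_NAMES, rng=rng)
    stakeholders = generate_stakeholder_presence(config, ALL_STATES)
    return SyntheticStudyArea(
        kebeles=kebeles,
        grid=grid,
        truth_assignment=truth,
        es_models=default_models(),
        value_weights=weights,
        value_survey=scores,
        stakeholders=stakeholders,
    )
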