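"""Potential ecosystem-service provision per kebele from LULC composition.

Eleven locally relevant ES (beef, biodiversity, cattle, firewood, honey,
khat, maize, plantation coffee, semi-forest coffee, sorghum, teff) are
modeled with a linear predictor over the kebele's class areas and social
covariates, floored at zero:

    total(k, s) = max(0, a_s + sum_c b_{s,c} area(k, c) + sum_j g_{s,j} x_{k,j})

Coefficients are supplied (or simulated) — fitting to field data is out of
scope. Totals can be normalized per capita (the appropriation perspective)
or per km^2 (the landscape perspective) and averaged over archetypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .archetype_clustering import ArchetypeAssignment
from .landscape_io import warn_data

logger = logging.getLogger(__name__)

VIEWS = ("total", "per_capita", "per_area")

STUDY_AREA = "study_area"


@dataclass
class ESModelSpec:
    """Linear provision model for one ES.

    class_coefs are ES units per hectare of a LULC class; covariate_coefs
    weight the kebele's social variables.
    """

    es_name: str
    intercept: float = 0.0
    class_coefs: dict[str, float] = field(default_factory=dict)
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    unit: str = ""


@dataclass
class ProvisionTable:
    """Kebele x ES matrix under one view (total / per_capita / per_area)."""

    values: pd.DataFrame
    view: str
    state: str

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")


def default_models() -> list[ESModelSpec]:
    """Shipped provision models for the 11 default ES.

    Signs follow the obvious land-use couplings: cereals load on cropland
    only, livestock on pasture, woody-linked services (firewood, honey,
    semi-forest coffee, biodiversity) on forest and woody vegetation, khat
    and plantation coffee on their own classes. Honey and semi-forest coffee
    carry small positive social covariates (importance of honey production,
    coffee-forest availability) per 10^3 units.
    """
    return [
        ESModelSpec("beef", 0.0, {"pasture": 0.045}, {}, "t/yr"),
        ESModelSpec(
            "biodiversity", 0.0, {"forest": 1.0, "woody_vegetation": 0.6}, {}, "index"
        ),
        ESModelSpec("cattle", 0.0, {"pasture": 0.5, "woody_vegetation": 0.1}, {}, "head"),
        ESModelSpec(
            "firewood", 0.0, {"woody_vegetation": 1.2, "forest": 0.5, "eucalyptus": 2.0},
            {}, "m3/yr",
        ),
        ESModelSpec(
            "honey", 0.0, {"forest": 0.08, "woody_vegetation": 0.05},
            {"honey_importance": 120.0}, "kg/yr",
        ),
        ESModelSpec("khat", 0.0, {"khat": 0.9}, {}, "t/yr"),
        ESModelSpec("maize", 0.0, {"cropland": 0.6}, {}, "t/yr"),
        ESModelSpec("plantation_coffee", 0.0, {"plantation_coffee": 0.7}, {}, "t/yr"),
        ESModelSpec(
            "semi_forest_coffee", 0.0, {"forest": 0.12},
            {"coffee_forest_availability": 150.0}, "t/yr",
        ),
        ESModelSpec("sorghum", 0.0, {"cropland": 0.5}, {}, "t/yr"),
        ESModelSpec("teff", 0.0, {"cropland": 0.4}, {}, "t/yr"),
    ]


def provision_totals(
    composition: pd.DataFrame,
    kebeles: pd.DataFrame,
    models: list[ESModelSpec],
    state: str = "baseline",
) -> ProvisionTable:
    """Total potential provision per kebele for every modeled ES.

    composition: kebele_id-indexed class-area table in hectares. A class a
    model references but the composition lacks counts as zero area (with a
    warning); a covariate missing from the kebele table is an error.
    Negative linear predictors floor at zero and are logged.
    """
    keb = kebeles.set_index("kebele_id")
    comp = composition.reindex(keb.index)

    names = [m.es_name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate es_name in model set")

    out = pd.DataFrame(index=keb.index, columns=names, dtype=float)
    for model in models:
        pred = pd.Series(model.intercept, index=keb.index, dtype=float)
        for cls, beta in model.class_coefs.items():
            if cls not in comp.columns:
                warn_data(
                    f"model {model.es_name!r}: class {cls!r} absent from "
                    f"composition; treated as 0 area"
                )
                continue
            pred += beta * comp[cls].fillna(0.0)
        for cov, gamma in model.covariate_coefs.items():
            if cov not in keb.columns:
                raise ValueError(
                    f"model {model.es_name!r} references unknown covariate {cov!r}"
                )
            pred += gamma * keb[cov].astype(float)
        floored = pred < 0
        if floored.any():
            logger.info(
                "floored %d negative predictions for %s at 0 (kebeles: %s)",
                int(floored.sum()), model.es_name, list(keb.index[floored]),
            )
        out[model.es_name] = pred.clip(lower=0.0)
    out.index.name = "kebele_id"
    return ProvisionTable(values=out, view="total", state=state)


def normalize(table: ProvisionTable, kebeles: pd.DataFrame, view: str) -> ProvisionTable:
    """Per-capita (divide by population) or per-area (divide by km^2) view."""
    if table.view != "total":
        raise ValueError("normalize expects a table in the 'total' view")
    if view not in ("per_capita", "per_area"):
        raise ValueError("view must be 'per_capita' or 'per_area'")
    keb = kebeles.set_index("kebele_id").reindex(table.values.index)
    if view == "per_capita":
        if (keb["population"] < 1).any():
            raise ValueError("population must be >= 1 for per-capita view")
        denom = keb["population"].astype(float)
    else:
        if (keb["area_km2"] <= 0).any():
            raise ValueError("area_km2 must be > 0 for per-area view")
        denom = keb["area_km2"].astype(float)
    return ProvisionTable(
        values=table.values.div(denom, axis=0), view=view, state=table.state
    )


def aggregate_means(
    table: ProvisionTable, assignment: ArchetypeAssignment
) -> pd.DataFrame:
    """Unweighted mean provision over member kebeles per archetype, plus a
    study-area row (mean over all kebeles, not over archetype means)."""
    units = list(table.values.index)
    missing = [u for u in units if u not in assignment.assignment]
    if missing:
        raise ValueError(f"assignment does not cover units: {missing}")
    labels = [assignment.assignment[u] for u in units]
    grouped = table.values.assign(_label=labels).groupby("_label").mean()
    present = set(grouped.index)
    empty = [lab for lab in assignment.labels if lab not in present]
    if empty:
        raise ValueError(f"empty archetypes: {empty}")
    grouped.loc[STUDY_AREA] = table.values.mean(axis=0)
    grouped.index.name = "aggregate"
    return grouped
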