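"""Socioeconomic readings of ES provision: specialization, plural values,
stakeholder presence.

Specialization is Simpson concentration: with a kebele's adjusted provision
shares p_s over ES, lambda = sum_s p_s^2, which is 1 when provision sits in
a single ES and 1/n_ES when spread uniformly. "Adjusted" provision is the
per-area density, log(1+x)-transformed and min-max scaled per ES over the
POOLED baseline-plus-scenario values, so scenario scores stay on the
baseline's scale. Value importance weights per-capita provision (same
pooled scaling) by the survey-derived weights of the four value types
(direct use, exchange, relational, intrinsic), reusing baseline weights for
all scenarios. Stakeholder presence is a study-area-level proportion table
over the four org types.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .es_provision import ProvisionTable
from .landscape_io import warn_data
from .synthetic_landscape import BASELINE, ORG_TYPES, VALUE_TYPES


# ---------------------------------------------------------------------------
# Pooled scaling helpers
# ---------------------------------------------------------------------------

def _pooled_minmax(frames: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Min-max scale each ES column using min/max pooled over all states.

    A column constant across the pool (notably all-zero) scales to 0
    everywhere, with a warning.
    """
    pool = pd.concat(frames.values(), axis=0)
    lo, hi = pool.min(axis=0), pool.max(axis=0)
    span = hi - lo
    flat = span[span == 0].index.tolist()
    if flat:
        warn_data(f"ES with constant pooled values scaled to 0: {flat}")
    out = {}
    for state, df in frames.items():
        scaled = (df - lo) / span.replace(0, np.nan)
        out[state] = scaled.fillna(0.0)
    return out


def _require_states(tables: Mapping[str, ProvisionTable], view: str) -> None:
    if BASELINE not in tables:
        raise ValueError(f"tables must include the {BASELINE!r} state")
    for state, table in tables.items():
        if table.view != view:
            raise ValueError(
                f"state {state!r}: expected view {view!r}, got {table.view!r}"
            )


# ---------------------------------------------------------------------------
# Adjusted provision and Simpson specialization
# ---------------------------------------------------------------------------

def adjusted_provision(
    totals: Mapping[str, ProvisionTable], kebeles: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Adjusted provision per state: per-area density, log1p, pooled min-max.

    Input tables must be in the 'total' view and include the baseline; the
    min-max runs per ES over the pooled kebele values of every state so
    states are commensurable. All entries land in [0, 1].
    """
    _require_states(totals, "total")
    area = kebeles.set_index("kebele_id")["area_km2"].astype(float)
    transformed = {}
    for state, table in totals.items():
        density = table.values.div(area.reindex(table.values.index), axis=0)
        transformed[state] = np.log1p(density)
    return _pooled_minmax(transformed)


def simpson_specialization(adjusted: pd.DataFrame, state: str = BASELINE) -> pd.Series:
    """Simpson concentration lambda = sum_s p_s^2 per kebele.

    p are the kebele's adjusted-provision shares, so any non-negative
    profile is accepted and the score is invariant to row scaling. A kebele
    with all-zero adjusted provision gets NaN (flagged, excluded from binning) with a
    warning rather than a silent 0.
    """
    if (adjusted < -1e-12).any().any():
        raise ValueError("adjusted provision must be non-negative")
    totals = adjusted.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warn_data(
            f"kebeles with all-zero adjusted provision (specialization "
            f"undefined): {list(adjusted.index[zero])}"
        )
    shares = adjusted.div(totals.replace(0, np.nan), axis=0)
    out = (shares**2).sum(axis=1, min_count=1)
    out.name = "specialization"
    out.attrs["state"] = state
    return out


# ---------------------------------------------------------------------------
# Value importance
# ---------------------------------------------------------------------------

def value_importance(
    percap: Mapping[str, ProvisionTable], weights: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Importance of the four value types per kebele and state.

    importance(k, v) = sum_s w(s, v) * m(k, s) with m the per-capita
    provision min-max scaled per ES over the pooled states, and w the
    baseline-elicited value-type weight of ES s. Weights must cover every
    ES present in the provision tables.
    """
    _require_states(percap, "per_capita")
    if list(weights.columns) != VALUE_TYPES:
        raise ValueError(f"weights must have exactly the columns {VALUE_TYPES}")
    if ((weights < 0) | (weights > 1)).any().any():
        raise ValueError("value weights must lie in [0, 1]")
    es_names = list(next(iter(percap.values())).values.columns)
    missing = [s for s in es_names if s not in weights.index]
    if missing:
        raise ValueError(f"ES missing from value weights: {missing}")

    scaled = _pooled_minmax({s: t.values for s, t in percap.items()})
    w = weights.loc[es_names, VALUE_TYPES].to_numpy(dtype=float)
    out = {}
    for state, m in scaled.items():
        imp = m.to_numpy(dtype=float) @ w
        out[state] = pd.DataFrame(imp, index=m.index, columns=VALUE_TYPES)
    return out


# ---------------------------------------------------------------------------
# Stakeholder presence
# ---------------------------------------------------------------------------

def stakeholder_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-state proportions of the four org types from raw counts.

    counts: state-indexed table with GO/PO/CBO/NGO columns, entries >= 0 and
    a positive total per state. Proportions sum to 1 per state. Retained at
    study-area level only.
    """
    missing = [o for o in ORG_TYPES if o not in counts.columns]
    if missing:
        raise ValueError(f"missing org-type columns: {missing}")
    unknown = [c for c in counts.columns if c not in ORG_TYPES]
    if unknown:
        raise ValueError(f"unknown org types: {unknown}")
    vals = counts[ORG_TYPES].astype(float)
    if (vals < 0).any().any():
        raise ValueError("stakeholder counts must be >= 0")
    totals = vals.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"states with all-zero stakeholder counts: {zero}")
    return vals.div(totals, axis=0)
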