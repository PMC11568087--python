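"""Hierarchical clustering of kebeles into social-ecological archetypes.

Kebeles are clustered on a standardized feature matrix (nine social and
ecological variables by default) with agglomerative Ward linkage on
Euclidean distances. The agglomeration is implemented directly (O(n^3)
Lance-Williams updates — negligible at administrative-unit counts) so the
tie-break is fully specified: at equal linkage distance the pair with the
lexicographically smallest cluster-id pair merges first, which makes the
dendrogram reproducible across platforms and input permutations of equal
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape_io import warn_data

SCALINGS = ("minmax", "zscore", "none")
LINKAGES = ("ward", "average", "single", "complete")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(matrix: pd.DataFrame, method: str = "minmax") -> pd.DataFrame:
    """Column-wise standardization of a units x variables feature matrix.

    minmax maps each column onto [0, 1]; a constant column is mapped to 0.5
    with a warning (it carries no clustering information but keeps the
    matrix shape). zscore centers and scales to unit sd (constant columns
    map to 0.0 with a warning).
    """
    if method not in SCALINGS:
        raise ValueError(f"unknown scaling {method!r}; expected one of {SCALINGS}")
    if len(matrix) < 2:
        raise ValueError("need at least 2 units to standardize")
    if matrix.isna().any().any():
        bad = [
            (str(matrix.index[i]), str(matrix.columns[j]))
            for i, j in zip(*np.where(matrix.isna().to_numpy()))
        ]
        raise ValueError(f"missing values at cells: {bad}")
    if method == "none":
        return matrix.copy()

    out = matrix.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy()
        if method == "minmax":
            lo, hi = x.min(), x.max()
            if hi == lo:
                warn_data(f"constant column {col!r} mapped to 0.5 under minmax scaling")
                out[col] = 0.5
            else:
                out[col] = (x - lo) / (hi - lo)
        else:  # zscore
            mu, sd = x.mean(), x.std(ddof=0)
            if sd == 0:
                warn_data(f"constant column {col!r} mapped to 0.0 under zscore scaling")
                out[col] = 0.0
            else:
                out[col] = (x - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Agglomeration
# ---------------------------------------------------------------------------

def linkage_matrix(values: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative linkage in scipy's (n-1) x 4 encoding.

    Each row is (id_a, id_b, distance, new_cluster_size) with id_a < id_b;
    original observations are clusters 0..n-1 and the cluster formed at step
    t gets id n+t. Merges are greedy by minimum linkage distance; exact
    distance ties break on the lexicographically smallest (id_a, id_b).

    Ward distances follow the scipy convention: the distance between
    singletons is their Euclidean distance and merged distances follow the
    Lance-Williams update on squared distances.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    X = np.asarray(values, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")

    # squared pairwise distances between active clusters, keyed by cluster id
    diff = X[:, None, :] - X[None, :, :]
    d2 = {(i, j): float(np.sum(diff[i, j] ** 2)) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (a, b) if a < b else (b, a)
                dist = d2[key]
                if best is None or dist < best[0] or (dist == best[0] and key < best[1]):
                    best = (dist, key)
        dist2, (a, b) = best
        new_id = n + step
        na, nb = sizes[a], sizes[b]
        merges[step] = (a, b, np.sqrt(dist2), na + nb)

        # Lance-Williams update against every other active cluster
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            if linkage == "ward":
                new = ((na + nc) * dac + (nb + nc) * dbc - nc * dist2) / (na + nb + nc)
            elif linkage == "average":
                # the average-linkage update acts on distances, not squares
                new = ((na * np.sqrt(dac) + nb * np.sqrt(dbc)) / (na + nb)) ** 2
            elif linkage == "single":
                new = min(dac, dbc)
            else:  # complete
                new = max(dac, dbc)
            d2[(min(new_id, c), max(new_id, c))] = new

        active.remove(a)
        active.remove(b)
        active.append(new_id)
        sizes[new_id] = na + nb
    return merges


def cut_linkage(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Flat cluster membership (arbitrary integer labels) after cutting the
    linkage at k clusters: perform the first n-k merges."""
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    members = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        members[n + step] = members.pop(a) + members.pop(b)
    labels = np.empty(n, dtype=int)
    for gid, (cid, obs) in enumerate(sorted(members.items())):
        labels[obs] = gid
    return labels


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeAssignment:
    """Partition of kebeles into archetypes plus per-archetype profiles."""

    assignment: dict[str, str]
    k: int
    linkage: str
    profiles: pd.DataFrame

    def members(self, label: str) -> list[str]:
        return [u for u, lab in self.assignment.items() if lab == label]

    @property
    def labels(self) -> list[str]:
        return list(self.profiles.index)


def cluster_kebeles(
    matrix: pd.DataFrame,
    k: int = 4,
    linkage: str = "ward",
) -> ArchetypeAssignment:
    """Cluster a standardized units x variables matrix into k archetypes.

    Labels are `archetype_1` ... `archetype_k`, numbered by descending
    cluster size (ties broken by the smallest member unit id), and profiles
    are the per-archetype means of the input matrix.
    """
    n = len(matrix)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_units-1={n - 1}")

    merges = linkage_matrix(matrix.to_numpy(dtype=float), linkage=linkage)
    raw = cut_linkage(merges, n, k)
    units = [str(u) for u in matrix.index]

    groups: dict[int, list[int]] = {}
    for i, g in enumerate(raw):
        groups.setdefault(int(g), []).append(i)
    ordered = sorted(
        groups.values(), key=lambda obs: (-len(obs), units[min(obs)])
    )
    assignment: dict[str, str] = {}
    for rank, obs in enumerate(ordered, start=1):
        for i in obs:
            assignment[units[i]] = f"archetype_{rank}"

    profiles = (
        matrix.assign(_label=[assignment[u] for u in units])
        .groupby("_label")
        .mean()
        .rename_axis("archetype")
    )
    return ArchetypeAssignment(assignment=assignment, k=k, linkage=linkage, profiles=profiles)


def profile_archetypes(
    assignment: ArchetypeAssignment, raw_matrix: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-archetype means of the raw (unscaled) variables plus naming
    suggestions: for each archetype, the variables on which it attains the
    maximum or minimum mean across archetypes."""
    units = [str(u) for u in raw_matrix.index]
    missing = [u for u in units if u not in assignment.assignment]
    if missing:
        raise ValueError(f"assignment does not cover units: {missing}")
    labels = [assignment.assignment[u] for u in units]
    profiles = (
        raw_matrix.assign(_label=labels).groupby("_label").mean().rename_axis("archetype")
    )
    if len(profiles) < assignment.k:
        raise ValueError("empty archetype in assignment")

    suggestions: dict[str, list[str]] = {lab: [] for lab in profiles.index}
    for var in profiles.columns:
        col = profiles[var]
        suggestions[col.idxmax()].append(f"high {var}")
        suggestions[col.idxmin()].append(f"low {var}")
    return profiles, suggestions


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand Index between two partitions (chance-corrected)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def features_from_kebeles(kebeles: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Extract the clustering feature matrix (kebele_id index) from a kebele table."""
    from .landscape_io import social_variable_names

    variables = variables or social_variable_names(kebeles)
    return kebeles.set_index("kebele_id")[variables].astype(float)
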