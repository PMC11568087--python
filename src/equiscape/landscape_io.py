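"""Readers and writers for the on-disk formats touched by the pipeline.

Rasters are single-band integer TIFFs (nodata declared via the GDAL_NODATA
tag) with CSV sidecars for the class legend and the zone legend and a JSON
sidecar for the cell size. Tables are UTF-8 CSV with '.' decimal. Reporting
geometries are GeoJSON derived from the zone raster.

Coordinates are row/col, 0-based, row 0 at north; areas come from cell
counts x cell_size^2. No CRS handling is performed — computation is purely
zonal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

GDAL_NODATA_TAG = 42113

#: columns every kebele table must provide; remaining columns are social variables
KEBELE_REQUIRED_COLUMNS = ("kebele_id", "woreda", "area_km2", "population")


# ---------------------------------------------------------------------------
# LandscapeGrid
# ---------------------------------------------------------------------------

@dataclass
class LandscapeGrid:
    """Categorical LULC raster plus a zone raster mapping cells to kebeles.

    Parameters
    ----------
    classes : 2-D integer array of LULC codes.
    zones : 2-D integer array of zone codes, same shape as ``classes``.
    cell_size_m : edge length of a cell in meters.
    legend : mapping LULC code -> class name; must cover all non-nodata codes.
    zone_legend : mapping zone code -> kebele id.
    nodata : integer code marking cells outside the study area.
    """

    classes: np.ndarray
    zones: np.ndarray
    cell_size_m: float
    legend: dict[int, str]
    zone_legend: dict[int, str] = field(default_factory=dict)
    nodata: int = -1

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int32)
        self.zones = np.asarray(self.zones, dtype=np.int32)
        self.validate()

    def validate(self) -> None:
        if self.classes.shape != self.zones.shape:
            raise ValueError(
                f"class raster shape {self.classes.shape} does not match "
                f"zone raster shape {self.zones.shape}"
            )
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        present = set(np.unique(self.classes).tolist()) - {self.nodata}
        unknown = sorted(present - set(self.legend))
        if unknown:
            raise ValueError(f"class codes without legend entry: {unknown}")
        valid = self.classes != self.nodata
        if np.any(self.zones[valid] == self.nodata):
            raise ValueError("every non-nodata class cell must have a non-nodata zone")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 1e4

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            classes=self.classes.copy(),
            zones=self.zones.copy(),
            cell_size_m=self.cell_size_m,
            legend=dict(self.legend),
            zone_legend=dict(self.zone_legend),
            nodata=self.nodata,
        )


def _write_band(path: Path, band: np.ndarray, nodata: int) -> None:
    tifffile.imwrite(
        path,
        band.astype(np.int32),
        extratags=[(GDAL_NODATA_TAG, "s", 0, str(nodata), False)],
    )


def _read_band(path: Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.int32)


def write_grid(grid: LandscapeGrid, directory: str | Path) -> Path:
    """Write a grid as lulc.tif + zones.tif + legend sidecars into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_band(directory / "lulc.tif", grid.classes, grid.nodata)
    _write_band(directory / "zones.tif", grid.zones, grid.nodata)
    pd.DataFrame(
        sorted(grid.legend.items()), columns=["code", "class_name"]
    ).to_csv(directory / "legend.csv", index=False)
    pd.DataFrame(
        sorted(grid.zone_legend.items()), columns=["code", "kebele_id"]
    ).to_csv(directory / "zone_legend.csv", index=False)
    (directory / "grid_meta.json").write_text(
        json.dumps({"cell_size_m": grid.cell_size_m, "nodata": grid.nodata}, indent=2)
    )
    return directory


def read_grid(directory: str | Path) -> LandscapeGrid:
    """Read a grid written by :func:`write_grid`; round-trips exactly."""
    directory = Path(directory)
    meta = json.loads((directory / "grid_meta.json").read_text())
    legend_df = pd.read_csv(directory / "legend.csv")
    zl_df = pd.read_csv(directory / "zone_legend.csv")
    return LandscapeGrid(
        classes=_read_band(directory / "lulc.tif"),
        zones=_read_band(directory / "zones.tif"),
        cell_size_m=float(meta["cell_size_m"]),
        legend=dict(zip(legend_df["code"].astype(int), legend_df["class_name"])),
        zone_legend=dict(zip(zl_df["code"].astype(int), zl_df["kebele_id"].astype(str))),
        nodata=int(meta["nodata"]),
    )


# ---------------------------------------------------------------------------
# Kebele table
# ---------------------------------------------------------------------------

def validate_kebele_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-unit table (unique ids, positive area, population >= 1)."""
    missing = [c for c in KEBELE_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"kebele table missing required columns: {missing}")
    dupes = table["kebele_id"][table["kebele_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate kebele_id values: {dupes}")
    if (table["area_km2"] <= 0).any():
        bad = table.loc[table["area_km2"] <= 0, "kebele_id"].tolist()
        raise ValueError(f"non-positive area_km2 for kebeles: {bad}")
    if (table["population"] < 1).any():
        bad = table.loc[table["population"] < 1, "kebele_id"].tolist()
        raise ValueError(f"population < 1 for kebeles: {bad}")
    social = social_variable_names(table)
    if table[social].isna().any().any() if social else False:
        raise ValueError("missing values in social variables")
    return table


def social_variable_names(table: pd.DataFrame) -> list[str]:
    """Names of the social-variable columns (everything beyond the required four)."""
    return [c for c in table.columns if c not in KEBELE_REQUIRED_COLUMNS]


def read_kebele_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"kebele_id": str, "woreda": str})
    table["population"] = table["population"].astype(int)
    return validate_kebele_table(table)


def write_kebele_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_kebele_table(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Long result tables
# ---------------------------------------------------------------------------

_LONG_SORT = ["unit", "aspect", "state"]


def write_long_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format result CSV with stable (unit, aspect, state) ordering."""
    cols = [c for c in _LONG_SORT if c in table.columns]
    out = table.sort_values(cols, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False)


def read_long_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"unit": str, "aspect": str, "state": str})


# ---------------------------------------------------------------------------
# GeoJSON reporting
# ---------------------------------------------------------------------------

def zone_polygons(grid: LandscapeGrid):
    """Derive one shapely polygon per kebele from the zone raster.

    Cells are unit squares of cell_size_m; per-row runs of equal zone are
    merged into rectangles before the union, keeping the geometry cheap.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    s = grid.cell_size_m
    nrow, _ = grid.shape
    rects: dict[int, list] = {}
    for r in range(nrow):
        row = grid.zones[r]
        # run-length encode the row
        change = np.flatnonzero(np.diff(row)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [row.size]))
        for c0, c1 in zip(starts, ends):
            code = int(row[c0])
            if code == grid.nodata:
                continue
            # y axis points north: row 0 at the top
            rects.setdefault(code, []).append(
                box(c0 * s, (nrow - r - 1) * s, c1 * s, (nrow - r) * s)
            )
    return {
        grid.zone_legend.get(code, str(code)): unary_union(geoms)
        for code, geoms in sorted(rects.items())
    }


def write_zones_geojson(
    grid: LandscapeGrid,
    path: str | Path,
    properties: dict[str, dict] | None = None,
) -> None:
    """Write kebele polygons as a GeoJSON FeatureCollection.

    *properties* maps kebele_id -> extra feature properties (archetype,
    levels, ...), merged on top of the kebele_id property.
    """
    from shapely.geometry import mapping

    polys = zone_polygons(grid)
    features = []
    for kebele_id, geom in polys.items():
        props = {"kebele_id": kebele_id}
        if properties and kebele_id in properties:
            props.update(properties[kebele_id])
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def warn_data(message: str) -> None:
    """Emit a data-quality warning (single chokepoint so tests can assert)."""
    warnings.warn(message, UserWarning, stacklevel=3)
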