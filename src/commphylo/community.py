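"""Plot-level community statistics and the supporting raster/range machinery.

The unit of analysis is a forest inventory plot with a binary species list.
The central statistic is the *mean family age* (MFA): each species inherits
the crown age of its family and the plot value is the unweighted mean over the
species present.  Community trait means work the same way.  *Realized cold
tolerance* is the coldest minimum-temperature-of-the-coldest-month value found
anywhere inside a species' range, computed by overlaying range cells on a
temperature raster.

Rasters use the plain-text ESRI ASCII grid format; cells are addressed
row-major from the north-west corner, 0-based.  Coordinates are WGS84
longitude/latitude in decimal degrees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CommPhyloError, ValidationError

__all__ = [
    "CommunityTable",
    "FamilyAgeMap",
    "TemperatureRaster",
    "RangeMap",
    "filter_plots",
    "mean_family_age",
    "realized_cold_tolerance",
    "realized_cold_tolerances",
    "community_trait_mean",
    "DISPERSAL_RANK",
    "PHENOLOGY_CODE",
]

log = logging.getLogger(__name__)

#: ranked dispersal-distance coding: unassisted < 50 m, animal 50 m - 1 km, wind > 1 km
DISPERSAL_RANK = {"unassisted": 1, "animal": 2, "wind": 3}
PHENOLOGY_CODE = {"evergreen": 0, "deciduous": 1}


@dataclass
class CommunityTable:
    """Plot x species incidences plus plot coordinates and local covariates.

    ``incidence``: binary DataFrame, plots as index, species as columns.
    ``plots``: DataFrame indexed identically with at least ``lon`` and ``lat``
    columns (decimal degrees); any further columns are local covariates
    (elevation, slope, aspect, physiographic class, natural-stand flag...).
    """

    incidence: pd.DataFrame
    plots: pd.DataFrame

    def __post_init__(self):
        inc = self.incidence
        vals = inc.to_numpy()
        if not np.isin(vals, (0, 1, True, False)).all():
            raise ValidationError("incidence table must be binary (0/1)")
        if not inc.index.equals(self.plots.index):
            raise ValidationError("incidence and plot-metadata indexes differ")
        for col in ("lon", "lat"):
            if col not in self.plots.columns:
                raise ValidationError(f"plot metadata lacks a {col!r} column")

    @classmethod
    def from_long(cls, occurrences: pd.DataFrame, plots: pd.DataFrame) -> "CommunityTable":
        """Build from a long table with ``plot_id`` and ``species`` columns."""
        inc = (
            occurrences.assign(present=1)
            .pivot_table(index="plot_id", columns="species", values="present", fill_value=0)
            .astype(int)
        )
        inc = inc.reindex(plots.index, fill_value=0)
        return cls(incidence=inc, plots=plots)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    def species_at(self, plot_id) -> list[str]:
        row = self.incidence.loc[plot_id]
        return list(row.index[row.astype(bool)])

    def subset(self, plot_ids) -> "CommunityTable":
        return CommunityTable(self.incidence.loc[plot_ids], self.plots.loc[plot_ids])


@dataclass
class FamilyAgeMap:
    """species -> family -> crown age (Myr); ``age_source`` is molecular or fossil."""

    species_to_family: dict
    family_age: dict
    age_source: str = "molecular"

    def __post_init__(self):
        bad = [f for f, a in self.family_age.items() if not a > 0]
        if bad:
            raise ValidationError(f"non-positive family ages: {bad[:5]}")

    def age_of(self, species: str) -> float:
        return float(self.family_age[self.species_to_family[species]])

    def species_ages(self, species: Iterable[str]) -> pd.Series:
        missing = [s for s in species if s not in self.species_to_family]
        if missing:
            raise ValidationError(f"species without a family mapping: {missing[:10]}")
        return pd.Series({s: self.age_of(s) for s in species}, dtype=float)


@dataclass
class TemperatureRaster:
    """Regular lon/lat grid of minimum temperature of the coldest month (degC).

    ``grid`` rows run north to south (row 0 = northernmost), columns west to
    east; ``xll``/``yll`` give the south-west corner, ``cellsize`` the square
    cell size in degrees.  ``nodata`` cells are masked on read.
    """

    grid: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        valid = self.grid[~self.mask]
        if valid.size and (valid.min() < -60 or valid.max() > 40):
            warnings.warn("raster values fall outside the [-60, 40] degC sanity band")

    @property
    def mask(self) -> np.ndarray:
        return self.grid == self.nodata

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """0-based (row, col) of the cell containing a point; row 0 is the NW corner."""
        nrows, ncols = self.grid.shape
        col = int((lon - self.xll) / self.cellsize)
        row = int((self.yll + nrows * self.cellsize - lat) / self.cellsize)
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValidationError(f"point ({lon}, {lat}) falls outside the raster")
        return row, col

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.cell_of(lon, lat)
        return float(self.grid[r, c])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.grid.shape[0]
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (nrows - row - 0.5) * self.cellsize
        return lon, lat

    # -- ESRI ASCII grid I/O ------------------------------------------------

    @classmethod
    def read_ascii(cls, path) -> "TemperatureRaster":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
                ):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        grid = np.array(rows)
        if grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValidationError(
                f"grid shape {grid.shape} does not match header "
                f"({int(header['nrows'])}, {int(header['ncols'])})"
            )
        return cls(
            grid=grid,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )

    def write_ascii(self, path) -> None:
        nrows, ncols = self.grid.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\nnrows {nrows}\n")
            fh.write(f"xllcorner {self.xll:.10g}\nyllcorner {self.yll:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\nNODATA_value {self.nodata:.10g}\n")
            for row in self.grid:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


class RangeMap(dict):
    """species -> set of (row, col) raster cells; plain dict with validation."""

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RangeMap":
        """Build from a long table with species, cell_row, cell_col columns."""
        rm = cls()
        for sp, grp in df.groupby("species"):
            rm[sp] = set(zip(grp["cell_row"].astype(int), grp["cell_col"].astype(int)))
        return rm

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"species": sp, "cell_row": r, "cell_col": c}
            for sp, cells in self.items()
            for r, c in sorted(cells)
        ]
        return pd.DataFrame(recs, columns=["species", "cell_row", "cell_col"])


# -- operations -----------------------------------------------------------------


def filter_plots(
    table: CommunityTable, min_species: int = 2, natural_only: bool = False
) -> CommunityTable:
    """Drop plots below the richness floor and, optionally, non-natural stands.

    Mirrors the inventory inclusion rules: a plot must hold at least two
    angiosperm tree species and (optionally) be coded as a natural stand
    (boolean ``natural`` column in the plot metadata).
    """
    rich_ok = table.richness() >= min_species
    if natural_only:
        if "natural" not in table.plots.columns:
            raise ValidationError("natural_only requires a 'natural' plot column")
        nat_ok = table.plots["natural"].astype(bool)
    else:
        nat_ok = pd.Series(True, index=table.plots.index)
    keep = rich_ok & nat_ok
    n_rich = int((~rich_ok).sum())
    n_nat = int((rich_ok & ~nat_ok).sum())
    log.info("filter_plots: removed %d below %d species, %d non-natural", n_rich,
             min_species, n_nat)
    if not keep.any():
        binding = "min_species" if n_rich >= n_nat else "natural_only"
        raise CommPhyloError(f"no plots survive filtering (binding filter: {binding})")
    return table.subset(table.plots.index[keep])


def mean_family_age(table: CommunityTable, ages: FamilyAgeMap) -> pd.Series:
    """Per-plot mean family age (Myr): unweighted mean over species present."""
    sp_age = ages.species_ages(table.species)
    inc = table.incidence.astype(float)
    totals = inc @ sp_age.reindex(table.species).to_numpy()
    counts = inc.sum(axis=1)
    if (counts == 0).any():
        raise ValidationError("plots with zero species present; run filter_plots first")
    mfa = totals / counts
    mfa.name = "mfa"
    return mfa


def realized_cold_tolerance(cells: Iterable[tuple[int, int]], raster: TemperatureRaster) -> float:
    """Coldest raster value inside a species' range (its realized tolerance)."""
    vals = [raster.grid[r, c] for r, c in cells]
    vals = [v for v in vals if v != raster.nodata]
    if not vals:
        raise ValidationError("range overlaps no valid raster cell")
    return float(min(vals))


def realized_cold_tolerances(ranges: RangeMap, raster: TemperatureRaster) -> pd.Series:
    """Realized cold tolerance for every species in a range map."""
    out = pd.Series(
        {sp: realized_cold_tolerance(cells, raster) for sp, cells in ranges.items()},
        dtype=float,
    )
    out.name = "cold_tolerance"
    return out


def community_trait_mean(table: CommunityTable, traits: Mapping | pd.Series) -> pd.Series:
    """Per-plot unweighted mean of a species trait over the species present.

    Species lacking a value are excluded from this trait's mean only; plots
    where no present species has a value are dropped with a warning.  Pass
    log10 seed sizes to report geometric means, and coded discrete traits
    (``DISPERSAL_RANK``, ``PHENOLOGY_CODE``) for ordinal/binary variables.
    """
    tr = pd.Series(traits, dtype=float).reindex(table.species)
    inc = table.incidence.astype(float)
    covered = inc.loc[:, tr.notna()]
    vals = tr.dropna()
    counts = covered.sum(axis=1)
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} plots have no trait coverage; dropped")
    means = (covered @ vals.to_numpy())[~empty] / counts[~empty]
    return means
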