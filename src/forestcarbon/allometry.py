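"""Tree allometry: timber volume, plot biomass carbon density and paired deltas.

Per-tree timber volume follows the standard two-predictor power law

    V_i = a * DBH^e * TH^f        [DBH in cm, TH in m, V in m^3]

with species-specific constants ``a, e, f``.  Plot volume is the sum over all
measured stems, and whole-stand biomass follows the biomass-expansion-factor
method, a linear conversion from timber volume,

    B = carbon_fraction * (b * V + c) / A     [kg C m^-2]

where ``A`` is the plot area (400 m^2 for a 20 x 20 m survey plot) and the
``carbon_fraction`` converts dry biomass to carbon (default 0.5).  Published
coefficient tables for the species of northern China may already embed a
carbon fraction; the table schema therefore carries ``carbon_fraction``
per species so either reading can be expressed (set it to 1.0 if ``b, c``
are calibrated directly to carbon).

Control (non-forested) plots carry no tree list; their biomass density is
looked up from a gridded background-biomass map at the plot coordinates.
The forestation effect for a pair is the difference forested minus control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    MissingDataError,
    UnknownSpeciesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: survey plot area in m^2 (20 x 20 m plots)
DEFAULT_PLOT_AREA_M2 = 400.0

#: minimum tree height admitted by the survey protocol, metres
MIN_TREE_HEIGHT_M = 2.5


@dataclass(frozen=True)
class AllometryCoefficients:
    """Species constants for the volume and biomass-expansion equations.

    Parameters
    ----------
    species
        Species code the constants apply to.
    a, e, f
        Volume-equation constants: ``V = a * DBH^e * TH^f``.
    b, c
        Biomass-expansion constants: ``biomass = b*V + c`` (kg dry mass
        per plot when V is the plot volume in m^3).
    carbon_fraction
        Dry-biomass-to-carbon conversion, in (0, 1].
    """

    species: str
    a: float
    e: float
    f: float
    b: float
    c: float
    carbon_fraction: float = 0.5

    def __post_init__(self):
        if not self.e > 0:
            raise ValidationError(f"{self.species}: exponent e must be > 0, got {self.e}")
        if self.f < 0:
            raise ValidationError(f"{self.species}: exponent f must be >= 0, got {self.f}")
        if not self.b > 0:
            raise ValidationError(f"{self.species}: expansion slope b must be > 0, got {self.b}")
        if not (0.0 < self.carbon_fraction <= 1.0):
            raise ValidationError(
                f"{self.species}: carbon_fraction must be in (0, 1], got {self.carbon_fraction}"
            )


class CoefficientTable:
    """Lookup of :class:`AllometryCoefficients` by species code."""

    def __init__(self, coefficients: Iterable[AllometryCoefficients]):
        self._by_species = {}
        for coef in coefficients:
            if coef.species in self._by_species:
                raise IntegrityError(f"duplicate coefficient row for species {coef.species!r}")
            self._by_species[coef.species] = coef

    def __getitem__(self, species: str) -> AllometryCoefficients:
        try:
            return self._by_species[species]
        except KeyError:
            raise UnknownSpeciesError(
                f"no allometry coefficients for species {species!r}"
            ) from None

    def __contains__(self, species: str) -> bool:
        return species in self._by_species

    def species(self) -> list[str]:
        return list(self._by_species)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CoefficientTable":
        required = {"species", "a", "e", "f", "b", "c"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"coefficient table missing columns: {sorted(missing)}")
        rows = []
        for rec in df.to_dict("records"):
            rows.append(
                AllometryCoefficients(
                    species=str(rec["species"]),
                    a=float(rec["a"]),
                    e=float(rec["e"]),
                    f=float(rec["f"]),
                    b=float(rec["b"]),
                    c=float(rec["c"]),
                    carbon_fraction=float(rec.get("carbon_fraction", 0.5)),
                )
            )
        return cls(rows)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": c.species,
                    "a": c.a,
                    "e": c.e,
                    "f": c.f,
                    "b": c.b,
                    "c": c.c,
                    "carbon_fraction": c.carbon_fraction,
                }
                for c in self._by_species.values()
            ]
        )


#: survey species codes: the five dominant plantation species plus 'other'
SPECIES_CODES = (
    "P_koraiensis",
    "L_gmelinii",
    "P_sylvestris",
    "P_tabuliformis",
    "Populus",
    "other",
)


def placeholder_coefficient_table() -> CoefficientTable:
    """A generic coefficient table usable when no calibrated table is supplied.

    These constants are PLACEHOLDERS with plausible magnitudes for the
    volume equation (DBH in cm, TH in m, V in m^3) and the biomass
    expansion, not species-calibrated values; analyses of real survey data
    must supply their own ``coefficients.csv``.
    """
    return CoefficientTable(
        AllometryCoefficients(species=s, a=1e-4, e=2.0, f=1.0, b=600.0, c=20.0,
                              carbon_fraction=0.5)
        for s in SPECIES_CODES
    )


def tree_volume(
    dbh_cm,
    th_m,
    coef: AllometryCoefficients,
    *,
    permissive: bool = False,
):
    """Timber volume of one tree (or an array of trees), m^3.

    ``V = a * DBH^e * TH^f``.  In strict mode (default) DBH must be positive
    and TH must exceed the 2.5 m survey threshold; ``permissive=True`` admits
    any non-negative measurements (used for boundary tests and non-survey
    data).
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    th = np.asarray(th_m, dtype=float)
    if permissive:
        if np.any(dbh < 0) or np.any(th < 0):
            raise ValidationError("DBH and TH must be non-negative")
    else:
        if np.any(dbh <= 0):
            raise ValidationError("DBH must be positive (strict survey mode)")
        if np.any(th <= MIN_TREE_HEIGHT_M):
            raise ValidationError(
                f"TH must exceed the survey threshold {MIN_TREE_HEIGHT_M} m "
                "(use permissive=True to override)"
            )
    vol = coef.a * dbh**coef.e * th**coef.f
    if vol.ndim == 0:
        return float(vol)
    return vol


def plot_volume(
    trees: pd.DataFrame,
    coefs: CoefficientTable,
    species: str,
    *,
    permissive: bool = False,
) -> float:
    """Total timber volume of a plot, m^3: the sum of per-tree volumes.

    ``trees`` must carry columns ``plot_id, dbh_cm, th_m`` and all rows must
    belong to one plot.  An empty table has volume 0.
    """
    if len(trees) == 0:
        return 0.0
    if trees["plot_id"].nunique() > 1:
        raise IntegrityError(
            f"plot_volume got trees from multiple plots: {sorted(trees['plot_id'].unique())}"
        )
    coef = coefs[species]
    vols = tree_volume(
        trees["dbh_cm"].to_numpy(), trees["th_m"].to_numpy(), coef, permissive=permissive
    )
    return float(np.sum(vols))


def biomass_density(
    volume_m3: float,
    coef: AllometryCoefficients,
    area_m2: float = DEFAULT_PLOT_AREA_M2,
) -> float:
    """Biomass carbon density of a plot, kg C m^-2.

    ``B = carbon_fraction * (b*V + c) / A``.
    """
    if area_m2 <= 0:
        raise ValidationError(f"plot area must be positive, got {area_m2}")
    if volume_m3 < 0:
        raise ValidationError(f"plot volume must be non-negative, got {volume_m3}")
    return coef.carbon_fraction * (coef.b * volume_m3 + coef.c) / area_m2


@dataclass(frozen=True)
class BiomassResult:
    plot_id: str
    volume_m3: float
    biomass_kg_m2: float
    area_m2: float
    n_trees: int


def plot_biomass_table(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    coefs: CoefficientTable,
    area_m2: float = DEFAULT_PLOT_AREA_M2,
    *,
    permissive: bool = False,
) -> pd.DataFrame:
    """Per-plot volume and biomass carbon density for all forested plots.

    Returns a frame with columns
    ``plot_id, volume_m3, biomass_kg_m2, area_m2, n_trees``.
    """
    forested = plots[plots["role"] == "forested"]
    tree_groups = dict(iter(trees.groupby("plot_id"))) if len(trees) else {}
    rows = []
    for rec in forested.itertuples():
        plot_trees = tree_groups.get(rec.plot_id, trees.iloc[0:0])
        v = plot_volume(plot_trees, coefs, rec.species, permissive=permissive)
        b = biomass_density(v, coefs[rec.species], area_m2)
        rows.append(
            {
                "plot_id": rec.plot_id,
                "volume_m3": v,
                "biomass_kg_m2": b,
                "area_m2": area_m2,
                "n_trees": len(plot_trees),
            }
        )
    return pd.DataFrame(rows, columns=["plot_id", "volume_m3", "biomass_kg_m2", "area_m2", "n_trees"])


class ControlBiomassRaster:
    """Cell-registered lon/lat grid of background biomass carbon density.

    The grid origin is the lower-left corner of the lower-left cell; a point
    is assigned to the cell whose half-open extent
    ``[x0 + i*dx, x0 + (i+1)*dx)`` contains it, so points exactly on a cell
    edge resolve to the lower-left cell of the tie.
    """

    def __init__(self, lon0: float, lat0: float, dlon: float, dlat: float, values: np.ndarray):
        if dlon <= 0 or dlat <= 0:
            raise ValidationError("cell sizes must be positive")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.dlon = float(dlon)
        self.dlat = float(dlat)
        self.values = np.asarray(values, dtype=float)  # shape (nlat, nlon)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be 2-D (nlat, nlon)")

    @property
    def shape(self):
        return self.values.shape

    def lookup(self, lon: float, lat: float) -> float:
        """Value of the cell containing the point; raises on miss or mask."""
        ix = int(np.floor((lon - self.lon0) / self.dlon))
        iy = int(np.floor((lat - self.lat0) / self.dlat))
        nlat, nlon = self.values.shape
        if not (0 <= ix < nlon and 0 <= iy < nlat):
            raise MissingDataError(f"point ({lon}, {lat}) outside raster extent")
        val = self.values[iy, ix]
        if np.isnan(val):
            raise MissingDataError(f"raster cell at ({lon}, {lat}) is masked")
        return float(val)

    def to_dataframe(self) -> pd.DataFrame:
        """Gridded-CSV form: one row per cell with cell-centre coordinates."""
        nlat, nlon = self.values.shape
        lons = self.lon0 + (np.arange(nlon) + 0.5) * self.dlon
        lats = self.lat0 + (np.arange(nlat) + 0.5) * self.dlat
        lon_g, lat_g = np.meshgrid(lons, lats)
        return pd.DataFrame(
            {"lon": lon_g.ravel(), "lat": lat_g.ravel(), "biomass_kg_m2": self.values.ravel()}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ControlBiomassRaster":
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        if len(lons) < 2 or len(lats) < 2:
            raise ValidationError("gridded CSV needs at least a 2x2 grid")
        dlon = float(np.min(np.diff(lons)))
        dlat = float(np.min(np.diff(lats)))
        nlon = len(lons)
        nlat = len(lats)
        values = np.full((nlat, nlon), np.nan)
        ii = np.searchsorted(lons, df["lon"].to_numpy())
        jj = np.searchsorted(lats, df["lat"].to_numpy())
        values[jj, ii] = df["biomass_kg_m2"].to_numpy()
        return cls(lons[0] - dlon / 2, lats[0] - dlat / 2, dlon, dlat, values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlBiomassRaster":
        return cls.from_dataframe(pd.read_csv(path))


def control_biomass(
    plot: Mapping, raster: ControlBiomassRaster
) -> float:
    """Background biomass density of a control plot from the gridded map."""
    return raster.lookup(float(plot["lon"]), float(plot["lat"]))


def delta_biomass_density(forested_kg_m2: float, control_kg_m2: float) -> float:
    """Forestation-induced change in biomass carbon density (forested − control).

    Negative values are meaningful (biomass loss relative to the background)
    and are preserved.
    """
    if forested_kg_m2 is None or control_kg_m2 is None:
        raise MissingDataError("both pair members must have a biomass density")
    return float(forested_kg_m2) - float(control_kg_m2)
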