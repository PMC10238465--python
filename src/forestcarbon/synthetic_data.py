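"""Synthetic paired-plot survey generator with known ground truth.

The generator emulates the design of a large paired forestation survey in
northern China: ~163 sites, each holding one non-forested control plot and
1–26 forested monoculture plots (five dominant species plus 'other', stand
ages ~5–50 yr), per-tree DBH/height measurements, and three replicate soil
profiles per plot over six fixed layers to 1 m.  Everything is drawn from
configurable response surfaces so that recovery tests can close the loop:

* the biomass response grows linearly with stand age at a species-specific
  rate and is modulated by a unimodal (Gaussian) factor of background soil
  total nitrogen density (STND) — fast-growing species gain the most at
  intermediate nitrogen;
* the soil-organic-carbon response declines monotonically with STND at a
  species-specific (negative) rate, crossing zero at a configurable STND,
  and saturates with stand age — nitrogen-rich soils lose SOC under
  forestation while nitrogen-poor soils gain it.

Tree lists are constructed by inverting the allometric chain: the target
plot biomass density fixes the target plot timber volume, stem sizes are
drawn from an age-dependent lognormal DBH distribution with a deterministic
height curve, and DBH is rescaled so the summed volume matches the target
exactly.  Soil profiles distribute the target plot densities over layers
with fixed depth fractions and realistic bulk densities, so integrating
them recovers the plot totals.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import allometry, soil_carbon
from .allometry import (
    AllometryCoefficients,
    CoefficientTable,
    ControlBiomassRaster,
    placeholder_coefficient_table,
)
from .errors import ConfigurationError, ValidationError

LAND_USE_TYPES = ("barren", "cropland", "grassland", "natural_forest", "riparian_sand")

#: fraction of the profile total carried by each of the six layers
LAYER_FRACTIONS = (0.25, 0.18, 0.18, 0.14, 0.15, 0.10)
#: dry bulk density per layer, g cm^-3 (increases with depth)
LAYER_BULK_DENSITY = (1.10, 1.15, 1.20, 1.30, 1.40, 1.50)
SOIL_VOLUME_FRACTION = 0.95
RING_VOLUME_CM3 = 100.0
INORGANIC_C_CONTENT = 0.002


@dataclass(frozen=True)
class SpeciesResponse:
    """Ground-truth response parameters for one species."""

    weight: float
    biomass_age_slope: float  # kg C m^-2 yr^-1
    hump_optimum: float = 1.2  # STND (kg N m^-2) of peak biomass response
    hump_width: float | None = 0.8  # Gaussian width; None disables the hump
    soc_stnd_slope: float = -0.5  # kg C m^-2 per kg N m^-2 (negative)


def default_species_responses() -> dict[str, SpeciesResponse]:
    """Study-condition defaults: growth rates ordered as observed in the
    field (larch and Mongolian pine fastest, Chinese pine slowest), and the
    soil response steepest for the fastest growers (the carbon–nitrogen
    trade-off)."""
    return {
        "P_koraiensis": SpeciesResponse(0.10, 0.20, soc_stnd_slope=-2.5),
        "L_gmelinii": SpeciesResponse(0.22, 0.30, soc_stnd_slope=-3.5),
        "P_sylvestris": SpeciesResponse(0.12, 0.28, soc_stnd_slope=-3.0),
        "P_tabuliformis": SpeciesResponse(0.16, 0.06, soc_stnd_slope=-0.8),
        "Populus": SpeciesResponse(0.30, 0.16, soc_stnd_slope=-2.0),
        "other": SpeciesResponse(0.10, 0.18, soc_stnd_slope=-2.2),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic survey.

    Defaults reproduce the survey conditions the analysis assumes: 163
    sites, 1–26 forested plots per site with ≈3.8 expected (matching ≈614
    forested plots in total), stand ages 5–50 yr, MAT −8…16 °C, MAP
    300…1300 mm, background STND ≈0.2–3 kg N m^-2.
    """

    n_sites: int = 163
    forested_per_site_range: tuple[int, int] = (1, 26)
    forested_geometric_p: float = 0.266  # shifted-geometric success prob
    species_responses: dict[str, SpeciesResponse] = field(
        default_factory=default_species_responses
    )
    age_range: tuple[int, int] = (5, 50)
    lon_range: tuple[float, float] = (106.81, 133.31)
    lat_range: tuple[float, float] = (34.2, 51.8)
    mat_range: tuple[float, float] = (-8.0, 16.0)
    map_range: tuple[float, float] = (300.0, 1300.0)
    stnd_range: tuple[float, float] = (0.2, 3.0)
    stnd_log_median: float = 0.9  # kg N m^-2, lognormal median
    stnd_log_sigma: float = 0.45
    stnd_zero_crossing: float = 1.4  # STND where the SOC response crosses zero
    soc_age_saturation_yr: float = 20.0
    cn_ratio: float = 10.0  # control SOCD / STND (kg C per kg N)
    control_biomass_mean: float = 1.0  # kg C m^-2
    control_biomass_sd: float = 0.3
    climate_noise_sd: float = 1.5  # °C on MAT; scaled x50 for MAP (mm)
    biomass_noise_sd: float = 0.8  # kg C m^-2 on the biomass response
    soc_noise_sd: float = 0.4  # kg C m^-2 on the soil response
    replicate_noise_sd: float = 0.05  # relative noise on layer contents
    truncation_probability: float = 0.02
    truncation_max_layer: int = 4  # truncated cores stop at 30 cm
    stem_density_per_m2: float = 0.2
    plot_area_m2: float = 400.0
    grid_shape: tuple[int, int] = (48, 72)  # (nlat, nlon)
    planted_mask_fraction: float = 0.7
    n_provinces: int = 7
    total_planted_area_km2: float = 123_000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        lo, hi = self.forested_per_site_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("forested_per_site_range must satisfy 1 <= min <= max")
        for name in ("age_range", "lon_range", "lat_range", "mat_range",
                     "map_range", "stnd_range"):
            a, b = getattr(self, name)
            if not a < b:
                raise ConfigurationError(f"{name} must be non-degenerate (min < max)")
        total_w = sum(r.weight for r in self.species_responses.values())
        if not math.isclose(total_w, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"species weights must sum to 1, got {total_w}")
        if not (0 < self.forested_geometric_p <= 1):
            raise ConfigurationError("forested_geometric_p must be in (0, 1]")


# ---------------------------------------------------------------------------
# ground-truth response surfaces
# ---------------------------------------------------------------------------

def true_response_surfaces(config: GeneratorConfig) -> tuple[Callable, Callable]:
    """The configured ground-truth surfaces, as vectorized callables.

    Returns ``(delta_biomass(age, stnd, species), delta_soc(stnd, age,
    species))``.  The biomass surface is unimodal in STND (when a hump
    width is configured) and linear in age; the SOC surface is monotone
    non-increasing in STND and saturates with age.
    """

    def delta_biomass(age, stnd, species):
        r = config.species_responses[species]
        age = np.asarray(age, dtype=float)
        stnd = np.asarray(stnd, dtype=float)
        if r.hump_width is None:
            hump = np.ones_like(stnd)
        else:
            hump = np.exp(-((stnd - r.hump_optimum) ** 2) / (2 * r.hump_width**2))
        out = r.biomass_age_slope * age * hump
        return float(out) if out.ndim == 0 else out

    def delta_soc(stnd, age, species):
        r = config.species_responses[species]
        age = np.asarray(age, dtype=float)
        stnd = np.asarray(stnd, dtype=float)
        age_factor = np.minimum(age / config.soc_age_saturation_yr, 1.0)
        out = r.soc_stnd_slope * (stnd - config.stnd_zero_crossing) * age_factor
        return float(out) if out.ndim == 0 else out

    return delta_biomass, delta_soc


# ---------------------------------------------------------------------------
# climate / nitrogen spatial fields
# ---------------------------------------------------------------------------

def _mat_at(lat, config, rng=None):
    lat0, lat1 = config.lat_range
    m0, m1 = config.mat_range
    base = np.interp(lat, [lat0, lat1], [m1, m0])  # warmer in the south
    if rng is not None:
        base = base + rng.normal(0.0, config.climate_noise_sd, size=np.shape(base))
    return np.clip(base, m0, m1)


def _map_at(lon, config, rng=None):
    lon0, lon1 = config.lon_range
    p0, p1 = config.map_range
    base = np.interp(lon, [lon0, lon1], [p0, p1])  # wetter in the east
    if rng is not None:
        base = base + rng.normal(0.0, 50.0 * config.climate_noise_sd, size=np.shape(base))
    return np.clip(base, p0, p1)


def _draw_stnd(config, rng, size, lon=None, lat=None):
    """Background STND: spatially structured (richer soils toward the cooler,
    wetter north-east, as for the phaeozem belt) plus lognormal site spread."""
    lo, hi = config.stnd_range
    log_med = math.log(config.stnd_log_median)
    if lon is not None and lat is not None:
        lon0, lon1 = config.lon_range
        lat0, lat1 = config.lat_range
        trend = 0.55 * ((np.asarray(lat) - lat0) / (lat1 - lat0) - 0.5) + 0.35 * (
            (np.asarray(lon) - lon0) / (lon1 - lon0) - 0.5
        )
    else:
        trend = 0.0
    vals = np.exp(log_med + trend + rng.normal(0.0, config.stnd_log_sigma, size))
    return np.clip(vals, lo, hi)


# ---------------------------------------------------------------------------
# sites and plots
# ---------------------------------------------------------------------------

@dataclass
class SiteCollection:
    """Sites with covariates and the control/forested plot register."""

    sites: pd.DataFrame
    plots: pd.DataFrame


def generate_sites(config: GeneratorConfig, rng: np.random.Generator | None = None) -> SiteCollection:
    """Draw sites (coordinates, climate, background nitrogen, land use) and
    their plots: exactly one control plus a range-bounded number of forested
    plots per site, species by weight, integer stand ages."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_sites
    lon = rng.uniform(*config.lon_range, n)
    lat = rng.uniform(*config.lat_range, n)
    mat = _mat_at(lat, config, rng)
    map_mm = _map_at(lon, config, rng)
    stnd = _draw_stnd(config, rng, n, lon=lon, lat=lat)
    land_use = rng.choice(LAND_USE_TYPES, size=n)
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "lon": lon, "lat": lat, "mat": mat, "map": map_mm,
            "stnd_background": stnd, "land_use": land_use,
        }
    )

    lo, hi = config.forested_per_site_range
    counts = np.minimum(lo + rng.geometric(config.forested_geometric_p, n) - 1, hi)
    species_codes = list(config.species_responses)
    weights = np.array([config.species_responses[s].weight for s in species_codes])
    a0, a1 = config.age_range
    rows = []
    for i, site_id in enumerate(sites["site_id"]):
        rows.append({"plot_id": f"{site_id}_C", "site_id": site_id, "role": "control",
                     "species": None, "stand_age": np.nan})
        for k in range(int(counts[i])):
            rows.append(
                {
                    "plot_id": f"{site_id}_F{k:02d}",
                    "site_id": site_id,
                    "role": "forested",
                    "species": rng.choice(species_codes, p=weights),
                    "stand_age": int(rng.integers(a0, a1 + 1)),
                }
            )
    plots = pd.DataFrame(rows).merge(
        sites[["site_id", "lon", "lat", "mat", "map", "stnd_background", "land_use"]],
        on="site_id",
    )
    return SiteCollection(sites=sites, plots=plots)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def generate_trees(
    plot: Mapping,
    target_biomass_kg_m2: float,
    coef: AllometryCoefficients,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """A tree list whose allometric biomass density equals the target exactly.

    Stem count comes from a fixed stem density, DBH from an age-increasing
    lognormal, height from a deterministic curve on DBH plus noise; DBH is
    then rescaled so the plot timber volume matches the volume implied by
    the target biomass (``V = (B*A/cf − c)/b``).  Control plots carry no
    tree list and raise.
    """
    if plot["role"] != "forested":
        raise ValidationError(f"plot {plot['plot_id']} is not forested; controls have no tree list")
    age = float(plot["stand_age"])
    cols = ["tree_id", "plot_id", "dbh_cm", "th_m"]
    if age <= 0:
        return pd.DataFrame(columns=cols)
    area = config.plot_area_m2
    v_target = (target_biomass_kg_m2 * area / coef.carbon_fraction - coef.c) / coef.b
    if v_target <= 0:
        return pd.DataFrame(columns=cols)
    n_trees = max(1, int(round(config.stem_density_per_m2 * area)))
    dbh = rng.lognormal(math.log(5.0 + 0.4 * age), 0.3, n_trees)
    th = np.maximum(1.3 + 0.6 * dbh**0.8 + rng.normal(0.0, 0.3, n_trees), 2.6)
    v_raw = float(np.sum(coef.a * dbh**coef.e * th**coef.f))
    dbh = dbh * (v_target / v_raw) ** (1.0 / coef.e)
    return pd.DataFrame(
        {
            "tree_id": [f"{plot['plot_id']}_T{i:03d}" for i in range(n_trees)],
            "plot_id": plot["plot_id"],
            "dbh_cm": dbh,
            "th_m": th,
        }
    )


# ---------------------------------------------------------------------------
# soil profiles
# ---------------------------------------------------------------------------

def generate_soil_profiles(
    plot: Mapping,
    socd_kg_m2: float,
    stnd_kg_m2: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Three replicate six-layer profiles integrating to the plot densities.

    The plot totals are spread over layers by fixed depth fractions; layer
    contents are back-calculated from fixed bulk densities and ring
    geometry.  With ``replicate_noise_sd = 0`` the three replicates are
    identical and the profile integrates to the targets exactly.  A core is
    truncated (layers beyond ``truncation_max_layer`` missing) with the
    configured probability.
    """
    truncated = rng.uniform() < config.truncation_probability
    n_layers = config.truncation_max_layer if truncated else soil_carbon.N_LAYERS
    rows = []
    for j in range(1, n_layers + 1):
        w = soil_carbon.LAYER_THICKNESS_CM[j]
        top, bottom = soil_carbon.LAYER_DEPTHS_CM[j]
        bd_eff = LAYER_BULK_DENSITY[j - 1] * SOIL_VOLUME_FRACTION
        sdw = bd_eff * RING_VOLUME_CM3
        denom = bd_eff * w * soil_carbon.UNIT_CONVERSION_KG_M2
        socc = max(socd_kg_m2, 0.0) * LAYER_FRACTIONS[j - 1] / denom
        stnc = max(stnd_kg_m2, 0.0) * LAYER_FRACTIONS[j - 1] / denom
        for rep in range(1, soil_carbon.N_REPLICATES + 1):
            jitter = (
                max(1.0 + rng.normal(0.0, config.replicate_noise_sd), 0.05)
                if config.replicate_noise_sd > 0
                else 1.0
            )
            socc_r = min(socc * jitter, 0.9)
            rows.append(
                {
                    "plot_id": plot["plot_id"],
                    "replicate": rep,
                    "layer_index": j,
                    "depth_top_cm": top,
                    "depth_bottom_cm": bottom,
                    "stcc": socc_r + INORGANIC_C_CONTENT,
                    "sicc": INORGANIC_C_CONTENT,
                    "stnc": min(stnc * jitter, 0.5),
                    "content_units": "fraction",
                    "sdw_g": sdw,
                    "ring_volume_cm3": RING_VOLUME_CM3,
                    "ps": SOIL_VOLUME_FRACTION,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gridded predictors, control raster, area table
# ---------------------------------------------------------------------------

def generate_control_raster(config: GeneratorConfig, rng: np.random.Generator) -> ControlBiomassRaster:
    """Coarse background-biomass map standing in for the 300-m control map."""
    nlat, nlon = 24, 36
    lon0, lon1 = config.lon_range
    lat0, lat1 = config.lat_range
    dlon = (lon1 - lon0) / nlon
    dlat = (lat1 - lat0) / nlat
    lons = lon0 + (np.arange(nlon) + 0.5) * dlon
    # background biomass rises gently toward the wetter east, plus noise
    gradient = 0.3 * (lons - lon0) / (lon1 - lon0)
    values = (
        config.control_biomass_mean
        + gradient[None, :]
        + rng.normal(0.0, config.control_biomass_sd, (nlat, nlon))
    )
    values = np.maximum(values, 0.05)
    return ControlBiomassRaster(lon0, lat0, dlon, dlat, values)


def generate_predictor_grid(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Regular lon/lat predictor grid with a planted-forest mask.

    Columns: ``lon, lat, mat, map, species, stand_age, stnd, province,
    mask``.  Provinces are nominal longitudinal bands (the aggregation only
    needs a label).
    """
    nlat, nlon = config.grid_shape
    lon0, lon1 = config.lon_range
    lat0, lat1 = config.lat_range
    lons = lon0 + (np.arange(nlon) + 0.5) * (lon1 - lon0) / nlon
    lats = lat0 + (np.arange(nlat) + 0.5) * (lat1 - lat0) / nlat
    lon_g, lat_g = np.meshgrid(lons, lats)
    n = lon_g.size
    species_codes = list(config.species_responses)
    weights = np.array([config.species_responses[s].weight for s in species_codes])
    a0, a1 = config.age_range
    prov = np.clip(
        ((lon_g.ravel() - lon0) / (lon1 - lon0) * config.n_provinces).astype(int),
        0, config.n_provinces - 1,
    )
    return pd.DataFrame(
        {
            "lon": lon_g.ravel(),
            "lat": lat_g.ravel(),
            "mat": _mat_at(lat_g.ravel(), config, rng),
            "map": _map_at(lon_g.ravel(), config, rng),
            "species": rng.choice(species_codes, p=weights, size=n),
            "stand_age": rng.integers(a0, a1 + 1, n).astype(float),
            "stnd": _draw_stnd(config, rng, n, lon=lon_g.ravel(), lat=lat_g.ravel()),
            "province": [f"province_{p + 1}" for p in prov],
            "mask": rng.uniform(size=n) < config.planted_mask_fraction,
        }
    )


def generate_soc_delta_grid(
    grid: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.Series:
    """Synthesized per-cell soil-carbon change on the predictor grid.

    Evaluates the ground-truth SOC response at each masked cell's STND,
    stand age and species, plus noise; stands in for an externally
    upscaled soil-change map.
    """
    _, soc_true = true_response_surfaces(config)
    out = pd.Series(np.nan, index=grid.index, name="delta_socd")
    masked = grid[grid["mask"].astype(bool)]
    vals = np.empty(len(masked))
    for i, rec in enumerate(masked.itertuples()):
        vals[i] = soc_true(rec.stnd, rec.stand_age, rec.species)
    if config.soc_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.soc_noise_sd, len(vals))
    out.loc[masked.index] = vals
    return out


def generate_area_table(grid: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Province x species planted areas proportional to masked-cell counts,
    scaled to the configured regional planted area (km^2)."""
    masked = grid[grid["mask"].astype(bool)]
    counts = masked.groupby(["province", "species"], as_index=False).size()
    counts["area_km2"] = counts["size"] / counts["size"].sum() * config.total_planted_area_km2
    return counts[["province", "species", "area_km2"]].rename(
        columns={"province": "province", "species": "species"}
    )


# ---------------------------------------------------------------------------
# full survey
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSurvey:
    """Everything one run of the generator produces."""

    config: GeneratorConfig
    sites: pd.DataFrame
    plots: pd.DataFrame
    trees: pd.DataFrame
    soil_samples: pd.DataFrame
    control_biomass: pd.DataFrame  # plot_id, biomass_kg_m2 for control plots
    control_raster: ControlBiomassRaster
    grid: pd.DataFrame
    soc_delta_grid: pd.Series
    area_table: pd.DataFrame
    coefficients: CoefficientTable


def generate_survey(
    config: GeneratorConfig | None = None,
    coefficients: CoefficientTable | None = None,
) -> SyntheticSurvey:
    """Run the full generator: sites, trees, soil, grids and areas.

    A single seeded generator drives every draw, so two runs with the same
    config produce byte-identical tables.
    """
    config = config or GeneratorConfig()
    coefs = coefficients or placeholder_coefficient_table()
    rng = np.random.default_rng(config.seed)
    collection = generate_sites(config, rng)
    plots = collection.plots
    raster = generate_control_raster(config, rng)
    bio_true, soc_true = true_response_surfaces(config)

    # control biomass from the map lookup
    ctrl_rows = []
    for rec in plots[plots["role"] == "control"].itertuples():
        ctrl_rows.append(
            {"plot_id": rec.plot_id, "site_id": rec.site_id,
             "biomass_kg_m2": raster.lookup(rec.lon, rec.lat)}
        )
    control_biomass = pd.DataFrame(ctrl_rows)
    ctrl_by_site = control_biomass.set_index("site_id")["biomass_kg_m2"]

    tree_frames, soil_frames = [], []
    for rec in plots.itertuples():
        plot = rec._asdict()
        site_stnd = rec.stnd_background
        socd_control = config.cn_ratio * site_stnd
        if rec.role == "control":
            soil_frames.append(
                generate_soil_profiles(plot, socd_control, site_stnd, config, rng)
            )
            continue
        b_control = float(ctrl_by_site[rec.site_id])
        noise = rng.normal(0.0, config.biomass_noise_sd) if config.biomass_noise_sd > 0 else 0.0
        delta_bio = bio_true(rec.stand_age, site_stnd, rec.species) + noise
        coef = coefs[rec.species]
        b_floor = coef.carbon_fraction * coef.c / config.plot_area_m2
        target_b = max(b_control + delta_bio, b_floor)
        tree_frames.append(generate_trees(plot, target_b, coef, config, rng))
        s_noise = rng.normal(0.0, config.soc_noise_sd) if config.soc_noise_sd > 0 else 0.0
        delta_soc = soc_true(site_stnd, rec.stand_age, rec.species) + s_noise
        soil_frames.append(
            generate_soil_profiles(
                plot, socd_control + delta_soc, site_stnd, config, rng
            )
        )

    tree_frames = [t for t in tree_frames if len(t)]
    trees = (
        pd.concat(tree_frames, ignore_index=True)
        if tree_frames
        else pd.DataFrame(columns=["tree_id", "plot_id", "dbh_cm", "th_m"])
    )
    soil_samples = pd.concat(soil_frames, ignore_index=True)
    grid = generate_predictor_grid(config, rng)
    soc_delta_grid = generate_soc_delta_grid(grid, config, rng)
    area_table = generate_area_table(grid, config)
    return SyntheticSurvey(
        config=config,
        sites=collection.sites,
        plots=plots,
        trees=trees,
        soil_samples=soil_samples,
        control_biomass=control_biomass[["plot_id", "biomass_kg_m2"]],
        control_raster=raster,
        grid=grid,
        soc_delta_grid=soc_delta_grid,
        area_table=area_table,
        coefficients=coefs,
    )


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``config`` with every noise source switched off (used by
    exact-recovery tests)."""
    return replace(
        config,
        climate_noise_sd=0.0,
        control_biomass_sd=0.0,
        biomass_noise_sd=0.0,
        soc_noise_sd=0.0,
        replicate_noise_sd=0.0,
        truncation_probability=0.0,
    )
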