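"""Layered soil organic carbon and total nitrogen densities.

Each plot is sampled by three replicate profiles over six fixed layers
(0–5, 5–10, 10–20, 20–30, 30–60, 60–100 cm).  Organic carbon content is the
difference between total and inorganic carbon content (SOCC = STCC − SICC,
clamped at zero).  A layer's area density is

    D_j = content_j * (SDW_j / V) * w_j * U

where ``SDW/V`` is the field bulk density times the soil volume fraction
(dry fine-soil mass over total ring volume, g cm^-3), ``w_j`` the layer
thickness in cm, and ``U`` the unit conversion.  With content as a mass
fraction the product has units g cm^-2 per cm of content scale; converting
g cm^-2 → kg m^-2 multiplies by 10, so ``U = 10`` for kg m^-2 output.
Per-layer densities are averaged over the replicate profiles and summed over
the layers present; profiles that could not be cored to 1 m simply sum fewer
layers and are flagged ``complete_to_1m=False``.

Paired deltas (forested − control) are computed over the set of layers the
two plots share so a truncated member never biases the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError

logger = logging.getLogger(__name__)

#: layer thicknesses in cm, indexed by layer_index 1..6
LAYER_THICKNESS_CM = {1: 5.0, 2: 5.0, 3: 10.0, 4: 10.0, 5: 30.0, 6: 40.0}

#: depth intervals (top, bottom) in cm per layer_index
LAYER_DEPTHS_CM = {
    1: (0, 5),
    2: (5, 10),
    3: (10, 20),
    4: (20, 30),
    5: (30, 60),
    6: (60, 100),
}

N_LAYERS = 6
N_REPLICATES = 3

#: fraction g cm^-3 cm -> kg m^-2  (1 g cm^-2 = 10 kg m^-2)
UNIT_CONVERSION_KG_M2 = 10.0


def organic_carbon_content(stcc, sicc):
    """Soil organic carbon content: STCC − SICC, clamped at zero.

    Returns ``(socc, clamped)`` where ``clamped`` marks samples whose raw
    difference was negative (measurement noise) and was set to 0.
    Accepts scalars or arrays.
    """
    stcc_a = np.asarray(stcc, dtype=float)
    sicc_a = np.asarray(sicc, dtype=float)
    if np.any(np.isnan(stcc_a)) or np.any(np.isnan(sicc_a)):
        raise MissingDataError("STCC and SICC must both be measured")
    if np.any(stcc_a < 0) or np.any(sicc_a < 0):
        raise ValidationError("carbon contents must be non-negative")
    raw = stcc_a - sicc_a
    clamped = raw < 0
    socc = np.where(clamped, 0.0, raw)
    if socc.ndim == 0:
        return float(socc), bool(clamped)
    return socc, clamped


def layer_density(content, sdw_g, ring_volume_cm3, thickness_cm):
    """Area density of one layer, kg m^-2.

    ``content`` is a mass fraction; ``sdw_g / ring_volume_cm3`` realises
    bulk density × soil volume fraction in g cm^-3.
    """
    content_a = np.asarray(content, dtype=float)
    v = np.asarray(ring_volume_cm3, dtype=float)
    sdw = np.asarray(sdw_g, dtype=float)
    w = np.asarray(thickness_cm, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("ring volume must be positive")
    if np.any(sdw <= 0):
        raise ValidationError("soil dry weight must be positive")
    if np.any(w <= 0):
        raise ValidationError("layer thickness must be positive")
    if np.any(content_a < 0) or np.any(content_a > 1):
        raise ValidationError("content must be a mass fraction in [0, 1]")
    dens = content_a * (sdw / v) * w * UNIT_CONVERSION_KG_M2
    if dens.ndim == 0:
        return float(dens)
    return dens


@dataclass(frozen=True)
class SoilProfileDensity:
    """Integrated per-plot soil densities over the sampled profile."""

    plot_id: str
    socd_kg_m2: float
    stnd_kg_m2: float
    layers_present: int
    complete_to_1m: bool
    n_clamped: int = 0


def _layer_sample_densities(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SOCD/STND (kg m^-2) with the clamping rule applied."""
    socc, clamped = organic_carbon_content(
        samples["stcc"].to_numpy(), samples["sicc"].to_numpy()
    )
    w = samples["layer_index"].map(LAYER_THICKNESS_CM).to_numpy()
    out = samples[["plot_id", "replicate", "layer_index"]].copy()
    out["socd"] = layer_density(socc, samples["sdw_g"].to_numpy(), samples["ring_volume_cm3"].to_numpy(), w)
    out["stnd"] = layer_density(
        samples["stnc"].to_numpy(), samples["sdw_g"].to_numpy(), samples["ring_volume_cm3"].to_numpy(), w
    )
    out["clamped"] = np.asarray(clamped, dtype=bool)
    return out


def layer_mean_densities(samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean layer densities per (plot_id, layer_index).

    Columns: ``plot_id, layer_index, socd, stnd, n_replicates, n_clamped``.
    """
    if len(samples) == 0:
        raise MissingDataError("no soil samples given")
    per_sample = _layer_sample_densities(samples)
    grouped = (
        per_sample.groupby(["plot_id", "layer_index"], as_index=False)
        .agg(
            socd=("socd", "mean"),
            stnd=("stnd", "mean"),
            n_replicates=("socd", "size"),
            n_clamped=("clamped", "sum"),
        )
    )
    return grouped


def profile_density(samples: pd.DataFrame) -> SoilProfileDensity:
    """Integrate one plot's samples to plot-level SOCD and STND.

    Layer densities are averaged over available replicates, then summed over
    the layers present.
    """
    if len(samples) == 0:
        raise MissingDataError("profile_density needs at least one sample")
    plot_ids = samples["plot_id"].unique()
    if len(plot_ids) > 1:
        raise ValidationError(f"samples span multiple plots: {sorted(plot_ids)}")
    means = layer_mean_densities(samples)
    layers = set(means["layer_index"])
    return SoilProfileDensity(
        plot_id=str(plot_ids[0]),
        socd_kg_m2=float(means["socd"].sum()),
        stnd_kg_m2=float(means["stnd"].sum()),
        layers_present=len(layers),
        complete_to_1m=layers == set(range(1, N_LAYERS + 1)),
        n_clamped=int(means["n_clamped"].sum()),
    )


def profile_density_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Plot-level soil densities for every plot in a sample table.

    Columns: ``plot_id, socd_kg_m2, stnd_kg_m2, layers_present,
    complete_to_1m, n_clamped``.
    """
    means = layer_mean_densities(samples)
    rows = []
    for plot_id, grp in means.groupby("plot_id"):
        layers = set(grp["layer_index"])
        rows.append(
            {
                "plot_id": plot_id,
                "socd_kg_m2": float(grp["socd"].sum()),
                "stnd_kg_m2": float(grp["stnd"].sum()),
                "layers_present": len(layers),
                "complete_to_1m": layers == set(range(1, N_LAYERS + 1)),
                "n_clamped": int(grp["n_clamped"].sum()),
            }
        )
    return pd.DataFrame(rows)


def delta_soil_density(
    control_samples: pd.DataFrame, forested_samples: pd.DataFrame
) -> dict:
    """Forestation-induced soil deltas (forested − control), kg m^-2.

    When the two plots were cored to different depths the comparison is
    restricted to the common layer set and flagged.  Returns a dict with
    ``delta_socd, delta_stnd, common_layers, depth_mismatch``.
    """
    ctrl = layer_mean_densities(control_samples)
    fore = layer_mean_densities(forested_samples)
    merged = fore.merge(ctrl, on="layer_index", suffixes=("_f", "_c"))
    if len(merged) == 0:
        raise MissingDataError("control and forested plots share no soil layers")
    mismatch = set(ctrl["layer_index"]) != set(fore["layer_index"])
    if mismatch:
        logger.warning(
            "depth-completeness mismatch between %s and %s; comparing %d common layers",
            control_samples["plot_id"].iloc[0],
            forested_samples["plot_id"].iloc[0],
            len(merged),
        )
    return {
        "delta_socd": float((merged["socd_f"] - merged["socd_c"]).sum()),
        "delta_stnd": float((merged["stnd_f"] - merged["stnd_c"]).sum()),
        "common_layers": int(len(merged)),
        "depth_mismatch": bool(mismatch),
    }
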