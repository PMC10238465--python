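"""Two-dimensional binned response surfaces, ratio maps and sign classes.

The climate- and nitrogen-gradient views of the paired deltas are built by
binning points (plot pairs or grid cells) into a two-dimensional space —
MAT x MAP or STND x stand age — and reporting the per-cell mean response,
with n-weighted marginal profiles along each axis.  The biomass–soil
asymmetry is summarized by the cellwise ratio delta-SOCD / delta-biomass
(guarded against near-zero denominators) and by a four-way sign
classification whose two mixed-sign classes together form the
"contrasting response" fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

SIGN_CLASSES = (
    "both_increase",
    "both_decrease",
    "biomass_up_soc_down",
    "biomass_down_soc_up",
    "undefined",
)
CONTRASTING_CLASSES = ("biomass_up_soc_down", "biomass_down_soc_up")


@dataclass
class BinnedSurface:
    """Mean response over a 2-D grid of half-open bins.

    ``mean[i, j]`` is the mean of z over points with x in
    ``[x_edges[i], x_edges[i+1])`` and y in ``[y_edges[j], y_edges[j+1])``;
    empty cells are NaN.  ``n_outside`` counts points outside all bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray  # (nx, ny)
    n: np.ndarray  # (nx, ny)
    n_outside: int
    x_name: str = "x"
    y_name: str = "y"


def _bin_index(values: np.ndarray, edges: np.ndarray):
    """Half-open [lo, hi) bin assignment; -1 marks out-of-range."""
    idx = np.digitize(values, edges, right=False) - 1
    idx[(idx < 0) | (values >= edges[-1]) | np.isnan(values)] = -1
    return idx


def bin2d_surface(x, y, z, x_edges, y_edges, x_name="x", y_name="y") -> BinnedSurface:
    """Bin points into the 2-D space and average the response per cell."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValidationError("x, y, z must have equal length")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    for e in (x_edges, y_edges):
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValidationError("bin edges must be strictly increasing, length >= 2")
    ok = ~np.isnan(z)
    ix = _bin_index(x, x_edges)
    iy = _bin_index(y, y_edges)
    inside = (ix >= 0) & (iy >= 0) & ok
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    count = np.zeros((nx, ny))
    total = np.zeros((nx, ny))
    np.add.at(count, (ix[inside], iy[inside]), 1)
    np.add.at(total, (ix[inside], iy[inside]), z[inside])
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    n_outside = int((~inside & ok).sum())
    if n_outside:
        logger.info("bin2d_surface: %d points outside the bin ranges", n_outside)
    return BinnedSurface(
        x_edges=x_edges, y_edges=y_edges, mean=mean, n=count,
        n_outside=n_outside, x_name=x_name, y_name=y_name,
    )


def marginal_profiles(surface: BinnedSurface) -> tuple[np.ndarray, np.ndarray]:
    """n-weighted means collapsed along each axis.

    Returns ``(x_profile, y_profile)``: the x profile has one value per
    x interval (averaging over y), and vice versa.  Empty intervals are NaN.
    """
    n = surface.n
    total = np.where(n > 0, surface.mean * n, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_prof = np.where(n.sum(axis=1) > 0, total.sum(axis=1) / n.sum(axis=1), np.nan)
        y_prof = np.where(n.sum(axis=0) > 0, total.sum(axis=0) / n.sum(axis=0), np.nan)
    return x_prof, y_prof


def ratio_map(delta_soc, delta_biomass, epsilon: float = 0.05) -> np.ndarray:
    """Cellwise delta-SOCD / delta-biomass where the denominator is resolvable.

    Cells with ``|delta_biomass| < epsilon`` (kg C m^-2) or missing inputs
    are NaN.
    """
    soc = np.asarray(delta_soc, dtype=float)
    bio = np.asarray(delta_biomass, dtype=float)
    if soc.shape != bio.shape:
        raise ValidationError(f"field shapes differ: {soc.shape} vs {bio.shape}")
    defined = (~np.isnan(soc)) & (~np.isnan(bio)) & (np.abs(bio) >= epsilon)
    out = np.full(soc.shape, np.nan)
    out[defined] = soc[defined] / bio[defined]
    return out


@dataclass
class SignClassField:
    """Per-cell sign category and the fractions over defined cells."""

    categories: np.ndarray  # dtype object / str, same shape as inputs
    fractions: dict[str, float]
    n_defined: int

    @property
    def contrasting_fraction(self) -> float:
        return sum(self.fractions.get(c, 0.0) for c in CONTRASTING_CLASSES)


def sign_classification(delta_soc, delta_biomass) -> SignClassField:
    """Classify cells by the signs of the biomass and soil responses.

    Strict signs are used; a cell with a missing delta or an exactly zero
    delta is 'undefined' and excluded from the fractions, so every
    contrasting cell has a strictly negative ratio wherever the ratio is
    defined.
    """
    soc = np.asarray(delta_soc, dtype=float)
    bio = np.asarray(delta_biomass, dtype=float)
    if soc.shape != bio.shape:
        raise ValidationError(f"field shapes differ: {soc.shape} vs {bio.shape}")
    cat = np.full(soc.shape, "undefined", dtype=object)
    defined = (~np.isnan(soc)) & (~np.isnan(bio)) & (soc != 0) & (bio != 0)
    cat[defined & (bio > 0) & (soc > 0)] = "both_increase"
    cat[defined & (bio < 0) & (soc < 0)] = "both_decrease"
    cat[defined & (bio > 0) & (soc < 0)] = "biomass_up_soc_down"
    cat[defined & (bio < 0) & (soc > 0)] = "biomass_down_soc_up"
    n_defined = int(defined.sum())
    fractions = {}
    for c in SIGN_CLASSES[:-1]:
        fractions[c] = float((cat == c).sum() / n_defined) if n_defined else np.nan
    return SignClassField(categories=cat, fractions=fractions, n_defined=n_defined)
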