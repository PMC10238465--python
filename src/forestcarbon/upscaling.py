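"""Model-tree-ensemble upscaling and area-weighted regional carbon totals.

Plot-level forestation deltas are upscaled to the region with an ensemble of
model trees: regression trees whose internal nodes split on the predictors
(MAP, MAT, tree species, stand age, longitude, latitude) by maximum variance
reduction and whose leaves hold linear models over the continuous
predictors.  Candidate trees are randomized by bootstrap resampling and
per-tree feature subsampling; the data are split 80/20 into training and
validation once, every candidate is scored on the validation set by mean
squared error, and the 20 best members are retained.  The ensemble
prediction is the member median, which is robust to individual runaway
leaves.

Regional totals weight the simulated mean density change for species group
j in province i by the corresponding planted area:

    total = sum_ij X_ij * A_ij

with ``X_ij`` in kg C m^-2 and ``A_ij`` in km^2; since
1 kg C m^-2 km^2 = 10^6 kg C = 10^-3 Tg C, the conversion to Tg C
multiplies by 1e-3.  The density change for the residual 'other' species
group is the mean of the five major species' values.  Uncertainties come
from repeating the full split-train-predict-aggregate chain with
independent seeds and reporting sd/sqrt(n_repeats) of each total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

CONTINUOUS_PREDICTORS = ("map", "mat", "stand_age", "lon", "lat")

#: kg C m^-2 * km^2 -> Tg C
KG_M2_KM2_TO_TG = 1e-3

MAJOR_SPECIES = (
    "P_koraiensis",
    "L_gmelinii",
    "P_sylvestris",
    "P_tabuliformis",
    "Populus",
)
OTHER_GROUP = "other"


# ---------------------------------------------------------------------------
# train/validation split
# ---------------------------------------------------------------------------

def split_train_validation(n: int, fraction: float = 0.8, seed: int | None = None):
    """Disjoint, exhaustive train/validation index split, reproducible by seed."""
    if n < 10:
        raise ValidationError(f"need at least 10 samples to split, got {n}")
    if not (0 < fraction < 1):
        raise ConfigurationError("training fraction must be in (0, 1) exclusive")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Column layout of the design matrix: continuous block then species one-hots."""

    species_levels: tuple[str, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return CONTINUOUS_PREDICTORS + tuple(f"species={s}" for s in self.species_levels)

    @property
    def n_continuous(self) -> int:
        return len(CONTINUOUS_PREDICTORS)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        cols = [df[c].to_numpy(dtype=float) for c in CONTINUOUS_PREDICTORS]
        sp = df["species"].to_numpy()
        for level in self.species_levels:
            cols.append((sp == level).astype(float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# model tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    feature: int = -1
    threshold: float = math.nan
    left: "_Node | None" = None
    right: "_Node | None" = None
    # leaf payload: linear model over [1, continuous predictors]
    coef: np.ndarray | None = None
    n_samples: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _best_split(X, y, features, min_leaf):
    """Exhaustive variance-reduction split search over candidate features.

    Returns ``(feature, threshold, gain)`` or None.  Thresholds are midpoints
    between adjacent sorted values; a split is admissible when both children
    hold at least ``min_leaf`` points.
    """
    n = len(y)
    parent_sse = np.sum((y - y.mean()) ** 2)
    best = None
    best_gain = 1e-12
    for j in features:
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total, total_sq = csum[-1], csq[-1]
        # candidate split after position k (1-based size of left child)
        ks = np.arange(min_leaf, n - min_leaf + 1)
        if len(ks) == 0:
            continue
        valid = xs[ks - 1] < xs[ks]  # only between distinct values
        ks = ks[valid]
        if len(ks) == 0:
            continue
        left_sse = csq[ks - 1] - csum[ks - 1] ** 2 / ks
        nr = n - ks
        right_sum = total - csum[ks - 1]
        right_sse = (total_sq - csq[ks - 1]) - right_sum**2 / nr
        gains = parent_sse - (left_sse + right_sse)
        k_best = int(np.argmax(gains))
        if gains[k_best] > best_gain:
            best_gain = float(gains[k_best])
            k = ks[k_best]
            best = (j, float((xs[k - 1] + xs[k]) / 2.0), best_gain)
    return best


def _fit_leaf(X_cont, y):
    """Least-squares linear model on the continuous block, mean fallback."""
    n = len(y)
    if n < X_cont.shape[1] + 2 or np.allclose(y, y[0]):
        coef = np.zeros(X_cont.shape[1] + 1)
        coef[0] = y.mean()
        return coef
    A = np.column_stack([np.ones(n), X_cont])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        coef = np.zeros(X_cont.shape[1] + 1)
        coef[0] = y.mean()
    return coef


@dataclass
class ModelTree:
    """A regression tree with linear models in the leaves."""

    spec: FeatureSpec
    root: _Node = field(default=None, repr=False)
    min_leaf: int = 10
    max_depth: int = 8
    training_index: np.ndarray | None = field(default=None, repr=False)
    y_range: tuple[float, float] | None = None

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        spec: FeatureSpec,
        *,
        min_leaf: int = 10,
        max_depth: int = 8,
        rng: np.random.Generator | None = None,
        bootstrap: bool = False,
        feature_fraction: float = 1.0,
        training_index: np.ndarray | None = None,
    ) -> "ModelTree":
        """Greedy recursive partitioning with variance-reduction splits.

        ``bootstrap`` resamples the rows with replacement and
        ``feature_fraction`` subsamples the split-candidate features per
        node — the randomization knobs of the ensemble.
        """
        if min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = rng or np.random.default_rng()
        if bootstrap:
            idx = rng.integers(0, len(y), size=len(y))
            X, y = X[idx], y[idx]
        n_cont = spec.n_continuous
        n_feat = X.shape[1]
        n_sub = max(1, int(round(feature_fraction * n_feat)))

        def build(Xn, yn, depth):
            node = _Node(n_samples=len(yn))
            if depth >= max_depth or len(yn) < 2 * min_leaf or np.ptp(yn) == 0:
                node.coef = _fit_leaf(Xn[:, :n_cont], yn)
                return node
            feats = (
                np.arange(n_feat)
                if n_sub >= n_feat
                else rng.choice(n_feat, size=n_sub, replace=False)
            )
            found = _best_split(Xn, yn, feats, min_leaf)
            if found is None:
                node.coef = _fit_leaf(Xn[:, :n_cont], yn)
                return node
            j, thr, _ = found
            mask = Xn[:, j] <= thr
            node.feature, node.threshold = j, thr
            node.left = build(Xn[mask], yn[mask], depth + 1)
            node.right = build(Xn[~mask], yn[~mask], depth + 1)
            return node

        tree = cls(
            spec=spec,
            min_leaf=min_leaf,
            max_depth=max_depth,
            training_index=training_index,
            y_range=(float(y.min()), float(y.max())),
        )
        tree.root = build(X, y, 0)
        return tree

    def predict(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        """Route rows to leaves and evaluate the leaf linear models.

        ``clip=True`` limits predictions to the training response range, a
        standard safeguard against linear-leaf extrapolation on gridded
        inputs outside the fitted hull.
        """
        X = np.asarray(X, dtype=float)
        n_cont = self.spec.n_continuous
        out = np.empty(len(X))
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if len(idx) == 0:
                continue
            if node.is_leaf:
                Xc = X[idx, :n_cont]
                out[idx] = node.coef[0] + Xc @ node.coef[1:]
            else:
                mask = X[idx, node.feature] <= node.threshold
                stack.append((node.left, idx[mask]))
                stack.append((node.right, idx[~mask]))
        if clip and self.y_range is not None:
            out = np.clip(out, self.y_range[0], self.y_range[1])
        return out

    @property
    def first_split(self) -> tuple[int, float] | None:
        if self.root.is_leaf:
            return None
        return self.root.feature, self.root.threshold


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """The retained best model trees and their held-out scores."""

    members: list[ModelTree]
    member_scores: np.ndarray  # validation MSE, ascending
    train_index: np.ndarray
    validation_index: np.ndarray
    spec: FeatureSpec
    seed: int | None
    validation_r2: float

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Median of member predictions for the rows of ``df``."""
        X = self.spec.matrix(df)
        preds = np.stack([m.predict(X) for m in self.members])
        return np.median(preds, axis=0)


def train_ensemble(
    pairs: pd.DataFrame,
    response: str = "delta_biomass",
    *,
    n_candidates: int = 100,
    n_keep: int = 20,
    train_fraction: float = 0.8,
    min_leaf: int = 10,
    max_depth: int = 8,
    feature_fraction: float = 0.7,
    bootstrap: bool = True,
    selection: str = "validation",
    seed: int | None = None,
) -> EnsembleModel:
    """Train randomized model trees and retain the best members.

    ``selection='validation'`` (default) scores every candidate on the
    common 20% hold-out; ``selection='oob'`` scores each candidate on its
    own out-of-bag rows (requires ``bootstrap=True``).
    """
    if n_candidates < n_keep:
        raise ConfigurationError(
            f"n_candidates ({n_candidates}) must be >= n_keep ({n_keep})"
        )
    if selection not in ("validation", "oob"):
        raise ConfigurationError("selection must be 'validation' or 'oob'")
    if selection == "oob" and not bootstrap:
        raise ConfigurationError("out-of-bag selection requires bootstrap sampling")
    spec = FeatureSpec(species_levels=tuple(sorted(pairs["species"].unique())))
    X = spec.matrix(pairs)
    y = pairs[response].to_numpy(dtype=float)
    train_idx, val_idx = split_train_validation(len(pairs), train_fraction, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    members, scores = [], []
    for _ in range(n_candidates):
        tree_rng = np.random.default_rng(rng.integers(0, 2**31))
        if selection == "oob":
            boot = tree_rng.integers(0, len(train_idx), size=len(train_idx))
            rows = train_idx[boot]
            oob = np.setdiff1d(train_idx, rows)
            tree = ModelTree.fit(
                X[rows], y[rows], spec, min_leaf=min_leaf, max_depth=max_depth,
                rng=tree_rng, bootstrap=False, feature_fraction=feature_fraction,
                training_index=rows,
            )
            score_idx = oob if len(oob) else val_idx
        else:
            tree = ModelTree.fit(
                X[train_idx], y[train_idx], spec, min_leaf=min_leaf,
                max_depth=max_depth, rng=tree_rng, bootstrap=bootstrap,
                feature_fraction=feature_fraction, training_index=train_idx,
            )
            score_idx = val_idx
        mse = float(np.mean((tree.predict(X[score_idx]) - y[score_idx]) ** 2))
        members.append(tree)
        scores.append(mse)

    order = np.argsort(scores, kind="stable")[:n_keep]
    kept = [members[i] for i in order]
    kept_scores = np.asarray(scores)[order]
    ens_val = np.median(np.stack([m.predict(X[val_idx]) for m in kept]), axis=0)
    r2 = float(r2_score(y[val_idx], ens_val)) if len(val_idx) >= 2 else math.nan
    logger.info(
        "ensemble: kept %d/%d members, validation R^2 = %.3f", n_keep, n_candidates, r2
    )
    return EnsembleModel(
        members=kept,
        member_scores=kept_scores,
        train_index=train_idx,
        validation_index=val_idx,
        spec=spec,
        seed=seed,
        validation_r2=r2,
    )


def predict_grid(model: EnsembleModel, grid: pd.DataFrame) -> pd.Series:
    """Per-cell median ensemble prediction over the planted-forest mask.

    Unmasked cells and masked cells with incomplete predictors are set to
    NaN; the incomplete count is logged as a QC figure.
    """
    required = list(CONTINUOUS_PREDICTORS) + ["species"]
    out = pd.Series(np.nan, index=grid.index, name="delta_biomass_pred")
    mask = grid["mask"].astype(bool) if "mask" in grid.columns else pd.Series(True, index=grid.index)
    if not mask.any():
        logger.warning("predict_grid: empty planted-forest mask")
        return out
    cells = grid[mask]
    complete = cells[required].notna().all(axis=1)
    n_bad = int((~complete).sum())
    if n_bad:
        logger.warning("predict_grid: %d masked cells missing predictors", n_bad)
    cells = cells[complete]
    out.loc[cells.index] = model.predict(cells)
    return out


# ---------------------------------------------------------------------------
# aggregation (area weighting)
# ---------------------------------------------------------------------------

def province_species_means(
    grid: pd.DataFrame, predictions: pd.Series
) -> pd.DataFrame:
    """Mean predicted density change per (province, species) over valid cells."""
    df = grid.assign(pred=predictions).dropna(subset=["pred"])
    return (
        df.groupby(["province", "species"], as_index=False)
        .agg(x_kg_m2=("pred", "mean"), n_cells=("pred", "size"))
    )


def _fill_other(x_table: pd.DataFrame) -> pd.DataFrame:
    """Set the 'other' group's density to the per-province mean of the majors."""
    out = []
    for prov, grp in x_table.groupby("province"):
        grp = grp.copy()
        majors = grp[grp["species"].isin(MAJOR_SPECIES)]
        if len(majors):
            other_x = float(majors["x_kg_m2"].mean())
            if (grp["species"] == OTHER_GROUP).any():
                grp.loc[grp["species"] == OTHER_GROUP, "x_kg_m2"] = other_x
            else:
                grp = pd.concat(
                    [grp, pd.DataFrame([{"province": prov, "species": OTHER_GROUP,
                                         "x_kg_m2": other_x, "n_cells": 0}])],
                    ignore_index=True,
                )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def aggregate_totals(
    x_table: pd.DataFrame,
    area_table: pd.DataFrame,
    soc_x_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Area-weighted per-species and grand totals, Tg C.

    ``x_table`` holds biomass density changes X_ij (``province, species,
    x_kg_m2``); ``area_table`` the planted areas A_ij (``province, species,
    area_km2``, non-negative).  ``soc_x_table`` optionally supplies soil
    density changes on the same keys for TOC totals.  Missing (province,
    species) densities are treated as zero-area contributions with a
    warning.  Output rows: one per species group plus ``Total`` and
    ``Average`` (total / total area).
    """
    if (area_table["area_km2"] < 0).any():
        raise ValidationError("planted areas must be non-negative")
    x_table = _fill_other(x_table)
    merged = area_table.merge(x_table, on=["province", "species"], how="left")
    n_missing = int(merged["x_kg_m2"].isna().sum())
    if n_missing:
        logger.warning("aggregate_totals: %d area cells without a density estimate", n_missing)
    merged["x_kg_m2"] = merged["x_kg_m2"].fillna(0.0)
    merged["biomass_tg"] = merged["x_kg_m2"] * merged["area_km2"] * KG_M2_KM2_TO_TG

    if soc_x_table is not None:
        soc = _fill_other(soc_x_table.rename(columns={"x_kg_m2": "x_kg_m2"}))
        merged = merged.merge(
            soc[["province", "species", "x_kg_m2"]].rename(columns={"x_kg_m2": "soc_kg_m2"}),
            on=["province", "species"],
            how="left",
        )
        merged["soc_kg_m2"] = merged["soc_kg_m2"].fillna(0.0)
        merged["soc_tg"] = merged["soc_kg_m2"] * merged["area_km2"] * KG_M2_KM2_TO_TG
    else:
        merged["soc_tg"] = 0.0

    rows = []
    for species, grp in merged.groupby("species"):
        area = float(grp["area_km2"].sum())
        bio = float(grp["biomass_tg"].sum())
        soc_t = float(grp["soc_tg"].sum())
        rows.append(
            {
                "group": species,
                "area_km2": area,
                "biomass_total_tg": bio,
                "soc_total_tg": soc_t,
                "toc_total_tg": bio + soc_t,
                "delta_biomass_density": bio / (area * KG_M2_KM2_TO_TG) if area else math.nan,
                "delta_socd": soc_t / (area * KG_M2_KM2_TO_TG) if area else math.nan,
            }
        )
    out = pd.DataFrame(rows)
    total_area = out["area_km2"].sum()
    bio_total = out["biomass_total_tg"].sum()
    soc_total = out["soc_total_tg"].sum()
    totals = {
        "group": "Total",
        "area_km2": total_area,
        "biomass_total_tg": bio_total,
        "soc_total_tg": soc_total,
        "toc_total_tg": bio_total + soc_total,
        "delta_biomass_density": math.nan,
        "delta_socd": math.nan,
    }
    average = {
        "group": "Average",
        "area_km2": total_area,
        "biomass_total_tg": math.nan,
        "soc_total_tg": math.nan,
        "toc_total_tg": math.nan,
        "delta_biomass_density": bio_total / (total_area * KG_M2_KM2_TO_TG),
        "delta_socd": soc_total / (total_area * KG_M2_KM2_TO_TG),
    }
    out = pd.concat([out, pd.DataFrame([totals, average])], ignore_index=True)
    out["delta_tocd"] = out["delta_biomass_density"] + out["delta_socd"]
    return out


def ensemble_uncertainty(
    pairs: pd.DataFrame,
    grid: pd.DataFrame,
    area_table: pd.DataFrame,
    soc_x_table: pd.DataFrame | None = None,
    *,
    n_repeats: int = 5,
    base_seed: int = 0,
    **train_kwargs,
) -> pd.DataFrame:
    """Standard errors of the regional totals over repeated simulations.

    The full split → train → predict → aggregate chain is repeated with
    independent seeds; the reported uncertainty of each total is the sample
    standard deviation across repeats divided by sqrt(n_repeats).
    """
    if n_repeats < 2:
        raise ValidationError("need at least 2 repeats for a standard error")
    runs = []
    for r in range(n_repeats):
        model = train_ensemble(pairs, seed=base_seed + 1000 * r, **train_kwargs)
        pred = predict_grid(model, grid)
        x_tab = province_species_means(grid, pred)
        totals = aggregate_totals(x_tab, area_table, soc_x_table)
        runs.append(totals.set_index("group")[["biomass_total_tg", "soc_total_tg", "toc_total_tg",
                                               "delta_biomass_density", "delta_socd", "delta_tocd"]])
    stacked = pd.concat(runs, keys=range(n_repeats))
    mean = stacked.groupby(level=1).mean()
    se = stacked.groupby(level=1).std(ddof=1) / math.sqrt(n_repeats)
    se.columns = [f"{c}_se" for c in se.columns]
    out = mean.join(se).reset_index().rename(columns={"level_1": "group"})
    return out


# ---------------------------------------------------------------------------
# totals-report identities and headline rates
# ---------------------------------------------------------------------------

def check_totals_consistency(totals: pd.DataFrame, atol: float = 0.02) -> dict:
    """Arithmetic identity checks on a totals report (Table-1-shaped frame).

    Verifies, per species group, TOC density = biomass density + SOC density
    and TOC total = biomass total + SOC total; that the column sums of the
    per-species totals match the ``Total`` row; and that the ``Average`` row
    densities equal total / planted area.  Returns a dict of booleans plus
    the recomputed sums.
    """
    species_rows = totals[~totals["group"].isin(["Total", "Average"])]
    total_row = totals[totals["group"] == "Total"].iloc[0]
    avg_row = totals[totals["group"] == "Average"].iloc[0]

    toc_density_ok = bool(
        np.allclose(
            species_rows["delta_tocd"],
            species_rows["delta_biomass_density"] + species_rows["delta_socd"],
            atol=atol,
        )
    )
    toc_total_ok = bool(
        np.allclose(
            species_rows["toc_total_tg"],
            species_rows["biomass_total_tg"] + species_rows["soc_total_tg"],
            atol=atol,
        )
    )
    bio_sum = float(species_rows["biomass_total_tg"].sum())
    soc_sum = float(species_rows["soc_total_tg"].sum())
    toc_sum = float(species_rows["toc_total_tg"].sum())
    sums_ok = bool(
        abs(bio_sum - total_row["biomass_total_tg"]) <= atol
        and abs(soc_sum - total_row["soc_total_tg"]) <= atol
        and abs(toc_sum - total_row["toc_total_tg"]) <= atol
    )
    avg_sum = float(avg_row["delta_biomass_density"] + avg_row["delta_socd"])
    avg_ok = bool(abs(avg_sum - avg_row["delta_tocd"]) <= atol)
    return {
        "toc_density_identity": toc_density_ok,
        "toc_total_identity": toc_total_ok,
        "column_sums_match_total": sums_ok,
        "average_row_identity": avg_ok,
        "biomass_total_tg": bio_sum,
        "soc_total_tg": soc_sum,
        "toc_total_tg": toc_sum,
        "mean_toc_density_kg_m2": avg_sum,
        "all_ok": toc_density_ok and toc_total_ok and sums_ok and avg_ok,
    }


def headline_rates(
    toc_total_tg: float,
    biomass_total_tg: float,
    years: float,
    reference_sinks_pg_yr: dict[str, float] | None = None,
) -> dict:
    """Derived headline quantities of a regional totals report.

    Returns the mean annual sequestration rate (Tg C yr^-1), the biomass
    share of the total (%), and — for each named reference sink given in
    Pg C yr^-1 — the rate expressed as a percentage of that sink.
    """
    if years <= 0:
        raise ValidationError("accounting period must be positive")
    rate = toc_total_tg / years
    out = {
        "annual_rate_tg_yr": rate,
        "biomass_share_pct": 100.0 * biomass_total_tg / toc_total_tg,
    }
    for name, sink_pg in (reference_sinks_pg_yr or {}).items():
        out[f"pct_of_{name}"] = 100.0 * rate / (sink_pg * 1000.0)
    return out


def implied_area_km2(total_tg: float, mean_density_kg_m2: float) -> float:
    """Planted area implied by a total stock change and its mean density.

    Tg / (kg m^-2) = 1e9 kg / (kg m^-2) = 1e9 m^2 = 1e3 km^2 per unit ratio.
    """
    if mean_density_kg_m2 <= 0:
        raise ValidationError("mean density must be positive")
    return total_tg / mean_density_kg_m2 * 1e3
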