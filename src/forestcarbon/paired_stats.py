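"""Pair-table construction and the survey's inferential statistics.

All inference runs on control–forested pair deltas.  The toolkit covers:

* one-sample t tests of group means against zero with Benjamini–Hochberg
  false-discovery-rate control across the groups tested together;
* a random-intercept linear mixed model, ``y = b0 + b1*x + u_site + e`` with
  ``u_site ~ N(0, s_u^2)`` and ``e ~ N(0, s_e^2)``, fitted by restricted
  maximum likelihood.  The variance ratio ``lambda = s_u^2 / s_e^2`` is
  profiled: for each candidate lambda the fixed effects have a closed
  generalized-least-squares solution (the block covariance
  ``I + lambda*J`` inverts analytically per site), and a one-dimensional
  optimizer minimizes the restricted deviance over log-lambda.  A boundary
  estimate (lambda -> 0) reduces exactly to ordinary least squares and is
  flagged rather than treated as a failure;
* binned group summaries along the soil-nitrogen gradient; and
* the per-species trade-off between the biomass-accumulation rate (slope of
  delta-biomass vs stand age) and the soil-carbon response (slope of
  delta-SOCD vs background STND).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import IntegrityError, ValidationError, ConvergenceError

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLDS = (0.05, 0.01, 0.001)


def significance_stars(p_adjusted: float) -> str:
    """Map an adjusted p-value to the conventional star annotation."""
    if np.isnan(p_adjusted):
        return ""
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def build_pair_table(
    plots: pd.DataFrame,
    biomass: pd.DataFrame,
    control_biomass: pd.DataFrame,
    soil: pd.DataFrame,
) -> pd.DataFrame:
    """Join plot metadata, biomass and soil densities into the pair table.

    Parameters
    ----------
    plots
        ``plot_id, site_id, role, species, stand_age, lon, lat, mat, map,
        stnd_background`` (site covariates repeated per plot).
    biomass
        Forested-plot biomass results (``plot_id, biomass_kg_m2``).
    control_biomass
        ``plot_id, biomass_kg_m2`` for control plots (map lookups).
    soil
        Plot-level soil densities (``plot_id, socd_kg_m2, stnd_kg_m2``).

    Returns one row per forested plot with ``delta_biomass, delta_socd,
    delta_tocd`` (the last is the exact sum of the first two).  Rows missing
    any required delta are excluded; the exclusion log is attached as
    ``result.attrs["exclusions"]``.
    """
    forested = plots[plots["role"] == "forested"].copy()
    controls = plots[plots["role"] == "control"]
    if forested["plot_id"].duplicated().any():
        dupes = forested.loc[forested["plot_id"].duplicated(), "plot_id"].tolist()
        raise IntegrityError(f"duplicate forested plot_id(s): {dupes}")

    ctrl_by_site = controls.set_index("site_id")["plot_id"]
    bio_f = biomass.set_index("plot_id")["biomass_kg_m2"]
    bio_c = control_biomass.set_index("plot_id")["biomass_kg_m2"]
    soil_idx = soil.set_index("plot_id")

    rows, exclusions = [], []
    for rec in forested.itertuples():
        reason = None
        ctrl_plot = ctrl_by_site.get(rec.site_id)
        if ctrl_plot is None:
            reason = "site has no control plot"
        elif rec.plot_id not in bio_f.index:
            reason = "missing forested biomass"
        elif ctrl_plot not in bio_c.index:
            reason = "missing control biomass"
        elif rec.plot_id not in soil_idx.index:
            reason = "missing forested soil profile"
        elif ctrl_plot not in soil_idx.index:
            reason = "missing control soil profile"
        if reason is not None:
            exclusions.append({"plot_id": rec.plot_id, "site_id": rec.site_id, "reason": reason})
            continue
        d_bio = float(bio_f[rec.plot_id] - bio_c[ctrl_plot])
        d_soc = float(soil_idx.loc[rec.plot_id, "socd_kg_m2"] - soil_idx.loc[ctrl_plot, "socd_kg_m2"])
        rows.append(
            {
                "site_id": rec.site_id,
                "plot_id": rec.plot_id,
                "species": rec.species,
                "stand_age": rec.stand_age,
                "delta_biomass": d_bio,
                "delta_socd": d_soc,
                "delta_tocd": d_bio + d_soc,
                "stnd_background": float(soil_idx.loc[ctrl_plot, "stnd_kg_m2"]),
                "mat": rec.mat,
                "map": getattr(rec, "map"),
                "lon": rec.lon,
                "lat": rec.lat,
            }
        )
    if exclusions:
        logger.info("build_pair_table excluded %d forested plots", len(exclusions))
    if not rows:
        logger.warning("pair table is empty")
    out = pd.DataFrame(
        rows,
        columns=[
            "site_id", "plot_id", "species", "stand_age", "delta_biomass",
            "delta_socd", "delta_tocd", "stnd_background", "mat", "map", "lon", "lat",
        ],
    )
    out.attrs["exclusions"] = exclusions
    return out


# ---------------------------------------------------------------------------
# one-sample tests with FDR control
# ---------------------------------------------------------------------------

def one_sample_tests_fdr(groups: dict[str, np.ndarray], null: float = 0.0) -> pd.DataFrame:
    """Two-sided one-sample t tests per group with BH adjustment across groups.

    Groups with fewer than two observations or zero variance are marked
    untestable and excluded from the FDR family.  Returns a frame with
    ``group, n, mean, se, t, p_raw, p_fdr, stars, testable``.
    """
    rows = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        n = len(v)
        mean = float(np.mean(v)) if n else math.nan
        sd = float(np.std(v, ddof=1)) if n >= 2 else math.nan
        testable = n >= 2 and sd > 0
        if testable:
            t_stat, p_raw = stats.ttest_1samp(v, null)
            se = sd / math.sqrt(n)
        else:
            t_stat, p_raw, se = math.nan, math.nan, math.nan
            logger.warning("group %r untestable (n=%d, sd=%s)", label, n, sd)
        rows.append(
            {
                "group": label, "n": n, "mean": mean, "se": se,
                "t": float(t_stat) if testable else math.nan,
                "p_raw": float(p_raw) if testable else math.nan,
                "testable": testable,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = math.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        _, p_adj, _, _ = multipletests(df.loc[mask, "p_raw"], method="fdr_bh")
        df.loc[mask, "p_fdr"] = p_adj
    df["stars"] = df["p_fdr"].map(significance_stars)
    return df


# ---------------------------------------------------------------------------
# random-intercept mixed model (profile REML)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """REML fit of ``y = intercept + slope*x + u_group + e``."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ci_slope: tuple[float, float]
    random_intercept_var: float
    residual_var: float
    n_groups: int
    n_obs: int
    df_resid: float
    reml_deviance: float
    reduced_to_ols: bool = False
    trace: list = field(default_factory=list, repr=False)


def _reml_pieces(lam: float, groups: list[tuple[np.ndarray, np.ndarray]], p: int):
    """GLS normal-equation pieces and REML log-det terms for a given lambda.

    Each group's covariance (up to sigma_e^2) is ``I + lam*J`` with inverse
    ``I - (lam / (1 + lam*n)) * J`` (Sherman–Morrison).
    """
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for X, y in groups:
        n_i = len(y)
        shrink = lam / (1.0 + lam * n_i)
        sx = X.sum(axis=0)
        sy = y.sum()
        xtvx += X.T @ X - shrink * np.outer(sx, sx)
        xtvy += X.T @ y - shrink * sx * sy
        ytvy += y @ y - shrink * sy * sy
        logdet_v += math.log1p(lam * n_i)
    return xtvx, xtvy, ytvy, logdet_v


def _reml_deviance(lam, groups, p, n_total):
    xtvx, xtvy, ytvy, logdet_v = _reml_pieces(lam, groups, p)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy  # r' V^-1 r
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / (n_total - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    dev = (n_total - p) * math.log(sigma2) + logdet_v + logdet_xtvx
    return dev, beta, sigma2, xtvx


def fit_random_intercept_model(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    group: str = "site_id",
    *,
    conf_level: float = 0.95,
    lambda_bounds: tuple[float, float] = (1e-8, 1e6),
) -> MixedModelFit:
    """Fit the random-intercept model of ``response`` on ``predictor``.

    The REML criterion is minimized over ``log(lambda)`` where
    ``lambda = s_u^2 / s_e^2``; fixed effects come from closed-form GLS at
    the optimum.  Confidence intervals use a t reference with containment
    degrees of freedom ``n_obs - n_groups - 1``.
    """
    df = data[[response, predictor, group]].dropna()
    n_total = len(df)
    if df[group].nunique() < 2:
        raise ValidationError("need at least two groups for a random intercept")
    if n_total < 3:
        raise ValidationError("need at least three observations")
    x = df[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("predictor is constant; slope not identifiable")
    y_all = df[response].to_numpy(dtype=float)

    p = 2
    groups = []
    for _, g in df.groupby(group):
        Xg = np.column_stack([np.ones(len(g)), g[predictor].to_numpy(dtype=float)])
        groups.append((Xg, g[response].to_numpy(dtype=float)))
    n_groups = len(groups)

    trace = []

    def objective(log_lam):
        lam = math.exp(log_lam)
        dev = _reml_deviance(lam, groups, p, n_total)[0]
        trace.append((lam, dev))
        return dev

    lo, hi = math.log(lambda_bounds[0]), math.log(lambda_bounds[1])
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise ConvergenceError("REML optimizer failed", trace=trace)
    lam_hat = math.exp(res.x)
    # check the boundary explicitly: the profile can be monotone decreasing
    dev_zero = _reml_deviance(0.0, groups, p, n_total)[0]
    reduced = False
    if dev_zero <= res.fun + 1e-10:
        lam_hat = 0.0
        reduced = True
    dev, beta, sigma2, xtvx = _reml_deviance(lam_hat, groups, p, n_total)
    cov_beta = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov_beta))
    df_resid = max(n_total - n_groups - 1, 1)
    t_crit = stats.t.ppf(0.5 + conf_level / 2, df_resid)
    if reduced:
        logger.info("random-intercept variance at boundary; fit reduced to ordinary regression")
    return MixedModelFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        ci_slope=(float(beta[1] - t_crit * se[1]), float(beta[1] + t_crit * se[1])),
        random_intercept_var=float(lam_hat * sigma2),
        residual_var=float(sigma2),
        n_groups=n_groups,
        n_obs=n_total,
        df_resid=float(df_resid),
        reml_deviance=float(dev),
        reduced_to_ols=reduced,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# binned summaries and the species trade-off
# ---------------------------------------------------------------------------

def group_summary(
    pair_table: pd.DataFrame,
    bin_edges,
    bin_variable: str = "stnd_background",
    value_columns: tuple[str, ...] = ("delta_biomass", "delta_socd", "delta_tocd"),
) -> pd.DataFrame:
    """Per-bin mean and standard error of the carbon deltas.

    Bins are half-open ``[lo, hi)`` (a value on an interior edge joins the
    upper bin); values outside all edges are dropped with a warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing, length >= 2")
    v = pair_table[bin_variable].to_numpy(dtype=float)
    idx = np.digitize(v, edges, right=False) - 1  # [lo, hi)
    in_range = (idx >= 0) & (idx < len(edges) - 1) & (v < edges[-1])
    n_out = int((~in_range).sum())
    if n_out:
        logger.warning("group_summary: %d values outside the bin range", n_out)
    rows = []
    for b in range(len(edges) - 1):
        sel = in_range & (idx == b)
        n = int(sel.sum())
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1], "n": n}
        for col in value_columns:
            vals = pair_table.loc[sel, col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.mean(vals)) if n else math.nan
            row[f"{col}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def species_tradeoff(pair_table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Per-species biomass-accumulation vs soil-carbon-response slopes.

    For each species with at least ``min_pairs`` pairs, fits the mixed model
    of ``delta_biomass`` on ``stand_age`` and of ``delta_socd`` on
    ``stnd_background``; species represented by a single site fall back to
    ordinary least squares (flagged ``ols_fallback``).
    """
    rows = []
    for species, grp in pair_table.groupby("species"):
        if len(grp) < min_pairs:
            logger.info("species %r omitted (%d pairs < %d)", species, len(grp), min_pairs)
            continue
        fallback = grp["site_id"].nunique() < 2
        slopes = {}
        for name, (resp, pred) in {
            "biomass_age_slope": ("delta_biomass", "stand_age"),
            "socd_stnd_slope": ("delta_socd", "stnd_background"),
        }.items():
            x = grp[pred].to_numpy(dtype=float)
            y = grp[resp].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                slopes[name] = math.nan
                continue
            if fallback:
                slopes[name] = float(np.polyfit(x, y, 1)[0])
            else:
                slopes[name] = fit_random_intercept_model(grp, resp, pred).slope
        rows.append(
            {
                "species": species,
                "n_pairs": len(grp),
                "n_sites": grp["site_id"].nunique(),
                "ols_fallback": fallback,
                **slopes,
            }
        )
    return pd.DataFrame(rows)
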