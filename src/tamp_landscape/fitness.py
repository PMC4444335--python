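"""Per-replicate fitness slopes and robust per-Tamp aggregation.

The relative fitness of a lineage is the ordinary-least-squares slope of its
log2 frequency ratio versus generations (a free intercept absorbs baseline
sampling noise).  Slopes from the technical-replicate chemostats of one
biological replicate are averaged; biological replicates of one Tamp are
then screened by a replicate-variance filter and aggregated into a single
Tamp fitness.

Aggregation follows the screen's contamination-robust rule: with more than
15 biological replicates the Tamp fitness is the *mode* of a Gaussian
kernel density estimate over the replicate values — replicates whose
amplicons formed incorrectly pull the mean but not the mode — and with 15
or fewer replicates the arithmetic mean is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateFitness",
    "TampFitness",
    "fit_replicate_slope",
    "trajectories_to_slopes",
    "combine_technical",
    "normalize_to_reference",
    "variance_filter",
    "calibrate_variance_threshold",
    "kde_mode",
    "aggregate_tamp",
    "aggregate_all",
]

MODE_MIN_REPLICATES = 15  # more than this -> KDE mode, else mean


@dataclass(frozen=True)
class ReplicateFitness:
    """OLS slope of one trajectory: relative fitness per generation."""

    slope: float
    n_points: int
    residual_se: float
    status: Literal["ok", "NA"]


@dataclass(frozen=True)
class TampFitness:
    """Aggregated fitness of one Tamp under one condition."""

    tamp: str
    condition: str
    fitness: float
    se: float
    n_replicates: int
    method: Literal["mode", "mean", "none"]
    status: Literal["kept", "dropped_variance", "dropped_insufficient"]


def fit_replicate_slope(log2_ratios: Sequence[float],
                        generations: Sequence[float],
                        min_points: int = 3) -> ReplicateFitness:
    """OLS slope over the non-missing points, with a free intercept.

    Fewer than ``min_points`` usable points gives status ``NA`` (two points
    always fit perfectly; three is the minimum informative count).
    Generations must be strictly increasing.
    """
    y = np.asarray(log2_ratios, dtype=float)
    g = np.asarray(generations, dtype=float)
    if len(y) != len(g):
        raise ValueError("log2_ratios and generations differ in length")
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g = y[mask], g[mask]
    if len(g) > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("generations must be strictly increasing")
    n = len(y)
    if n < min_points:
        return ReplicateFitness(np.nan, n, np.nan, "NA")
    gbar, ybar = g.mean(), y.mean()
    sxx = float(np.sum((g - gbar) ** 2))
    if sxx == 0:
        return ReplicateFitness(np.nan, n, np.nan, "NA")
    slope = float(np.sum((g - gbar) * (y - ybar)) / sxx)
    resid = y - (ybar + slope * (g - gbar))
    dof = n - 2
    residual_se = float(np.sqrt(np.sum(resid ** 2) / dof)) if dof > 0 else 0.0
    return ReplicateFitness(slope, n, residual_se, "ok")


def trajectories_to_slopes(trajectories: pd.DataFrame,
                           min_points: int = 3,
                           include_t0: bool = True) -> pd.DataFrame:
    """Fit a slope for every row of a trajectory table.

    Trajectory values are log2 ratios relative to the first timepoint, so
    the baseline contributes the point (g=0, 0); ``include_t0=False`` drops
    it.  Returns columns ``tamp, replicate_bc, technical_replicate,
    [condition,] slope, n_points, residual_se, status``.
    """
    t_cols = sorted((c for c in trajectories.columns
                     if c.startswith("t") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    g_cols = [f"g{c[1:]}" for c in t_cols]
    has_cond = "condition" in trajectories.columns
    rows = []
    for row in trajectories.itertuples():
        y = np.array([getattr(row, c) for c in t_cols], dtype=float)
        g = np.array([getattr(row, c) for c in g_cols], dtype=float)
        if include_t0:
            y = np.concatenate([[0.0], y])
            g = np.concatenate([[0.0], g])
        fit = fit_replicate_slope(y, g, min_points=min_points)
        rec = {"tamp": row.gene, "replicate_bc": row.mer,
               "technical_replicate": row.replicate,
               "slope": fit.slope, "n_points": fit.n_points,
               "residual_se": fit.residual_se, "status": fit.status}
        if has_cond:
            rec["condition"] = row.condition
        rows.append(rec)
    return pd.DataFrame(rows)


def combine_technical(slopes: pd.DataFrame) -> pd.DataFrame:
    """Average the ok slopes of one biological replicate across chemostats.

    Input is the frame from :func:`trajectories_to_slopes`; rows are grouped
    by (Tamp, replicate barcode) and, if present, condition.  A biological
    replicate with no ok technical replicate keeps status ``NA``.
    """
    group_cols = ["tamp", "replicate_bc"]
    if "condition" in slopes.columns:
        group_cols = ["condition"] + group_cols
    rows = []
    for key, sub in slopes.groupby(group_cols, sort=True):
        ok = sub[sub["status"] == "ok"]
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        if len(ok):
            rec.update(slope=float(ok["slope"].mean()),
                       n_technical=int(len(ok)), status="ok")
        else:
            rec.update(slope=np.nan, n_technical=0, status="NA")
        rows.append(rec)
    return pd.DataFrame(rows)


def normalize_to_reference(fitness: pd.DataFrame, reference: str,
                           value_col: str = "slope",
                           key_col: str = "tamp") -> pd.DataFrame:
    """Shift fitness values so the reference strain sits exactly at 0.

    Pairwise differences are preserved; normalizing twice is a no-op.  If a
    ``condition`` column is present the reference is resolved per condition.
    Raises if the reference is absent or has no usable value.
    """
    out = fitness.copy()

    def shift(sub: pd.DataFrame) -> pd.DataFrame:
        ref = sub[sub[key_col] == reference]
        if "status" in ref.columns:
            ref = ref[ref["status"] == "ok"]
        vals = ref[value_col].dropna()
        if vals.empty:
            raise ValueError(
                f"reference {reference!r} missing or NA; cannot normalize")
        sub = sub.copy()
        sub[value_col] = sub[value_col] - float(vals.mean())
        return sub

    if "condition" in out.columns:
        parts = [shift(sub) for _, sub in out.groupby("condition", sort=True)]
        return pd.concat(parts, ignore_index=True)
    return shift(out)


def variance_filter(values: Sequence[float], sd_threshold: float = 0.05,
                    ) -> Literal["kept", "dropped_variance",
                                 "dropped_insufficient"]:
    """Flag a Tamp whose biological replicates disagree too much.

    Needs at least two usable replicate values to measure a spread;
    otherwise the Tamp is ``dropped_insufficient``.  The statistic is the
    sample standard deviation (ddof=1).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return "dropped_insufficient"
    return "dropped_variance" if float(np.std(v, ddof=1)) > sd_threshold \
        else "kept"


def calibrate_variance_threshold(replicate_fitness: pd.DataFrame,
                                 target_fraction: float = 0.2,
                                 group_cols: Sequence[str] | None = None,
                                 value_col: str = "slope") -> float:
    """Pick the SD cutoff that removes a target fraction of Tamps.

    The screen reports the *outcome* of its variance filter (about 20% of
    Tamps removed) rather than the cutoff, so the cutoff is calibrated as
    the (1 - target) quantile of per-Tamp replicate standard deviations.
    Groups default to (condition, Tamp) when a condition column is present,
    matching how the filter is applied.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    if group_cols is None:
        group_cols = (["condition", "tamp"]
                      if "condition" in replicate_fitness.columns
                      else ["tamp"])
    sds = (replicate_fitness.dropna(subset=[value_col])
           .groupby(list(group_cols))[value_col]
           .std(ddof=1).dropna())
    if sds.empty:
        raise ValueError("no groups with >= 2 replicates to calibrate on")
    return float(np.quantile(sds.to_numpy(), 1.0 - target_fraction))


def kde_mode(values: Sequence[float], grid_points: int = 512,
             bw_method: str | float = "silverman") -> float:
    """Argmax of a Gaussian KDE over the replicate values.

    The grid spans [min - h, max + h] where h is the kernel bandwidth.
    Degenerate inputs (a single value, or zero spread) return that value.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values")
    if len(v) == 1 or np.ptp(v) == 0:
        return float(v[0])
    kde = stats.gaussian_kde(v, bw_method=bw_method)
    h = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - h, v.max() + h, grid_points)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def aggregate_tamp(tamp: str, condition: str, values: Sequence[float],
                   sd_threshold: float = 0.05,
                   mode_min_replicates: int = MODE_MIN_REPLICATES,
                   bootstrap_se: bool = False,
                   n_bootstrap: int = 200,
                   rng: np.random.Generator | int = 0) -> TampFitness:
    """Variance-filter and aggregate the biological replicates of one Tamp.

    More than ``mode_min_replicates`` usable replicates: the KDE mode;
    otherwise the arithmetic mean.  SE is sample SD / sqrt(n) in both cases
    for comparability (optionally a seeded bootstrap SE of the estimator).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    status = variance_filter(v, sd_threshold)
    if status == "dropped_insufficient":
        return TampFitness(tamp, condition, np.nan, np.nan, n, "none", status)
    use_mode = n > mode_min_replicates
    estimator = kde_mode if use_mode else (lambda x: float(np.mean(x)))
    value = float(estimator(v))
    if bootstrap_se:
        r = np.random.default_rng(rng)
        boots = [estimator(r.choice(v, size=n, replace=True))
                 for _ in range(n_bootstrap)]
        se = float(np.std(boots, ddof=1))
    else:
        se = float(np.std(v, ddof=1) / np.sqrt(n))
    return TampFitness(tamp, condition, value, se, n,
                       "mode" if use_mode else "mean", status)


def aggregate_all(biological: pd.DataFrame,
                  sd_threshold: float = 0.05,
                  mode_min_replicates: int = MODE_MIN_REPLICATES,
                  value_col: str = "slope") -> pd.DataFrame:
    """Aggregate a whole biological-replicate frame to per-Tamp fitness.

    Input needs columns ``tamp``, ``condition`` (optional) and the value
    column.  Output columns mirror :class:`TampFitness`.
    """
    group_cols = ["tamp"]
    if "condition" in biological.columns:
        group_cols = ["condition", "tamp"]
    rows = []
    for key, sub in biological.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cond = key[0] if len(key) == 2 else ""
        tamp = key[-1]
        tf = aggregate_tamp(tamp, cond, sub[value_col].to_numpy(),
                            sd_threshold=sd_threshold,
                            mode_min_replicates=mode_min_replicates)
        rows.append({"tamp": tf.tamp, "condition": tf.condition,
                     "fitness": tf.fitness, "se": tf.se,
                     "n_replicates": tf.n_replicates, "method": tf.method,
                     "status": tf.status})
    return pd.DataFrame(rows)
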