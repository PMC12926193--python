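"""Cell-state trajectories from topic loadings and along-trajectory tests.

A trajectory is, by definition, the (optionally reversed) loading of one
topic, rank-transformed and scaled to [0, 100] over the cells where it is
defined (a cell mask intersected with a minimum-loading filter; all other
cells are undefined/NaN). The module provides composition and feature
summaries along the trajectory, quintile-based differential activity
between case and control cells, and the mixed-effects logistic
likelihood-ratio test of whether a topic's loadings predict donor-level
case status:

    full:    logit(P(case)) ~ loading + MTratio + nFrags + (1 | donor)
    null:    logit(P(case)) ~           MTratio + nFrags + (1 | donor)

with LRT = 2 (ll_full - ll_null) referred to chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import fit_glmm

__all__ = [
    "Trajectory",
    "trajectory_from_loading",
    "quantile_groups",
    "composition_along",
    "feature_trajectory_matrix",
    "spearman_with_trajectory",
    "quintile_differential_activity",
    "mixed_logit_topic_association",
]


@dataclass
class Trajectory:
    """Per-cell trajectory value in [0, 100]; NaN where undefined."""

    values: np.ndarray
    source_topic: int
    reversed: bool
    min_loading: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def trajectory_from_loading(
    Q: np.ndarray,
    topic: int,
    cell_mask: np.ndarray | None = None,
    reverse: bool = False,
    min_loading: float = 0.0,
) -> Trajectory:
    """Rank-percentile trajectory from one topic's loadings.

    Defined cells are those in ``cell_mask`` with loading >= min_loading;
    values are 100 * (rank - 1) / (n - 1) of the (reversed) loading, with
    ties sharing the mean rank. Rank scaling makes the trajectory invariant
    to strictly monotone transforms of the loadings.
    """
    Q = np.asarray(Q)
    if topic >= Q.shape[1]:
        raise ValueError(f"topic {topic} out of range for K={Q.shape[1]}")
    loading = Q[:, topic].astype(float)
    mask = np.ones(Q.shape[0], bool) if cell_mask is None else np.asarray(cell_mask, bool)
    defined = mask & (loading >= min_loading)
    n = int(defined.sum())
    if n < 2:
        raise ValueError(f"only {n} defined cell(s); need at least 2")
    vals = np.full(Q.shape[0], np.nan)
    x = loading[defined]
    if reverse:
        x = -x
    ranks = stats.rankdata(x, method="average")
    vals[defined] = 100.0 * (ranks - 1.0) / (n - 1.0)
    return Trajectory(
        values=vals, source_topic=topic, reversed=reverse, min_loading=min_loading
    )


def quantile_groups(traj: Trajectory, q: int = 5) -> np.ndarray:
    """Assign defined cells to q quantile bins (default quintiles), 0-based.

    Bins partition the defined cells with sizes differing by at most one
    when values are distinct; ties are assigned by stable sort order.
    """
    labels = np.full(traj.values.size, -1, dtype=int)
    idx = np.flatnonzero(traj.defined)
    order = np.argsort(traj.values[idx], kind="stable")
    n = idx.size
    # contiguous blocks of near-equal size
    edges = np.floor(np.arange(1, n + 1) * q / n - 1e-12).astype(int)
    labels[idx[order]] = edges
    return labels


def composition_along(
    traj: Trajectory,
    labels: np.ndarray,
    target,
    n_bins: int = 100,
    smooth_window: int = 0,
) -> np.ndarray:
    """Per-percentile fraction of target-labeled cells along the trajectory.

    Empty bins propagate NaN (never imputed). ``smooth_window`` applies a
    centered moving average over bins, ignoring NaNs.
    """
    idx = np.flatnonzero(traj.defined)
    if idx.size < n_bins:
        raise ValueError("need at least n_bins defined cells")
    v = traj.values[idx]
    is_target = np.asarray(labels)[idx] == target
    bins = np.minimum((v / 100.0 * n_bins).astype(int), n_bins - 1)
    num = np.bincount(bins, weights=is_target.astype(float), minlength=n_bins)
    den = np.bincount(bins, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(den > 0, num / den, np.nan)
    if smooth_window and smooth_window > 1:
        prop = _nan_moving_average(prop, smooth_window)
    return prop


def _nan_moving_average(x: np.ndarray, w: int) -> np.ndarray:
    half = w // 2
    out = np.full_like(x, np.nan, dtype=float)
    for i in range(x.size):
        seg = x[max(0, i - half) : i + half + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def feature_trajectory_matrix(
    traj: Trajectory,
    features: np.ndarray,
    feature_names: list[str] | None = None,
    n_bins: int = 100,
    var_cutoff: float = 0.8,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Binned, smoothed, variance-filtered, row-scaled feature x bin matrix.

    Features are averaged per trajectory percentile bin, smoothed with a
    centered moving average, filtered to the top (1 - var_cutoff) variance
    quantile across bins, and min-max scaled to [0, 1] per row.
    """
    F = np.atleast_2d(np.asarray(features, float).T).T  # cells x features
    idx = np.flatnonzero(traj.defined)
    v = traj.values[idx]
    bins = np.minimum((v / 100.0 * n_bins).astype(int), n_bins - 1)
    den = np.bincount(bins, minlength=n_bins).astype(float)
    binned = np.vstack(
        [
            np.bincount(bins, weights=F[idx, j], minlength=n_bins)
            / np.maximum(den, 1.0)
            for j in range(F.shape[1])
        ]
    )
    binned[:, den == 0] = np.nan
    if smooth_window and smooth_window > 1:
        binned = np.vstack([_nan_moving_average(r, smooth_window) for r in binned])
    variances = np.nanvar(binned, axis=1)
    thresh = np.quantile(variances, var_cutoff)
    keep = variances > thresh if np.any(variances > thresh) else variances >= thresh
    keep &= variances > 1e-24  # constant features never survive
    binned = binned[keep]
    lo = np.nanmin(binned, axis=1, keepdims=True)
    hi = np.nanmax(binned, axis=1, keepdims=True)
    scaled = (binned - lo) / np.maximum(hi - lo, 1e-300)
    names = (
        [feature_names[j] for j in np.flatnonzero(keep)]
        if feature_names is not None
        else list(np.flatnonzero(keep))
    )
    return pd.DataFrame(scaled, index=names, columns=np.arange(n_bins))


def spearman_with_trajectory(
    features: np.ndarray, traj: Trajectory
) -> np.ndarray:
    """Per-feature Spearman correlation with the trajectory (NaN if constant)."""
    F = np.atleast_2d(np.asarray(features, float).T).T
    idx = np.flatnonzero(traj.defined)
    v = traj.values[idx]
    out = np.full(F.shape[1], np.nan)
    for j in range(F.shape[1]):
        x = F[idx, j]
        if np.std(x) < 1e-300:
            continue
        out[j] = stats.spearmanr(x, v).statistic
    return out


def quintile_differential_activity(
    traj: Trajectory,
    features: np.ndarray,
    condition: np.ndarray,
    case_label="case",
    feature_names: list[str] | None = None,
    q: int = 5,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Differential feature activity along the trajectory.

    Group A (control) = all cells in the first quintile (both conditions);
    group B = case cells in quintiles 2..q. Per feature: Wilcoxon rank-sum
    p, Benjamini-Hochberg FDR, and log2 fold change of group means.
    """
    F = np.atleast_2d(np.asarray(features, float).T).T
    groups = quantile_groups(traj, q=q)
    cond = np.asarray(condition)
    in_a = groups == 0
    in_b = (groups > 0) & (cond == case_label)
    if in_a.sum() < min_cells or in_b.sum() < min_cells:
        raise ValueError(
            f"comparison groups too small (A={int(in_a.sum())}, B={int(in_b.sum())})"
        )
    eps = 1e-9
    p = np.empty(F.shape[1])
    lfc = np.empty(F.shape[1])
    for j in range(F.shape[1]):
        a, b = F[in_a, j], F[in_b, j]
        p[j] = stats.mannwhitneyu(b, a, alternative="two-sided").pvalue
        with np.errstate(invalid="ignore", divide="ignore"):
            # NaN for features whose group mean is negative (log2 undefined)
            lfc[j] = np.log2((b.mean() + eps) / (a.mean() + eps))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": feature_names if feature_names is not None else np.arange(F.shape[1]),
            "p": p,
            "fdr": fdr,
            "log2fc": lfc,
            "n_control": int(in_a.sum()),
            "n_case": int(in_b.sum()),
        }
    )


def mixed_logit_topic_association(
    loading: np.ndarray,
    MTratio: np.ndarray,
    nFrags: np.ndarray,
    donor: np.ndarray,
    status: np.ndarray,
    min_loading: float = 0.01,
) -> dict:
    """Mixed-effects logistic LRT of topic loading vs donor case status.

    Cells with loading <= min_loading are removed (loadings below the
    cutoff are mostly estimation noise). ``status`` is per-cell 0/1
    (constant within donor). Covariates are z-scaled; donors enter as a
    random intercept; models are fit by Laplace approximation and compared
    with a 1-df LRT. Non-convergence yields a flagged record with missing
    p, never a silent value.
    """
    loading = np.asarray(loading, float)
    keep = loading > min_loading
    y = np.asarray(status, float)[keep]
    donor_codes = pd.Categorical(np.asarray(donor)[keep]).codes.astype(np.int64)
    if len(set(y[donor_codes == c][0] for c in np.unique(donor_codes))) < 2:
        raise ValueError("need donors of both statuses")

    def zs(a):
        a = np.asarray(a, float)[keep]
        sd = a.std()
        return (a - a.mean()) / (sd if sd > 1e-12 else 1.0)

    covs = np.column_stack([zs(MTratio), zs(nFrags)])
    ones = np.ones(int(keep.sum()))
    X_full = np.column_stack([ones, zs(loading), covs])
    X_null = np.column_stack([ones, covs])
    full = fit_glmm(y, X_full, [donor_codes], family="binomial", method="laplace")
    null = fit_glmm(y, X_null, [donor_codes], family="binomial", method="laplace")
    if not (full.converged and null.converged):
        return {
            "lrt_stat": np.nan,
            "p": np.nan,
            "coef_loading": np.nan,
            "converged": False,
            "n_cells": int(keep.sum()),
        }
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return {
        "lrt_stat": stat,
        "p": float(stats.chi2.sf(stat, df=1)),
        "coef_loading": float(full.beta[1]),
        "sigma_donor": float(full.sigma[0]),
        "converged": True,
        "n_cells": int(keep.sum()),
    }
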