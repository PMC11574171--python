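"""Reliability and state-comparison statistics.

ICC(2,k) from a two-way crossed random-effects model fitted by REML on
all available cells (so unbalanced run counts are handled), per-subject
reliability of the z-scored nine-measure vectors, and the paired
vigilant-vs-drowsy one-way ANOVA with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist
from scipy.stats import f_oneway, pearsonr


class StatsError(ValueError):
    pass


class InsufficientDataError(StatsError):
    pass


@dataclass
class ICCResult:
    """ICC(2,k) with the underlying variance components.

    icc = var_subject / (var_subject + (var_run + var_error) / k_effective)
    where k_effective is the mean run count over retained subjects.
    """

    icc: float
    k_effective: float
    variance_components: Tuple[float, float, float]  # subject, run, residual
    n_subjects: int


@dataclass
class AnovaResult:
    F: float
    df: Tuple[int, int]
    p: float
    significant_bonferroni: bool


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 9) -> float:
    """Per-test threshold for a family of ``n_tests`` comparisons."""
    return alpha / n_tests


# ---------------------------------------------------------------------------
# ICC(2,k)


def _anova_type_start(table: np.ndarray) -> np.ndarray:
    """Moment-based variance-component starting values (exact REML optimum
    on balanced data when interior)."""
    n, k = table.shape
    if not np.isnan(table).any() and n > 1 and k > 1:
        row_means = table.mean(axis=1)
        col_means = table.mean(axis=0)
        grand = table.mean()
        msr = k * row_means.var(ddof=1)
        msc = n * col_means.var(ddof=1)
        resid = table - row_means[:, None] - col_means[None, :] + grand
        mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
        start = np.array([(msr - mse) / k, (msc - mse) / n, mse])
    else:
        row_means = np.nanmean(table, axis=1)
        col_means = np.nanmean(table, axis=0)
        grand = np.nanmean(table)
        resid = table - row_means[:, None] - col_means[None, :] + grand
        start = np.array([
            np.nanvar(row_means, ddof=1),
            np.nanvar(col_means, ddof=1),
            np.nanvar(resid, ddof=1),
        ])
    floor = max(np.nanvar(table) * 1e-6, 1e-12)
    return np.maximum(start, floor)


def _reml_neg2ll(logv: np.ndarray, y: np.ndarray, zty: np.ndarray,
                 zt1: np.ndarray, C: np.ndarray, n_s: int, n_r: int) -> float:
    """-2 x restricted log-likelihood (constants dropped) of the two-way
    crossed model, via the Woodbury identity on the q = n_s + n_r factors."""
    vs, vr, ve = np.exp(logv)
    N = y.size
    d = np.concatenate([np.full(n_s, vs), np.full(n_r, vr)])
    s = np.sqrt(d)
    M = ve * np.eye(n_s + n_r) + (s[:, None] * C) * s[None, :]
    try:
        cho = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_m = 2.0 * np.log(np.diag(cho[0])).sum()
    logdet_v = (N - n_s - n_r) * np.log(ve) + logdet_m

    by = s * zty
    b1 = s * zt1
    yy = float(y @ y)
    oy = float(y.sum())

    y_viy = (yy - by @ cho_solve(cho, by)) / ve
    x_vix = (N - b1 @ cho_solve(cho, b1)) / ve
    x_viy = (oy - b1 @ cho_solve(cho, by)) / ve
    if x_vix <= 0:
        return np.inf
    quad = y_viy - x_viy ** 2 / x_vix
    return logdet_v + np.log(x_vix) + quad


def icc2k(table: "pd.DataFrame | np.ndarray") -> ICCResult:
    """ICC(2,k) of a subject x run table (NaN = missing run).

    Variance components are estimated by REML for the two-way crossed
    random-effects model on all available cells; subjects with fewer than
    two runs are dropped.  On balanced data the result agrees with the
    Shrout-Fleiss mean-square formula
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise StatsError("expected a 2-D subject x run table")
    counts = np.isfinite(arr).sum(axis=1)
    keep = counts >= 2
    if keep.sum() < 2:
        raise InsufficientDataError(
            "need at least two subjects with two or more runs")
    arr = arr[keep]
    present = np.isfinite(arr)
    y_all = arr[present]
    if y_all.size == 0 or np.allclose(y_all.var(), 0.0):
        raise StatsError("degenerate table: zero total variance")

    subj_idx, run_idx = np.nonzero(present)
    n_s = arr.shape[0]
    n_r = arr.shape[1]
    y = y_all

    # scale out the magnitude so the optimizer sees O(1) variances
    scale = y.std()
    ys = y / scale

    q = n_s + n_r
    zty = np.concatenate([
        np.bincount(subj_idx, weights=ys, minlength=n_s),
        np.bincount(run_idx, weights=ys, minlength=n_r),
    ])
    zt1 = np.concatenate([
        np.bincount(subj_idx, minlength=n_s).astype(float),
        np.bincount(run_idx, minlength=n_r).astype(float),
    ])
    C = np.zeros((q, q))
    np.add.at(C, (subj_idx, n_s + run_idx), 1.0)
    C[n_s:, :n_s] = C[:n_s, n_s:].T
    C[:n_s, :n_s] = np.diag(zt1[:n_s])
    C[n_s:, n_s:] = np.diag(zt1[n_s:])

    start = np.log(_anova_type_start(arr / scale))
    args = (ys, zty, zt1, C, n_s, n_r)
    res = optimize.minimize(_reml_neg2ll, start, args=args, method="L-BFGS-B",
                            bounds=[(-30.0, 10.0)] * 3)
    res2 = optimize.minimize(_reml_neg2ll, res.x, args=args, method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-12,
                                      "maxiter": 4000})
    best = res2.x if res2.fun <= res.fun else res.x
    vs, vr, ve = np.exp(best) * scale ** 2
    k_eff = float(counts[keep].mean())
    icc = vs / (vs + (vr + ve) / k_eff)
    return ICCResult(icc=float(icc), k_effective=k_eff,
                     variance_components=(float(vs), float(vr), float(ve)),
                     n_subjects=int(n_s))


def shrout_fleiss_icc2k(table: np.ndarray) -> float:
    """Mean-square ICC(2,k) for a balanced complete table,
    (MSR - MSE)/(MSR + (MSC - MSE)/n)."""
    arr = np.asarray(table, dtype=float)
    if np.isnan(arr).any():
        raise StatsError("mean-square formula needs a complete table")
    n, k = arr.shape
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    grand = arr.mean()
    msr = k * row_means.var(ddof=1)
    msc = n * col_means.var(ddof=1)
    mse = ((arr - row_means[:, None] - col_means[None, :] + grand) ** 2
           ).sum() / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


# ---------------------------------------------------------------------------
# Within-subject reliability


def within_subject_reliability(df: pd.DataFrame,
                               measure_cols: Sequence[str],
                               subject_col: str = "subject",
                               min_overlap: int = 3
                               ) -> Tuple[pd.Series, Dict[str, float]]:
    """Per-subject between-run correlation of z-scored measure vectors.

    Each measure is centered and scaled across all rows pooled (one state
    at a time upstream).  For every subject with >= 2 runs, Pearson
    correlations of the z-scored vectors are computed for each run pair
    over their jointly non-missing measures (pairs with fewer than
    ``min_overlap`` shared measures are skipped) and averaged.

    Returns the per-subject series plus mean/median/std summary.
    """
    z = df.copy()
    for col in measure_cols:
        col_std = z[col].std(ddof=1)
        if np.isfinite(col_std) and col_std > 0:
            z[col] = (z[col] - z[col].mean()) / col_std
        else:
            z[col] = np.nan

    out = {}
    for subject, grp in z.groupby(subject_col):
        vecs = grp[list(measure_cols)].to_numpy(dtype=float)
        if vecs.shape[0] < 2:
            continue
        rs = []
        for i in range(vecs.shape[0]):
            for j in range(i + 1, vecs.shape[0]):
                both = np.isfinite(vecs[i]) & np.isfinite(vecs[j])
                if both.sum() < min_overlap:
                    continue
                a, b = vecs[i][both], vecs[j][both]
                if a.std() == 0 or b.std() == 0:
                    continue
                rs.append(pearsonr(a, b).statistic)
        if rs:
            out[subject] = float(np.mean(rs))
    series = pd.Series(out, name="within_subject_r", dtype=float)
    summary = {
        "mean": float(series.mean()) if len(series) else np.nan,
        "median": float(series.median()) if len(series) else np.nan,
        "std": float(series.std(ddof=1)) if len(series) > 1 else np.nan,
        "n_subjects": int(len(series)),
    }
    return series, summary


# ---------------------------------------------------------------------------
# Paired-state ANOVA


def paired_state_anova(vigilant: Sequence[float], drowsy: Sequence[float],
                       alpha: float = bonferroni_alpha()) -> AnovaResult:
    """Two-group one-way ANOVA on the paired per-subject state values.

    Only subjects with both state values enter (rows with a missing value
    in either vector are dropped); m complete pairs give df = (1, 2m-2).
    The significance flag applies the Bonferroni-adjusted alpha
    (0.05/9 = 0.0056 by default).
    """
    v = np.asarray(vigilant, dtype=float)
    d = np.asarray(drowsy, dtype=float)
    if v.shape != d.shape:
        raise StatsError("state vectors must be paired (equal length)")
    both = np.isfinite(v) & np.isfinite(d)
    m = int(both.sum())
    if m < 2:
        raise InsufficientDataError("need at least 2 complete subject pairs")
    res = f_oneway(v[both], d[both])
    F = float(res.statistic)
    df = (1, 2 * m - 2)
    p = float(f_dist.sf(F, *df))
    return AnovaResult(F=F, df=df, p=p, significant_bonferroni=bool(p < alpha))
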