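"""Twin intra-pair correlations and ACE/ADE variance-component models.

Phenotypic variance is decomposed into additive-genetic (A), shared
environment (C) or dominance (D), and unique environment (E) parts by
maximizing the bivariate-normal likelihood over twin pairs.  Cross-twin
covariance is a2 + c2 in MZ pairs and 0.5*a2 + c2 in DZ pairs under ACE,
and a2 + d2 versus 0.5*a2 + 0.25*d2 under ADE.  Sub-models are compared
by chi-square path-dropping and AIC; confidence intervals come from the
profile likelihood (-2LL rising by the chi-square(1) quantile, 3.841 at
95%).

The likelihood is parameterized directly in nonnegative variance
components (the squares of the path coefficients), which removes the
sign ambiguity of the path parameterization; seeded multi-starts guard
against ridge-like flat spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

LOG_2PI = math.log(2.0 * math.pi)

MODEL_COMPONENTS: Dict[str, Tuple[str, ...]] = {
    "ACE": ("a2", "c2", "e2"),
    "ADE": ("a2", "d2", "e2"),
    "AE": ("a2", "e2"),
    "CE": ("c2", "e2"),
    "E": ("e2",),
}

#: cross-twin loading of each component in (MZ, DZ) pairs
_SHARING = {"a2": (1.0, 0.5), "c2": (1.0, 1.0), "d2": (1.0, 0.25), "e2": (0.0, 0.0)}

_VE_FLOOR = 1e-6


class TwinFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class TwinPair:
    """One phenotype observation for one twin pair (one vigilance state).

    A family may contribute several rows, one per state, with the state
    carried by the vig covariate — exactly the duplication used in the
    source analysis, non-independence included.
    """

    family_id: int
    zygosity: str
    y1: float
    y2: float
    age1: float
    age2: float
    sex1: int
    sex2: int
    vig1: int
    vig2: int


@dataclass
class CorrelationResult:
    r: float
    df: int
    p_one_sided: float


@dataclass
class ProfileCI:
    lower: float
    upper: float
    lower_at_boundary: bool = False
    upper_at_boundary: bool = False


@dataclass
class VarianceComponents:
    """A fitted twin model: standardized fractions, betas, fit indices."""

    model: str
    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0
    raw_components: Dict[str, float] = field(default_factory=dict)
    total_variance: float = np.nan
    betas: Dict[str, float] = field(default_factory=dict)
    minus2LL: float = np.nan
    aic: float = np.nan
    aic_chisq: Optional[float] = None
    n_free: int = 0
    n_pairs_used: Tuple[int, int] = (0, 0)
    ci: Dict[str, ProfileCI] = field(default_factory=dict)

    def standardized(self, component: str) -> float:
        return getattr(self, component)


# ---------------------------------------------------------------------------
# Correlations and family choice


def intrapair_correlation(pairs: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of (y1, y2) over complete pairs of one zygosity,
    with df = n - 2 and a one-sided p from the t transform."""
    y1 = pd.to_numeric(pairs["y1"], errors="coerce").to_numpy(dtype=float)
    y2 = pd.to_numeric(pairs["y2"], errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(y1) & np.isfinite(y2)
    n = int(ok.sum())
    if n < 3:
        raise TwinFitError(f"need >= 3 complete pairs, got {n}")
    a, b = y1[ok], y2[ok]
    if a.std() == 0 or b.std() == 0:
        raise TwinFitError("zero variance in a twin column: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    df = n - 2
    tval = r * math.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(t_dist.sf(tval, df))
    return CorrelationResult(r=r, df=df, p_one_sided=p)


def choose_model_family(r_mz: float, r_dz: float) -> str:
    """ADE when r_mz > 2 r_dz with a nonnegative r_dz, else ACE.

    The boundary r_mz == 2 r_dz goes to ACE (AE is reachable from it by
    dropping C); a negative r_dz also defaults to ACE, since DE is
    biologically implausible and dominance cannot explain r_dz < 0.
    """
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        raise TwinFitError("need finite twin correlations")
    return "ADE" if (r_mz > 2.0 * r_dz and r_dz >= 0.0) else "ACE"


# ---------------------------------------------------------------------------
# Likelihood machinery


@dataclass
class _TwinData:
    Y: Dict[str, np.ndarray]      # zygosity -> (n, 2) phenotypes
    X: Dict[str, np.ndarray]      # zygosity -> (n, 2, p) design
    beta_names: List[str]
    n_mz: int
    n_dz: int


def _prepare(pairs: pd.DataFrame, covariates: bool,
             standardize: bool) -> _TwinData:
    cols = ["y1", "y2"] + (["age1", "age2", "sex1", "sex2", "vig1", "vig2"]
                           if covariates else [])
    df = pairs.copy()
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    complete = np.isfinite(df[cols].to_numpy(dtype=float)).all(axis=1)
    df = df.loc[complete]
    n_mz = int((df["zygosity"] == "MZ").sum())
    n_dz = int((df["zygosity"] == "DZ").sum())
    if n_mz + n_dz < 10:
        raise TwinFitError(
            f"need >= 10 complete pairs across zygosities, got {n_mz + n_dz}")

    if standardize:
        y_all = np.concatenate([df["y1"].to_numpy(), df["y2"].to_numpy()])
        mu, sd = y_all.mean(), y_all.std()
        if sd == 0:
            raise TwinFitError("zero phenotypic variance")
        df = df.assign(y1=(df["y1"] - mu) / sd, y2=(df["y2"] - mu) / sd)

    beta_names = ["intercept"] + (["age", "sex", "vig"] if covariates else [])
    Y, X = {}, {}
    for zyg in ("MZ", "DZ"):
        g = df[df["zygosity"] == zyg]
        n = len(g)
        Y[zyg] = g[["y1", "y2"]].to_numpy(dtype=float)
        design = np.ones((n, 2, len(beta_names)))
        if covariates:
            design[:, 0, 1] = g["age1"]
            design[:, 1, 1] = g["age2"]
            design[:, 0, 2] = g["sex1"]
            design[:, 1, 2] = g["sex2"]
            design[:, 0, 3] = g["vig1"]
            design[:, 1, 3] = g["vig2"]
        X[zyg] = design
    return _TwinData(Y=Y, X=X, beta_names=beta_names, n_mz=n_mz, n_dz=n_dz)


def _model_sigmas(model: str, comps: np.ndarray) -> Dict[str, np.ndarray]:
    """2x2 covariance per zygosity from the component vector."""
    names = MODEL_COMPONENTS[model]
    total = float(comps.sum())
    cov = {"MZ": 0.0, "DZ": 0.0}
    for name, v in zip(names, comps):
        w_mz, w_dz = _SHARING[name]
        cov["MZ"] += w_mz * v
        cov["DZ"] += w_dz * v
    return {z: np.array([[total, cov[z]], [cov[z], total]]) for z in ("MZ", "DZ")}


def _neg2ll_given_sigmas(data: _TwinData, sigmas: Dict[str, np.ndarray]
                         ) -> Tuple[float, np.ndarray]:
    """-2 log likelihood with the mean betas profiled out by GLS."""
    p = len(data.beta_names)
    A = np.zeros((p, p))
    b = np.zeros(p)
    invs, logdets = {}, {}
    for zyg in ("MZ", "DZ"):
        S = sigmas[zyg]
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        if det <= 0 or S[0, 0] <= 0:
            return np.inf, np.zeros(p)
        invs[zyg] = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        logdets[zyg] = math.log(det)
        X, Y = data.X[zyg], data.Y[zyg]
        if len(Y) == 0:
            continue
        A += np.einsum("nip,ij,njq->pq", X, invs[zyg], X)
        b += np.einsum("nip,ij,nj->p", X, invs[zyg], Y)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    n2ll = 0.0
    for zyg in ("MZ", "DZ"):
        Y, X = data.Y[zyg], data.X[zyg]
        if len(Y) == 0:
            continue
        R = Y - X @ beta
        quad = np.einsum("ni,ij,nj->", R, invs[zyg], R)
        n2ll += len(Y) * (2.0 * LOG_2PI + logdets[zyg]) + quad
    return float(n2ll), beta


def _neg2ll(comps: np.ndarray, model: str, data: _TwinData) -> float:
    if (comps < 0).any():
        return np.inf
    return _neg2ll_given_sigmas(data, _model_sigmas(model, comps))[0]


def _moment_start(model: str, data: _TwinData) -> np.ndarray:
    """Crude covariance-matching starting values, clipped to be feasible."""
    ys = np.concatenate([data.Y["MZ"].ravel(), data.Y["DZ"].ravel()])
    v = max(ys.var(), 1e-6)
    names = MODEL_COMPONENTS[model]
    m = len(names)
    start = np.full(m, v / m)
    return start


def fit_twin_model(pairs: pd.DataFrame, model: str, covariates: bool = True,
                   standardize: bool = True, n_starts: int = 8,
                   seed: int = 0) -> VarianceComponents:
    """Maximum-likelihood fit of one twin variance-component model.

    Parameters
    ----------
    pairs : DataFrame
        Columns family_id, zygosity (MZ/DZ), y1, y2 and, when
        ``covariates`` is on, age1/2, sex1/2, vig1/2.  Pairs missing any
        required value are dropped listwise.
    model : {"ACE", "ADE", "AE", "CE", "E"}
    standardize : bool
        z-score the phenotype over all individuals entering the fit
        (the reporting convention; components then sum to ~1).
    n_starts : int
        Seeded random multi-starts beyond the moment-based one.

    Raises
    ------
    TwinFitError
        On insufficient data or non-convergence of every start (the error
        carries the best -2LL found).
    """
    if model not in MODEL_COMPONENTS:
        raise TwinFitError(f"unknown model {model!r}")
    data = _prepare(pairs, covariates, standardize)
    names = MODEL_COMPONENTS[model]
    m = len(names)
    e_idx = names.index("e2")
    bounds = [(0.0, None)] * m
    bounds[e_idx] = (_VE_FLOOR, None)

    ys = np.concatenate([data.Y["MZ"].ravel(), data.Y["DZ"].ravel()])
    v_tot = max(ys.var(), 1e-6)
    rng = np.random.default_rng(seed)
    starts = [_moment_start(model, data)]
    for _ in range(n_starts):
        w = rng.dirichlet(np.ones(m))
        starts.append(np.maximum(w * v_tot, 1e-4))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(_neg2ll, x0, args=(model, data),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or res.success
    if best is None or not np.isfinite(best.fun):
        raise TwinFitError("twin model fit failed to produce a finite -2LL")
    if not any_success:
        # L-BFGS-B sometimes flags a line-search failure at the optimum;
        # polish with a derivative-free pass before giving up
        x0 = np.clip(best.x, [b[0] for b in bounds], None)
        polish = optimize.minimize(_neg2ll, x0, args=(model, data),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-10,
                                            "maxiter": 2000})
        if polish.fun <= best.fun + 1e-8:
            best = polish
        else:
            raise TwinFitError(
                f"twin model optimization did not converge; best -2LL {best.fun:.4f}")

    comps = np.maximum(best.x, 0.0)
    comps[e_idx] = max(comps[e_idx], _VE_FLOOR)
    n2ll, beta = _neg2ll_given_sigmas(data, _model_sigmas(model, comps))
    total = float(comps.sum())
    n_free = m + len(data.beta_names)

    fit = VarianceComponents(
        model=model,
        raw_components={n: float(v) for n, v in zip(names, comps)},
        total_variance=total,
        betas={n: float(v) for n, v in zip(data.beta_names, beta)},
        minus2LL=float(n2ll),
        aic=float(n2ll + 2 * n_free),
        n_free=n_free,
        n_pairs_used=(data.n_mz, data.n_dz),
    )
    for n, v in zip(names, comps):
        setattr(fit, n, float(v / total))
    return fit


# ---------------------------------------------------------------------------
# Saturated model (for the chi-square flavour of AIC)


def fit_saturated(pairs: pd.DataFrame, covariates: bool = True,
                  standardize: bool = True) -> Tuple[float, int]:
    """-2LL and parameter count of the saturated model: shared mean betas,
    free 2x2 covariance per zygosity (Cholesky-parameterized)."""
    data = _prepare(pairs, covariates, standardize)

    def unpack(x: np.ndarray) -> Dict[str, np.ndarray]:
        out = {}
        for i, zyg in enumerate(("MZ", "DZ")):
            l11, l21, l22 = x[3 * i:3 * i + 3]
            L = np.array([[l11, 0.0], [l21, l22]])
            out[zyg] = L @ L.T
        return out

    def obj(x: np.ndarray) -> float:
        return _neg2ll_given_sigmas(data, unpack(x))[0]

    x0 = []
    for zyg in ("MZ", "DZ"):
        Y = data.Y[zyg]
        cov = np.cov(Y.T) if len(Y) > 1 else np.eye(2)
        try:
            L = np.linalg.cholesky(cov + 1e-6 * np.eye(2))
        except np.linalg.LinAlgError:
            L = np.eye(2)
        x0.extend([L[0, 0], L[1, 0], L[1, 1]])
    bounds = [(1e-4, None), (None, None), (1e-4, None)] * 2
    res = optimize.minimize(obj, np.asarray(x0), method="L-BFGS-B", bounds=bounds)
    n_free = 6 + len(data.beta_names)
    return float(res.fun), n_free


# ---------------------------------------------------------------------------
# Model comparison and selection


@dataclass
class NestedComparison:
    full_model: str
    reduced_model: str
    chi2: float
    df: int
    p: float


def nested_comparison(full: VarianceComponents,
                      reduced: VarianceComponents,
                      tol: float = 1e-4) -> NestedComparison:
    """Likelihood-ratio test of a sub-model against the model it nests in."""
    chi2 = reduced.minus2LL - full.minus2LL
    if chi2 < -tol:
        raise TwinFitError(
            f"reduced model fits better by {-chi2:.4g}: optimizer failure, refit"
        )
    chi2 = max(chi2, 0.0)
    df = full.n_free - reduced.n_free
    if df < 0:
        raise TwinFitError("reduced model has more parameters than the full one")
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    return NestedComparison(full.model, reduced.model, float(chi2), df, p)


def select_best_model(fits: Dict[str, VarianceComponents],
                      alpha: float = 0.05
                      ) -> Tuple[VarianceComponents, List[NestedComparison]]:
    """Path-dropping selection within one family of fitted models.

    From the full ACE (or ADE) fit, dropping C (or D) and — in the ACE
    family — dropping A are tested at ``alpha``; among surviving
    two-component models the AE-vs-CE tie is broken by lower AIC, and the
    last path is then tested against the E model.  DE is never considered.
    """
    comparisons: List[NestedComparison] = []
    if "ACE" in fits:
        full = fits["ACE"]
        cands = []
        cmp_c = nested_comparison(full, fits["AE"])
        comparisons.append(cmp_c)
        if cmp_c.p > alpha:
            cands.append(fits["AE"])
        cmp_a = nested_comparison(full, fits["CE"])
        comparisons.append(cmp_a)
        if cmp_a.p > alpha:
            cands.append(fits["CE"])
        if not cands:
            return full, comparisons
        best2 = min(cands, key=lambda f: f.aic)
    elif "ADE" in fits:
        full = fits["ADE"]
        cmp_d = nested_comparison(full, fits["AE"])
        comparisons.append(cmp_d)
        if cmp_d.p > alpha:
            best2 = fits["AE"]
        else:
            return full, comparisons
    else:
        raise TwinFitError("fits must contain a full ACE or ADE model")

    cmp_e = nested_comparison(best2, fits["E"])
    comparisons.append(cmp_e)
    if cmp_e.p > alpha:
        return fits["E"], comparisons
    return best2, comparisons


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals


def _constrained_neg2ll(f: float, model: str, component: str,
                        data: _TwinData, v_start: float) -> float:
    """min -2LL subject to standardized(component) == f."""
    names = MODEL_COMPONENTS[model]
    idx = names.index(component)
    others = [i for i in range(len(names)) if i != idx]
    f = min(max(f, 1e-9), 1.0 - 1e-9)

    def build(x: np.ndarray) -> np.ndarray:
        V = x[0]
        comps = np.empty(len(names))
        comps[idx] = f * V
        rest = (1.0 - f) * V
        if len(others) == 1:
            comps[others[0]] = rest
        elif len(others) == 2:
            t = x[1]
            comps[others[0]] = t * rest
            comps[others[1]] = (1.0 - t) * rest
        return comps

    def obj(x: np.ndarray) -> float:
        return _neg2ll(build(x), model, data)

    if len(others) == 2:
        x0 = np.array([v_start, 0.5])
        bounds = [(1e-8, None), (0.0, 1.0)]
    elif len(others) == 1:
        x0 = np.array([v_start])
        bounds = [(1e-8, None)]
    else:  # single-component model: fraction is identically 1
        return _neg2ll(np.array([v_start]), model, data)
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
    return float(res.fun)


def profile_ci(pairs: pd.DataFrame, fit: VarianceComponents, component: str,
               covariates: bool = True, standardize: bool = True,
               level: float = 0.95) -> ProfileCI:
    """Profile-likelihood CI for a standardized variance fraction.

    Bounds are where -2LL rises by the chi-square(1) quantile (3.841 at
    95%) above its minimum while the total variance, the remaining
    component split and the betas are re-optimized.  The search is
    bracketed in [0, 1]; an unbracketed bound is reported at the boundary
    with a flag.
    """
    if component not in MODEL_COMPONENTS[fit.model]:
        raise TwinFitError(
            f"component {component!r} is not in model {fit.model}")
    data = _prepare(pairs, covariates, standardize)
    crit = float(chi2_dist.ppf(level, 1))
    target = fit.minus2LL + crit
    f_hat = fit.standardized(component)
    v_hat = fit.total_variance

    def g(f: float) -> float:
        return _constrained_neg2ll(f, fit.model, component, data, v_hat) - target

    if len(MODEL_COMPONENTS[fit.model]) == 1:
        return ProfileCI(1.0, 1.0, True, True)

    # lower bound
    if f_hat <= 1e-6 or g(1e-9) <= 0.0:
        lower, lo_flag = 0.0, True
    else:
        lower = float(optimize.brentq(g, 1e-9, max(f_hat, 2e-9), xtol=1e-4))
        lo_flag = False
    # upper bound
    if f_hat >= 1.0 - 1e-6 or g(1.0 - 1e-9) <= 0.0:
        upper, hi_flag = 1.0, True
    else:
        upper = float(optimize.brentq(g, min(f_hat, 1.0 - 2e-9), 1.0 - 1e-9,
                                      xtol=1e-4))
        hi_flag = False
    return ProfileCI(lower, upper, lo_flag, hi_flag)


# ---------------------------------------------------------------------------
# High-level analysis


@dataclass
class HeritabilityResult:
    r_mz: CorrelationResult
    r_dz: CorrelationResult
    family: str
    fits: Dict[str, VarianceComponents]
    best: VarianceComponents
    comparisons: List[NestedComparison]
    saturated_minus2LL: float
    saturated_n_free: int


def heritability_analysis(pairs: pd.DataFrame, covariates: bool = True,
                          alpha: float = 0.05, compute_ci: bool = True,
                          n_starts: int = 8, seed: int = 0
                          ) -> HeritabilityResult:
    """Full twin analysis of one phenotype: correlations, family choice,
    nested fits, selection, and profile CIs on the best model.

    Both AIC flavours are available downstream: ``aic`` is -2LL + 2k and
    ``aic_chisq`` is the chi-square-versus-saturated variant
    (chi2 - 2*df); they differ by a data constant and rank identically.
    """
    r_mz = intrapair_correlation(pairs[pairs["zygosity"] == "MZ"])
    r_dz = intrapair_correlation(pairs[pairs["zygosity"] == "DZ"])
    family = choose_model_family(r_mz.r, r_dz.r)

    models = [family, "AE", "E"] + (["CE"] if family == "ACE" else [])
    fits = {m: fit_twin_model(pairs, m, covariates=covariates,
                              n_starts=n_starts, seed=seed)
            for m in models}
    sat_n2ll, sat_free = fit_saturated(pairs, covariates=covariates)
    for f in fits.values():
        chi2 = max(f.minus2LL - sat_n2ll, 0.0)
        f.aic_chisq = float(chi2 - 2 * (sat_free - f.n_free))
    best, comparisons = select_best_model(fits, alpha=alpha)
    if compute_ci:
        for comp in MODEL_COMPONENTS[best.model]:
            best.ci[comp] = profile_ci(pairs, best, comp, covariates=covariates)
    return HeritabilityResult(r_mz=r_mz, r_dz=r_dz, family=family, fits=fits,
                              best=best, comparisons=comparisons,
                              saturated_minus2LL=sat_n2ll,
                              saturated_n_free=sat_free)
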