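import math

import numpy as np
import pandas as pd
import pytest

from biprkit import twin
from biprkit.synthetic import TwinCohortSpec, simulate_twin_cohort
from biprkit.twin import (
    TwinFitError,
    choose_model_family,
    fit_twin_model,
    heritability_analysis,
    intrapair_correlation,
    nested_comparison,
    profile_ci,
    select_best_model,
)

LOG_2PI = math.log(2.0 * math.pi)


def _pairs(y1, y2, zygosity="MZ"):
    n = len(y1)
    return pd.DataFrame({
        "family_id": range(n), "zygosity": [zygosity] * n,
        "y1": y1, "y2": y2,
    })


def _cohort(model, a2, cd2, e2, n_mz, n_dz, seed):
    return simulate_twin_cohort(TwinCohortSpec(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, model=model,
        a2=a2, c2_or_d2=cd2, e2=e2, seed=seed))


# ---------------------------------------------------------------------------
# intra-pair correlations


def test_correlation_identity():
    y = np.arange(10.0)
    res = intrapair_correlation(_pairs(y, y))
    assert res.r == pytest.approx(1.0)
    assert res.df == 8


def test_correlation_negation():
    y = np.arange(10.0)
    res = intrapair_correlation(_pairs(y, -y))
    assert res.r == pytest.approx(-1.0)


def test_correlation_matches_direct_formula():
    rng = np.random.default_rng(4)
    y1, y2 = rng.standard_normal(10), rng.standard_normal(10)
    res = intrapair_correlation(_pairs(y1, y2))
    # brute-force covariance / sd oracle
    oracle = (((y1 - y1.mean()) * (y2 - y2.mean())).sum()
              / np.sqrt(((y1 - y1.mean()) ** 2).sum() * ((y2 - y2.mean()) ** 2).sum()))
    assert res.r == pytest.approx(oracle, abs=1e-12)


def test_correlation_listwise_deletion():
    y1 = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
    y2 = np.array([1.1, 2.1, 3.1, 4.0, np.nan])
    res = intrapair_correlation(_pairs(y1, y2))
    assert res.df == 1  # 3 complete pairs


def test_correlation_errors():
    with pytest.raises(TwinFitError):
        intrapair_correlation(_pairs([1.0, 2.0], [1.0, 2.0]))
    with pytest.raises(TwinFitError):
        intrapair_correlation(_pairs([1.0] * 5, list(range(5))))


# ---------------------------------------------------------------------------
# family choice


@pytest.mark.parametrize("r_mz,r_dz,family", [
    (0.535, 0.221, "ADE"),   # blink-rate pattern: r_mz > 2 r_dz
    (0.625, 0.506, "ACE"),   # pupil-size pattern: r_mz < 2 r_dz
    (0.4, 0.2, "ACE"),       # exact equality -> ACE (AE reachable by dropping C)
    (0.59, -0.24, "ACE"),    # negative r_dz never triggers ADE
])
def test_choose_model_family(r_mz, r_dz, family):
    assert choose_model_family(r_mz, r_dz) == family


# ---------------------------------------------------------------------------
# likelihood fitting


def test_e_model_matches_independence_closed_form():
    rng = np.random.default_rng(0)
    y = rng.standard_normal((60, 2))
    df = _pairs(y[:, 0], y[:, 1], "MZ")
    df = pd.concat([df, _pairs(*rng.standard_normal((2, 40)), "DZ")],
                   ignore_index=True)
    fit = fit_twin_model(df, "E", covariates=False, standardize=True)
    # closed form: independent unit normals after z-scoring
    z = np.concatenate([df.y1, df.y2])
    z = (z - z.mean()) / z.std()
    closed = ((LOG_2PI + np.log(z.var()) + 1.0) * z.size)
    assert abs(fit.minus2LL - closed) < 2.0
    assert fit.e2 == pytest.approx(1.0)


def _ae_neg2ll_grid_oracle(df, a_grid, e_grid, b0_grid):
    """Brute-force -2LL of the AE model on an (a, e, b0) grid."""
    best = (np.inf, None)
    groups = []
    for zyg, w in (("MZ", 1.0), ("DZ", 0.5)):
        sub = df[df.zygosity == zyg]
        groups.append((w, sub.y1.to_numpy(), sub.y2.to_numpy()))
    for a in a_grid:
        for e in e_grid:
            v = a * a + e * e
            n2 = np.zeros_like(b0_grid)
            ok = True
            for w, y1, y2 in groups:
                c = w * a * a
                det = v * v - c * c
                if det <= 0:
                    ok = False
                    break
                r1 = y1[:, None] - b0_grid[None, :]
                r2 = y2[:, None] - b0_grid[None, :]
                quad = ((v * (r1 ** 2 + r2 ** 2) - 2 * c * r1 * r2) / det).sum(axis=0)
                n2 += len(y1) * (2 * LOG_2PI + np.log(det)) + quad
            if ok:
                i = int(np.argmin(n2))
                if n2[i] < best[0]:
                    best = (float(n2[i]), (a, e, float(b0_grid[i])))
    return best


def test_ae_fit_matches_grid_search_oracle():
    df = _cohort("AE", 0.5, 0.0, 0.5, 12, 8, seed=21)
    fit = fit_twin_model(df, "AE", covariates=False, standardize=False)

    step = 0.005
    coarse, (a0, e0, b0) = _ae_neg2ll_grid_oracle(
        df,
        np.arange(step, 1.6, step), np.arange(step, 1.6, step),
        np.arange(-0.5, 0.5 + step, step))
    # refine around the coarse optimum (still exhaustive evaluation)
    fine = 0.0002
    refined, _ = _ae_neg2ll_grid_oracle(
        df,
        np.arange(max(fine, a0 - 0.006), a0 + 0.006, fine),
        np.arange(max(fine, e0 - 0.006), e0 + 0.006, fine),
        np.arange(b0 - 0.006, b0 + 0.006, fine))
    assert abs(fit.minus2LL - refined) < 1e-3


def test_ae_parameter_recovery_large_cohort():
    df = _cohort("AE", 0.6, 0.0, 0.4, 2000, 2000, seed=13)
    fit = fit_twin_model(df, "AE", covariates=False)
    assert 0.55 <= fit.a2 <= 0.65
    assert fit.a2 + fit.e2 == pytest.approx(1.0, abs=1e-6)


def test_fractions_affine_invariant():
    df = _cohort("AE", 0.5, 0.0, 0.5, 100, 100, seed=3)
    fit1 = fit_twin_model(df, "AE", covariates=False)
    df2 = df.assign(y1=5.0 * df.y1 + 100.0, y2=5.0 * df.y2 + 100.0)
    fit2 = fit_twin_model(df2, "AE", covariates=False)
    assert fit2.a2 == pytest.approx(fit1.a2, abs=1e-4)


def test_mz_covariance_at_least_dz():
    df = _cohort("ACE", 0.4, 0.2, 0.4, 200, 200, seed=5)
    fit = fit_twin_model(df, "ACE", covariates=False)
    cov_mz = fit.raw_components["a2"] + fit.raw_components["c2"]
    cov_dz = 0.5 * fit.raw_components["a2"] + fit.raw_components["c2"]
    assert cov_mz >= cov_dz


def test_fit_with_covariates_recovers_betas():
    spec = TwinCohortSpec(n_mz_pairs=1500, n_dz_pairs=1500, model="AE",
                          a2=0.5, c2_or_d2=0.0, e2=0.5,
                          beta_age=0.05, beta_sex=0.3, beta_vig=-0.2, seed=9)
    df = simulate_twin_cohort(spec)
    fit = fit_twin_model(df, "AE", covariates=True, standardize=False)
    assert fit.betas["age"] == pytest.approx(0.05, abs=0.02)
    assert fit.betas["sex"] == pytest.approx(0.3, abs=0.1)
    assert fit.betas["vig"] == pytest.approx(-0.2, abs=0.1)


def test_insufficient_pairs_error():
    df = _cohort("AE", 0.5, 0.0, 0.5, 3, 3, seed=1).iloc[:5]
    with pytest.raises(TwinFitError):
        fit_twin_model(df, "AE", covariates=False)


# ---------------------------------------------------------------------------
# nested comparison and selection


def test_nested_self_comparison_zero():
    df = _cohort("AE", 0.5, 0.0, 0.5, 50, 50, seed=2)
    fit = fit_twin_model(df, "AE", covariates=False)
    cmp = nested_comparison(fit, fit)
    assert cmp.chi2 == 0.0 and cmp.df == 0


def test_full_never_fits_worse_than_reduced():
    df = _cohort("ACE", 0.4, 0.2, 0.4, 150, 150, seed=7)
    full = fit_twin_model(df, "ACE", covariates=False)
    for reduced_name in ("AE", "CE", "E"):
        reduced = fit_twin_model(df, reduced_name, covariates=False)
        assert reduced.minus2LL >= full.minus2LL - 1e-4


def test_ae_vs_e_power():
    df = _cohort("AE", 0.6, 0.0, 0.4, 500, 500, seed=11)
    ae = fit_twin_model(df, "AE", covariates=False)
    e = fit_twin_model(df, "E", covariates=False)
    cmp = nested_comparison(ae, e)
    assert cmp.p < 0.001


def test_dropping_true_zero_c_not_significant_majority():
    hits = 0
    reps = 40
    for s in range(reps):
        df = _cohort("AE", 0.5, 0.0, 0.5, 250, 250, seed=1000 + s)
        ace = fit_twin_model(df, "ACE", covariates=False, n_starts=2)
        ae = fit_twin_model(df, "AE", covariates=False, n_starts=2)
        if nested_comparison(ace, ae).p > 0.05:
            hits += 1
    assert hits >= int(0.75 * reps)


def test_select_e_compatible_on_pure_noise():
    df = _cohort("E", 0.0, 0.0, 1.0, 300, 300, seed=23)
    fits = {m: fit_twin_model(df, m, covariates=False, n_starts=2)
            for m in ("ACE", "AE", "CE", "E")}
    best, comparisons = select_best_model(fits)
    assert best.model == "E"


def test_select_requires_full_model():
    df = _cohort("AE", 0.5, 0.0, 0.5, 50, 50, seed=2)
    fits = {"AE": fit_twin_model(df, "AE", covariates=False)}
    with pytest.raises(TwinFitError):
        select_best_model(fits)


# ---------------------------------------------------------------------------
# profile CIs


def test_ci_width_shrinks_with_n():
    widths = []
    for n in (100, 400, 1600):
        df = _cohort("AE", 0.5, 0.0, 0.5, n, n, seed=31)
        fit = fit_twin_model(df, "AE", covariates=False, n_starts=2)
        ci = profile_ci(df, fit, "a2", covariates=False)
        widths.append(ci.upper - ci.lower)
    assert widths[0] > widths[1] > widths[2]


def test_e2_ci_contains_one_for_pure_noise():
    df = _cohort("E", 0.0, 0.0, 1.0, 150, 150, seed=37)
    fit = fit_twin_model(df, "E", covariates=False)
    ci = profile_ci(df, fit, "e2", covariates=False)
    assert ci.lower <= 1.0 <= ci.upper


def test_a2_ci_brackets_estimate():
    df = _cohort("AE", 0.5, 0.0, 0.5, 200, 200, seed=41)
    fit = fit_twin_model(df, "AE", covariates=False)
    ci = profile_ci(df, fit, "a2", covariates=False)
    assert ci.lower <= fit.a2 <= ci.upper
    assert 0.0 <= ci.lower < ci.upper <= 1.0


# ---------------------------------------------------------------------------
# end-to-end single-phenotype analysis


def test_heritability_analysis_ae_cohort():
    df = _cohort("AE", 0.6, 0.0, 0.4, 400, 400, seed=47)
    res = heritability_analysis(df, covariates=False, n_starts=2)
    assert res.best.model == "AE"
    assert 0.5 <= res.best.a2 <= 0.7
    assert res.best.ci["a2"].lower <= 0.6 <= res.best.ci["a2"].upper
    # the two AIC flavours rank the candidate models identically
    by_aic = sorted(res.fits, key=lambda m: res.fits[m].aic)
    by_chisq = sorted(res.fits, key=lambda m: res.fits[m].aic_chisq)
    assert by_aic == by_chisq
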