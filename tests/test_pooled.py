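"""Mixed-model machinery, AICc, the fate likelihood-ratio test, and the
one-sided KS test, each checked against an independent route (explicit
marginal Gaussian likelihood, closed forms, exact permutation enumeration)."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla
from scipy import optimize, stats

from nestphen.pooled import (LmmFit, RandomStructure, TestResult, aicc,
                             fit_lmm, ks_one_sided, lrt_fate, make_pooled_table)


def simulate_lmm(rng, n_groups=20, per_group=40, int_sd=3.0, slope_sd=0.1,
                 resid_sd=2.0, day_slope=0.3, fate_effect=0.0, intercept=15.0):
    rows = []
    for g in range(n_groups):
        a = rng.normal(0, int_sd)
        b = rng.normal(0, slope_sd)
        for _ in range(per_group):
            d = rng.uniform(-30, 30)
            fate = int(rng.random() < 0.4)
            gh = (intercept + a + (day_slope + b) * d + fate_effect * fate
                  + rng.normal(0, resid_sd))
            rows.append({"GH": gh, "DAY": 150 + d, "FATE": fate,
                         "stratum": f"g{g:02d}"})
    df = pd.DataFrame(rows)
    df["DAY_c"] = df["DAY"] - df["DAY"].median()
    return df


def marginal_ml_loglik_max(df, structure):
    """Independent oracle: maximize the explicit marginal Gaussian likelihood
    over variance components (log-Cholesky scale) with profiled GLS fixed
    effects."""
    y = df["GH"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["DAY_c"].to_numpy()])
    groups = [np.flatnonzero((df["stratum"] == g).to_numpy())
              for g in df["stratum"].unique()]
    q = 1 if structure is RandomStructure.INTERCEPT_ONLY else 2

    def loglik(theta):
        if q == 1:
            L = np.array([[np.exp(theta[0])]])
        else:
            L = np.array([[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]])
        G = L @ L.T
        sigma2 = np.exp(2 * theta[-1])
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        quad_parts, logdet = [], 0.0
        for idx in groups:
            Z = X[idx][:, :q]
            V = sigma2 * np.eye(len(idx)) + Z @ G @ Z.T
            c = sla.cho_factor(V)
            logdet += 2 * np.log(np.diag(c[0])).sum()
            XtVX += X[idx].T @ sla.cho_solve(c, X[idx])
            XtVy += X[idx].T @ sla.cho_solve(c, y[idx])
            quad_parts.append((idx, c))
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for idx, c in quad_parts:
            r = y[idx] - X[idx] @ beta
            quad += r @ sla.cho_solve(c, r)
        return -0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad)

    best = -np.inf
    for start in ([0.5, -0.5], [0.0, 0.0], [1.5, 0.5]):
        theta0 = np.zeros(q * (q + 1) // 2 + 1)
        theta0[0], theta0[-1] = start
        res = optimize.minimize(lambda t: -loglik(t), theta0,
                                method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-10,
                                         "xatol": 1e-8})
        best = max(best, -res.fun)
    return best


def test_single_stratum_reduces_to_ols():
    rng = np.random.default_rng(1)
    df = simulate_lmm(rng, n_groups=1, per_group=80, int_sd=0.0, slope_sd=0.0)
    fit = fit_lmm(df, RandomStructure.INTERCEPT_ONLY, target="REML")
    X = np.column_stack([np.ones(len(df)), df["DAY_c"]])
    beta = np.linalg.lstsq(X, df["GH"].to_numpy(), rcond=None)[0]
    assert fit.fixef("Intercept") == pytest.approx(beta[0], abs=1e-6)
    assert fit.fixef("DAY_c") == pytest.approx(beta[1], abs=1e-6)
    assert fit.boundary  # stratum sd estimated at the zero boundary


def test_variance_components_recovered():
    # average over replicate studies: with 20 strata a single draw's
    # between-stratum sd is itself noisy
    fits = []
    for seed in (2, 3, 4):
        rng = np.random.default_rng(seed)
        df = simulate_lmm(rng, n_groups=20, per_group=40,
                          int_sd=3.0, slope_sd=0.1, resid_sd=2.0)
        fits.append(fit_lmm(df, RandomStructure.INTERCEPT_SLOPE, target="REML"))
    assert np.mean([f.intercept_sd for f in fits]) == pytest.approx(3.0, rel=0.25)
    assert np.mean([f.slope_sd for f in fits]) == pytest.approx(0.1, rel=0.25)
    assert np.mean([f.residual_sd for f in fits]) == pytest.approx(2.0, rel=0.25)
    assert all(abs(f.intercept_slope_corr) <= 1.0 for f in fits)


@pytest.mark.parametrize("structure", list(RandomStructure))
def test_ml_loglik_matches_explicit_marginal_likelihood(structure):
    rng = np.random.default_rng(3)
    df = simulate_lmm(rng, n_groups=6, per_group=12)
    fit = fit_lmm(df, structure, target="ML")
    oracle = marginal_ml_loglik_max(df, structure)
    assert fit.loglik == pytest.approx(oracle, abs=1e-3)


def test_loglik_invariant_to_day_recentring():
    rng = np.random.default_rng(4)
    df = simulate_lmm(rng, n_groups=8, per_group=20)
    fit_a = fit_lmm(df, RandomStructure.INTERCEPT_ONLY, target="ML")
    shifted = df.copy()
    shifted["DAY_c"] = shifted["DAY_c"] + 17.0
    fit_b = fit_lmm(shifted, RandomStructure.INTERCEPT_ONLY, target="ML")
    assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-6)
    assert fit_a.fixef("DAY_c") == pytest.approx(fit_b.fixef("DAY_c"), abs=1e-6)
    assert fit_a.fixef("Intercept") != pytest.approx(fit_b.fixef("Intercept"), abs=1e-3)


def test_aicc_direct_substitution():
    fit = LmmFit(structure=RandomStructure.INTERCEPT_ONLY, target="ML",
                 include_fate=False, fixed_effects={}, intercept_sd=1.0,
                 slope_sd=None, intercept_slope_corr=None, residual_sd=1.0,
                 loglik=-100.0, n_obs=1000, n_parameters=3, boundary=False,
                 converged=True, center_day=0.0)
    assert aicc(fit) == pytest.approx(200 + 6 + 24 / 996)


def test_aicc_approaches_aic_for_large_n():
    fit = LmmFit(structure=RandomStructure.INTERCEPT_ONLY, target="ML",
                 include_fate=False, fixed_effects={}, intercept_sd=1.0,
                 slope_sd=None, intercept_slope_corr=None, residual_sd=1.0,
                 loglik=-100.0, n_obs=10**7, n_parameters=3, boundary=False,
                 converged=True, center_day=0.0)
    aic = -2 * -100.0 + 2 * 3
    assert aicc(fit) - aic < 1e-5


def test_aicc_undefined_for_tiny_n():
    fit = LmmFit(structure=RandomStructure.INTERCEPT_ONLY, target="ML",
                 include_fate=False, fixed_effects={}, intercept_sd=1.0,
                 slope_sd=None, intercept_slope_corr=None, residual_sd=1.0,
                 loglik=-1.0, n_obs=4, n_parameters=3, boundary=False,
                 converged=True, center_day=0.0)
    with pytest.raises(ValueError, match="AICc undefined"):
        aicc(fit)


def test_aicc_ordering_invariant_to_height_units():
    rng = np.random.default_rng(6)
    df_cm = simulate_lmm(rng, n_groups=12, per_group=30, slope_sd=0.1)
    df_mm = df_cm.copy()
    df_mm["GH"] = df_mm["GH"] * 10.0
    for df in (df_cm, df_mm):
        gaps = {}
        for s in RandomStructure:
            gaps[s] = aicc(fit_lmm(df, s, target="REML"))
        df.attrs["winner"] = min(gaps, key=lambda s: gaps[s])
    assert df_cm.attrs["winner"] == df_mm.attrs["winner"]


def test_lrt_identical_fits_gives_zero():
    fit = LmmFit(structure=RandomStructure.INTERCEPT_ONLY, target="ML",
                 include_fate=False, fixed_effects={}, intercept_sd=1.0,
                 slope_sd=None, intercept_slope_corr=None, residual_sd=1.0,
                 loglik=-50.0, n_obs=100, n_parameters=4, boundary=False,
                 converged=True, center_day=0.0)
    alt = LmmFit(**{**fit.__dict__, "include_fate": True, "n_parameters": 5})
    res = lrt_fate(fit, alt)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_lrt_chi_square_tail():
    null = LmmFit(structure=RandomStructure.INTERCEPT_SLOPE, target="ML",
                  include_fate=False, fixed_effects={}, intercept_sd=1.0,
                  slope_sd=0.1, intercept_slope_corr=0.0, residual_sd=1.0,
                  loglik=-100.0, n_obs=800, n_parameters=6, boundary=False,
                  converged=True, center_day=0.0)
    alt = LmmFit(**{**null.__dict__, "include_fate": True,
                    "n_parameters": 7, "loglik": -100.0 + 2.74 / 2})
    res = lrt_fate(null, alt)
    assert res.statistic == pytest.approx(2.74)
    assert round(res.p_value, 3) == 0.098


def test_lrt_requires_ml_and_nesting():
    base = dict(structure=RandomStructure.INTERCEPT_ONLY, fixed_effects={},
                intercept_sd=1.0, slope_sd=None, intercept_slope_corr=None,
                residual_sd=1.0, n_obs=100, n_parameters=4, boundary=False,
                converged=True, center_day=0.0)
    null = LmmFit(target="REML", include_fate=False, loglik=-50.0, **base)
    alt = LmmFit(target="REML", include_fate=True, loglik=-49.0, **base)
    with pytest.raises(ValueError, match="ML"):
        lrt_fate(null, alt)
    null_ml = LmmFit(target="ML", include_fate=False, loglik=-50.0, **base)
    worse_alt = LmmFit(target="ML", include_fate=True, loglik=-51.0, **base)
    with pytest.raises(RuntimeError, match="nesting"):
        lrt_fate(null_ml, worse_alt)


def exact_dplus_pvalue(hatched, failed):
    """Enumeration oracle: P(D+ >= observed) over all label assignments."""
    pooled = np.concatenate([hatched, failed])
    m, n = len(hatched), len(failed)

    def dplus(f, h):
        pts = np.unique(pooled)
        ef = np.searchsorted(np.sort(f), pts, side="right") / len(f)
        eh = np.searchsorted(np.sort(h), pts, side="right") / len(h)
        return np.max(ef - eh)

    obs = dplus(failed, hatched)
    count = 0
    for sel in itertools.combinations(range(m + n), m):
        mask = np.zeros(m + n, bool)
        mask[list(sel)] = True
        if dplus(pooled[~mask], pooled[mask]) >= obs - 1e-12:
            count += 1
    return count / comb(m + n, m)


def test_ks_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = ks_one_sided(x, x.copy())
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_ks_shift_alternative_detected():
    rng = np.random.default_rng(8)
    failed = rng.normal(10, 3, 100)
    hatched = failed + 10.0
    res = ks_one_sided(hatched, failed)
    assert res.p_value < 0.001
    # and the test is one-sided: the reversed shift is not "significant"
    rev = ks_one_sided(failed, hatched)
    assert rev.p_value > 0.5


def test_ks_exact_path_matches_enumeration_oracle():
    rng = np.random.default_rng(9)
    for m, n in [(3, 4), (5, 5), (6, 4), (7, 7)]:
        hatched = rng.normal(1.0, 1.0, m)
        failed = rng.normal(0.0, 1.0, n)
        res = ks_one_sided(hatched, failed)
        assert "exact" in res.method
        assert res.p_value == pytest.approx(
            exact_dplus_pvalue(hatched, failed), abs=1e-12)


def test_ks_statistic_agrees_with_scipy():
    rng = np.random.default_rng(10)
    hatched = rng.normal(16, 3, 40)
    failed = rng.normal(15, 3, 55)
    res = ks_one_sided(hatched, failed)
    sp = stats.ks_2samp(failed, hatched, alternative="greater")
    assert res.statistic == pytest.approx(sp.statistic, abs=1e-12)


def test_ks_empty_sample_raises():
    with pytest.raises(ValueError, match="non-empty"):
        ks_one_sided([], [1.0])


def test_make_pooled_table_centers_at_median():
    from conftest import make_nest, make_study
    from nestphen.phenology import PhenologyFit, correct_heights

    nests = [make_nest(nest_id=f"n{i}", initiation_day=100 + 3 * i,
                       measurement_day=130 + 3 * i) for i in range(5)]
    fit = PhenologyFit(site_id="A", year=2000, slope_beta_grass=0.1,
                       intercept=15.0, center_day=136.0, n_obs=5,
                       residual_sd=1.0, r_squared=0.5)
    cd = correct_heights(make_study(nests), [fit])
    table = make_pooled_table(cd)
    assert table["DAY_c"].median() == 0.0
    assert set(table["FATE"]) == {1}
    assert (table["stratum"] == "A:2000").all()
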