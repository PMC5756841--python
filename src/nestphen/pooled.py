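"""Pooled cross-study tests of grass height at successful vs failed nests.

After correcting heights to hatch date, the pooled analysis asks whether any
fate difference in grass height survives the phenology adjustment:

1. choose the null (phenology) model's random-effect structure by REML AICc —
   random intercepts per study-area:year stratum, ``(1|STUDY:YEAR)``, versus
   random intercepts and slopes for day, ``(DAY|STUDY:YEAR)``;
2. likelihood-ratio test (ML refits) for a fixed nest-fate effect added to
   the selected phenology structure, chi-square with 1 df;
3. a one-sided two-sample Kolmogorov-Smirnov test of corrected heights at
   hatched vs failed nests, alternative: grass taller at successful nests.

DAY is centered by subtracting the median day of measurement. Mixed models
are Gaussian LMMs fitted with statsmodels ``MixedLM`` (ML or REML); boundary
variance estimates are flagged, not suppressed.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from nestphen.phenology import CorrectedDataset

__all__ = ["RandomStructure", "LmmFit", "TestResult", "make_pooled_table",
           "fit_lmm", "aicc", "lrt_fate", "ks_one_sided"]


class RandomStructure(str, enum.Enum):
    INTERCEPT_ONLY = "INTERCEPT_ONLY"
    INTERCEPT_SLOPE = "INTERCEPT_SLOPE"


@dataclass
class LmmFit:
    """A fitted Gaussian linear mixed model for pooled grass heights."""

    structure: RandomStructure
    target: str                       # "ML" | "REML"
    include_fate: bool
    fixed_effects: dict               # name -> (estimate, se)
    intercept_sd: float
    slope_sd: Optional[float]
    intercept_slope_corr: Optional[float]
    residual_sd: float
    loglik: float
    n_obs: int
    n_parameters: int
    boundary: bool
    converged: bool
    center_day: float

    def fixef(self, name: str) -> float:
        return self.fixed_effects[name][0]


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class despite the name

    statistic: float
    df: object          # int for the LRT, (m, n) for KS
    p_value: float
    alternative: str
    method: str


def make_pooled_table(corrected: CorrectedDataset,
                      height_col: str = "grass_height_measured") -> pd.DataFrame:
    """Per-nest rows for the pooled LMM: GH, DAY, DAY_c, FATE, stratum.

    DAY is the ordinal day of measurement; DAY_c subtracts the pooled median
    measurement day. FATE codes failed = 0, hatched = 1. The default height
    column is the height as measured: in the mixed model phenology enters
    through DAY, so heights must be paired with the day they were measured
    (a hatch-date-corrected height belongs with the hatch date instead).
    """
    t = corrected.table
    out = pd.DataFrame({
        "GH": t[height_col].to_numpy(float),
        "DAY": t["measurement_day"].to_numpy(float),
        "FATE": (t["fate"] == "HATCHED").astype(int).to_numpy(),
        "stratum": t["site_id"].astype(str) + ":" + t["year"].astype(str),
    })
    out["DAY_c"] = out["DAY"] - float(out["DAY"].median())
    return out


def fit_lmm(data: pd.DataFrame, structure: RandomStructure = RandomStructure.INTERCEPT_ONLY,
            target: str = "REML", include_fate: bool = False) -> LmmFit:
    """Fit the pooled Gaussian mixed model of GH on centered DAY (+ FATE).

    Random effects are per stratum: intercept only, or an unstructured
    intercept+slope covariance. Optimization retries over several scipy
    methods with fixed starts, so the fit is deterministic given the data;
    non-convergence raises, and variance components estimated at the zero
    boundary set ``boundary=True`` on the result.
    """
    import statsmodels.api as sm

    structure = RandomStructure(structure)
    if target not in ("ML", "REML"):
        raise ValueError("target must be 'ML' or 'REML'")
    strata = data["stratum"].to_numpy()
    if len(np.unique(strata)) < 1:
        raise ValueError("no strata in pooled data")

    names = ["Intercept", "DAY_c"] + (["FATE"] if include_fate else [])
    exog = np.column_stack([np.ones(len(data)), data["DAY_c"].to_numpy(float)]
                           + ([data["FATE"].to_numpy(float)] if include_fate else []))
    endog = data["GH"].to_numpy(float)
    if structure is RandomStructure.INTERCEPT_ONLY:
        exog_re = np.ones((len(data), 1))
    else:
        exog_re = np.column_stack([np.ones(len(data)), data["DAY_c"].to_numpy(float)])

    if len(np.unique(strata)) == 1:
        # a single stratum cannot separate the random intercept from the fixed
        # one: the model degenerates to OLS with the variance at the boundary
        return _single_stratum_ols(endog, exog, names, structure, target, data)

    model = sm.MixedLM(endog, exog, groups=strata, exog_re=exog_re)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # fixed optimizer cascade; the best finite likelihood wins, which
        # keeps nested ML fits ordered and the whole fit deterministic.
        # Fallback methods only run while no converged optimum is in hand.
        for i, method in enumerate(("lbfgs", "powell", "bfgs", "nm", "cg")):
            try:
                r = model.fit(reml=(target == "REML"), method=method, maxiter=2000)
            except Exception:
                continue
            if r is not None and np.isfinite(r.llf):
                if result is None or r.llf > result.llf + 1e-10:
                    result = r
            if i >= 1 and result is not None and getattr(result, "converged", True):
                break
    if result is None:
        raise RuntimeError("mixed-model optimizer failed to converge "
                           f"({structure.value}, {target})")

    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    resid_sd = float(np.sqrt(result.scale))
    int_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    slope_sd = corr = None
    n_vc = 1
    if structure is RandomStructure.INTERCEPT_SLOPE:
        slope_sd = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        denom = int_sd * slope_sd
        corr = float(cov_re[0, 1] / denom) if denom > 0 else 0.0
        corr = float(np.clip(corr, -1.0, 1.0))
        n_vc = 3
    boundary = int_sd < 1e-6 * max(resid_sd, 1e-12) or \
        (slope_sd is not None and slope_sd < 1e-8 * max(resid_sd, 1e-12))

    fe = {n: (float(b), float(s))
          for n, b, s in zip(names, result.fe_params, result.bse_fe)}
    center = float(data["DAY"].median()) if "DAY" in data else 0.0
    return LmmFit(
        structure=structure, target=target, include_fate=include_fate,
        fixed_effects=fe, intercept_sd=int_sd, slope_sd=slope_sd,
        intercept_slope_corr=corr, residual_sd=resid_sd,
        loglik=float(result.llf), n_obs=len(data),
        n_parameters=len(names) + n_vc + 1,
        boundary=bool(boundary), converged=bool(getattr(result, "converged", True)),
        center_day=center,
    )


def _single_stratum_ols(endog, exog, names, structure, target, data) -> LmmFit:
    n, p = exog.shape
    beta, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    resid = endog - exog @ beta
    rss = float(resid @ resid)
    if target == "ML":
        sigma2 = rss / n
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2) + rss / sigma2)
    else:
        sigma2 = rss / (n - p)
        _, logdet_xx = np.linalg.slogdet(exog.T @ exog)
        llf = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2)
                      + logdet_xx - p * np.log(sigma2) + rss / sigma2)
    xtx_inv = np.linalg.inv(exog.T @ exog)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    fe = {nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)}
    n_vc = 1 if structure is RandomStructure.INTERCEPT_ONLY else 3
    slope_sd = None if structure is RandomStructure.INTERCEPT_ONLY else 0.0
    corr = None if structure is RandomStructure.INTERCEPT_ONLY else 0.0
    return LmmFit(structure=structure, target=target,
                  include_fate="FATE" in names, fixed_effects=fe,
                  intercept_sd=0.0, slope_sd=slope_sd,
                  intercept_slope_corr=corr,
                  residual_sd=float(np.sqrt(sigma2)), loglik=float(llf),
                  n_obs=n, n_parameters=len(names) + n_vc + 1, boundary=True,
                  converged=True,
                  center_day=float(data["DAY"].median()) if "DAY" in data else 0.0)


def aicc(fit: LmmFit) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1), k counting fixed effects,
    variance/covariance components and the residual variance."""
    k, n = fit.n_parameters, fit.n_obs
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def lrt_fate(null_fit: LmmFit, alt_fit: LmmFit) -> TestResult:
    """Likelihood-ratio test for the FATE fixed effect, chi-square df=1.

    Both fits must be ML and share structure; the alternative adds exactly
    the FATE term.
    """
    if null_fit.target != "ML" or alt_fit.target != "ML":
        raise ValueError("LRT requires ML fits of both models")
    if null_fit.include_fate or not alt_fit.include_fate:
        raise ValueError("alternative must add FATE to the FATE-free null")
    if null_fit.structure != alt_fit.structure:
        raise ValueError("null and alternative must share the random structure")
    delta = alt_fit.loglik - null_fit.loglik
    if delta < -1e-6:
        raise RuntimeError("alternative log-likelihood below the null's: "
                           "optimizer violated model nesting")
    stat = max(0.0, 2.0 * delta)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, df=1, p_value=p,
                      alternative="FATE effect != 0", method="likelihood-ratio")


def _dplus(failed: np.ndarray, hatched: np.ndarray) -> float:
    """sup_x [ECDF_failed(x) - ECDF_hatched(x)], evaluated at all pooled
    jump points (ties handled deterministically)."""
    pts = np.unique(np.concatenate([failed, hatched]))
    ef = np.searchsorted(np.sort(failed), pts, side="right") / failed.size
    eh = np.searchsorted(np.sort(hatched), pts, side="right") / hatched.size
    return float(np.max(ef - eh))


def ks_one_sided(heights_hatched, heights_failed,
                 exact_limit: int = 20) -> TestResult:
    """One-sided two-sample KS test: are hatched-nest heights stochastically
    larger than failed-nest heights?

    D+ = sup_x [ECDF_failed(x) - ECDF_hatched(x)], positive under the
    alternative. p is the asymptotic tail exp(-2 D+^2 mn/(m+n)) unless
    m + n <= ``exact_limit``, in which case it is the exact permutation
    probability over all C(m+n, m) label assignments of the pooled values.
    """
    hatched = np.asarray(heights_hatched, float)
    failed = np.asarray(heights_failed, float)
    if hatched.size == 0 or failed.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = hatched.size, failed.size
    d = _dplus(failed, hatched)

    if m + n <= exact_limit:
        pooled = np.concatenate([hatched, failed])
        idx = np.arange(m + n)
        count = 0
        for hsel in itertools.combinations(idx, m):
            hmask = np.zeros(m + n, bool)
            hmask[list(hsel)] = True
            if _dplus(pooled[~hmask], pooled[hmask]) >= d - 1e-12:
                count += 1
        p = count / comb(m + n, m)
        method = "one-sided KS (exact permutation)"
    else:
        p = float(np.exp(-2.0 * d * d * m * n / (m + n)))
        method = "one-sided KS (asymptotic)"
    return TestResult(statistic=d, df=(m, n), p_value=min(1.0, p),
                      alternative="hatched heights stochastically larger",
                      method=method)
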