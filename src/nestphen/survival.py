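"""Bayesian daily nest-survival model with interval-censored encounter data.

Model
-----
A nest alive on day t-1 survives to day t with probability S_t where
``logit(S_t) = beta0 + x' beta``; failure is absorbing. Visits are periodic,
so a nest's state between visits is unobserved. For a visit interval of L
days the exact marginal likelihood is

* survived the interval: ``prod_t S_t``
* failed within it:      ``1 - prod_t S_t``

the sum over all possible failure-day placements, because once failed the
nest stays failed. The implementation marginalizes analytically rather than
imputing latent daily states; for an absorbing failure state the two are
exactly equivalent.

Priors are independent Normal(0, prior_sd) on all coefficients (default sd
1000, i.e. vague). Sampling uses an adaptive random-walk Metropolis sampler
(Haario-style covariance adaptation during warmup, global scale tuned toward
35% acceptance), several independent chains with seeds split from a master
seed, and split-chain R-hat / effective-size diagnostics via ArviZ.

Nest success over the incubation period is the product of the 27 daily
survival probabilities; posterior success curves over a grass-height grid
carry pointwise means and 95% credible intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from nestphen.simulate import Fate, StudyDataset, VisitState

__all__ = [
    "SurvivalModelSpec", "McmcSettings", "EncounterInterval", "IntervalSet",
    "SurvivalPosterior", "build_intervals", "interval_loglik", "fit_survival",
    "success_curve",
]


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Covariate structure and priors for the daily-survival model.

    ``covariates`` are nest-level constants looked up on each record:
    ``"grass_height"`` resolves to the nest's (optionally overridden) height,
    anything else to ``NestRecord.covariates``. Continuous covariates are
    centered (not standardized) at the dataset mean so coefficients stay in
    per-unit (per-cm) scale. ``include_age``/``include_age2`` add nest age
    (days since initiation) and its square as time-varying daily terms,
    centered at the dataset mean age. Year effects, when requested, are
    year-level offsets with a shared Normal(0, sigma_year) prior and a
    half-Normal(0, 5) hyperprior on sigma_year.
    """

    covariates: tuple = ("grass_height",)
    include_age: bool = False
    include_age2: bool = False
    include_year_random_effect: bool = False
    prior_sd: float = 1000.0
    center: bool = True

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")
        if self.include_age2 and not self.include_age:
            raise ValueError("include_age2 requires include_age")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 3
    iters: int = 30_000   # kept draws per chain
    warmup: int = 20_000  # discarded adaptation draws per chain
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.iters < 1 or self.warmup < 0:
            raise ValueError("chains, iters >= 1 and warmup >= 0 required")


@dataclass
class EncounterInterval:
    """One visit-to-visit interval with its daily covariate rows.

    ``X`` has one row per day ``start_day+1 .. end_day`` and one column per
    model parameter (leading intercept column of ones).
    """

    nest_id: str
    start_day: int
    end_day: int
    outcome: str  # "SURVIVED" | "FAILED_WITHIN"
    X: np.ndarray

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ValueError(f"nest {self.nest_id}: empty interval "
                             f"[{self.start_day}, {self.end_day}]")
        if self.X.shape[0] != self.end_day - self.start_day:
            raise ValueError(f"nest {self.nest_id}: covariate rows != interval length")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


@dataclass
class IntervalSet:
    """Encounter intervals plus the design bookkeeping needed to fit/predict."""

    intervals: list
    param_names: list
    centers: dict                  # covariate name -> centering value
    n_year_levels: int = 0
    year_levels: tuple = ()
    constant_within_nest: bool = True
    observed_grass_range: Optional[tuple] = None
    mean_age: float = 0.0

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]


def build_intervals(dataset: StudyDataset, spec: SurvivalModelSpec,
                    heights: Optional[dict] = None) -> IntervalSet:
    """Convert encounter histories into visit-to-visit intervals.

    Consecutive visit pairs become intervals starting the day after the
    earlier visit; the final interval of a failed nest carries outcome
    ``FAILED_WITHIN``. ``heights`` optionally maps nest_id -> grass height
    (e.g. phenology-corrected values); by default the measured mean is used.
    """
    def height_of(nest):
        if heights is not None:
            return float(heights[nest.nest_id])
        return float(nest.grass_height_mean)

    def raw_value(nest, name):
        if name == "grass_height":
            return height_of(nest)
        try:
            return float(nest.covariates[name])
        except KeyError:
            raise KeyError(f"nest {nest.nest_id} lacks covariate {name!r}") from None

    centers = {}
    if spec.center and dataset.nests:
        for name in spec.covariates:
            centers[name] = float(np.mean([raw_value(n, name) for n in dataset.nests]))
    else:
        centers = {name: 0.0 for name in spec.covariates}

    mean_age = 0.0
    if spec.include_age:
        ages = []
        for nest in dataset.nests:
            days = [d for d, _ in nest.visits]
            ages.extend(range(days[0] + 1 - nest.initiation_day,
                              days[-1] + 1 - nest.initiation_day))
        mean_age = float(np.mean(ages)) if (spec.center and ages) else 0.0

    year_levels = tuple(sorted({n.year for n in dataset.nests})) \
        if spec.include_year_random_effect else ()

    param_names = ["beta0"] + [f"beta_{c}" for c in spec.covariates]
    if spec.include_age:
        param_names.append("beta_age")
    if spec.include_age2:
        param_names.append("beta_age2")
    param_names += [f"year_{y}" for y in year_levels]

    heights_obs = [height_of(n) for n in dataset.nests]
    grange = (min(heights_obs), max(heights_obs)) if heights_obs else None

    intervals = []
    for nest in dataset.nests:
        days = [d for d, _ in nest.visits]
        states = [VisitState(s) for _, s in nest.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"nest {nest.nest_id}: non-monotone visit days")
        if len(days) < 2:
            continue  # a single visit carries no exposure
        base = [1.0] + [raw_value(nest, c) - centers[c] for c in spec.covariates]
        for (d0, d1, s1) in zip(days[:-1], days[1:], states[1:]):
            n_days = d1 - d0
            row = np.array(base, float)
            X = np.tile(row, (n_days, 1))
            if spec.include_age:
                age = np.arange(d0 + 1, d1 + 1, dtype=float) - nest.initiation_day
                cols = [age - mean_age]
                if spec.include_age2:
                    cols.append((age - mean_age) ** 2)
                X = np.hstack([X, np.column_stack(cols)])
            if year_levels:
                yind = np.zeros((n_days, len(year_levels)))
                yind[:, year_levels.index(nest.year)] = 1.0
                X = np.hstack([X, yind])
            outcome = "FAILED_WITHIN" if s1 is VisitState.FAILED else "SURVIVED"
            intervals.append(EncounterInterval(nest.nest_id, d0, d1, outcome, X))

    return IntervalSet(
        intervals=intervals,
        param_names=param_names,
        centers=centers,
        n_year_levels=len(year_levels),
        year_levels=year_levels,
        constant_within_nest=not spec.include_age,
        observed_grass_range=grange,
        mean_age=mean_age,
    )


def _log_expit(eta: np.ndarray) -> np.ndarray:
    # log(1/(1+e^-eta)) stably
    return -np.logaddexp(0.0, -eta)


def _log1mexp(logp: np.ndarray) -> np.ndarray:
    # log(1 - e^logp) for logp < 0
    logp = np.minimum(logp, -1e-300)
    with np.errstate(divide="ignore"):
        return np.where(logp > -0.693, np.log(-np.expm1(logp)),
                        np.log1p(-np.exp(logp)))


def interval_loglik(interval: EncounterInterval, params: np.ndarray) -> float:
    """Exact marginal log-likelihood of one encounter interval.

    ``log prod_t S_t`` if the nest survived the interval, ``log(1 - prod_t
    S_t)`` if it failed within it — the analytic sum over the unobserved
    failure day, valid because failure is absorbing.
    """
    params = np.asarray(params, float)
    eta = interval.X @ params
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    logp = float(_log_expit(eta).sum())
    if interval.outcome == "SURVIVED":
        return logp
    return float(_log1mexp(np.array(logp)))


class _PackedData:
    """Vectorized likelihood over all intervals.

    When no covariate varies within an interval each interval collapses to a
    single design row plus a length, which makes one likelihood evaluation
    O(number of intervals) instead of O(number of exposure days).
    """

    def __init__(self, iset: IntervalSet):
        self.constant = iset.constant_within_nest
        self.empty = len(iset) == 0
        p = len(iset.param_names)
        if self.empty:
            return
        if self.constant:
            # all survived intervals of a nest share one design row, so they
            # collapse to (row, total exposure days); each nest contributes at
            # most one failed interval
            nest_idx: dict = {}
            rows, surv_len, fail_nest, fail_len = [], [], [], []
            for iv in iset.intervals:
                i = nest_idx.get(iv.nest_id)
                if i is None:
                    i = nest_idx[iv.nest_id] = len(rows)
                    rows.append(iv.X[0])
                    surv_len.append(0.0)
                if iv.outcome == "SURVIVED":
                    surv_len[i] += iv.n_days
                else:
                    fail_nest.append(i)
                    fail_len.append(float(iv.n_days))
            self.Xnest = np.array(rows)
            self.surv_len = np.array(surv_len)
            self.fail_nest = np.array(fail_nest, int)
            self.fail_len = np.array(fail_len)
        else:
            self.failed = np.array([iv.outcome == "FAILED_WITHIN" for iv in iset])
            self.Xall = np.vstack([iv.X for iv in iset.intervals]) \
                if len(iset) else np.zeros((0, p))
            lens = np.array([iv.n_days for iv in iset.intervals], int)
            self.starts = np.concatenate([[0], np.cumsum(lens)[:-1]])

    def loglik(self, beta: np.ndarray) -> float:
        if self.empty:
            return 0.0
        if self.constant:
            logs = _log_expit(self.Xnest @ beta)
            ll = float(self.surv_len @ logs)
            if self.fail_nest.size:
                ll += float(_log1mexp(self.fail_len * logs[self.fail_nest]).sum())
            return ll
        logs = _log_expit(self.Xall @ beta)
        logp = np.add.reduceat(logs, self.starts)
        ll = logp[~self.failed].sum()
        lf = logp[self.failed]
        if lf.size:
            ll += _log1mexp(lf).sum()
        return float(ll)


def _make_logpost(packed: _PackedData, iset: IntervalSet, spec: SurvivalModelSpec):
    n_coef = len(iset.param_names) - iset.n_year_levels
    n_year = iset.n_year_levels
    hier = spec.include_year_random_effect and n_year > 0
    prior_var = spec.prior_sd ** 2

    def logpost(theta: np.ndarray) -> float:
        beta = theta[:n_coef + n_year]
        lp = packed.loglik(beta)
        lp += -0.5 * float(beta[:n_coef] @ beta[:n_coef]) / prior_var
        if hier:
            log_sigma = theta[-1]
            sigma = np.exp(log_sigma)
            u = beta[n_coef:]
            lp += -0.5 * float(u @ u) / sigma ** 2 - n_year * log_sigma
            lp += -0.5 * sigma ** 2 / 25.0 + log_sigma  # half-N(0,5) + Jacobian
        return lp

    dim = n_coef + n_year + (1 if hier else 0)
    names = list(iset.param_names) + (["log_sigma_year"] if hier else [])
    return logpost, dim, names


@dataclass
class SurvivalPosterior:
    """Pooled post-warmup MCMC draws plus convergence diagnostics."""

    draws: np.ndarray          # (chains, kept, n_params)
    param_names: list
    warmup: int
    seed: int
    acceptance: np.ndarray     # per-chain acceptance rate
    centers: dict
    observed_grass_range: Optional[tuple]
    mean_age: float
    spec: SurvivalModelSpec
    summary_table: pd.DataFrame = field(default=None, repr=False)
    converged: bool = True

    @property
    def flat(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*kept, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def param(self, name: str) -> np.ndarray:
        return self.flat[:, self.param_names.index(name)]

    def credible_interval(self, name: str, level: float = 0.95):
        x = self.param(name)
        a = 100 * (1 - level) / 2
        return float(np.percentile(x, a)), float(np.percentile(x, 100 - a))


def _summarize(draws: np.ndarray, names: list) -> pd.DataFrame:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={n: draws[:, :, i] for i, n in enumerate(names)})
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
        rows = []
        for i, n in enumerate(names):
            x = draws[:, :, i].reshape(-1)
            rows.append({
                "parameter": n,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": float(np.percentile(x, 2.5)),
                "q50": float(np.percentile(x, 50)),
                "q97.5": float(np.percentile(x, 97.5)),
                "rhat": float(rhat_ds[n].values),
                "ess": float(ess_ds[n].values),
            })
    return pd.DataFrame(rows)


def _run_chain(logpost, dim, iters, warmup, rng, start, cov0=None):
    """Adaptive random-walk Metropolis: proposal covariance seeded from a
    Laplace approximation at the mode, then Haario adaptation plus a
    Robbins-Monro global scale targeting ~35% acceptance, frozen after warmup."""
    theta = start.copy()
    lp = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the chain start")
    total = warmup + iters
    out = np.empty((iters, dim))
    log_scale = np.log(2.38 / np.sqrt(dim))
    cov = np.eye(dim) if cov0 is None else cov0
    chol = np.linalg.cholesky(cov)
    mean_acc = 0.0
    n_acc_window = 0
    hist_mean = theta.copy()
    hist_cov = cov.copy() * 1e-2
    n_hist = 1
    accepted = 0
    for it in range(total):
        prop = theta + np.exp(log_scale) * (chol @ rng.standard_normal(dim))
        lp_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            theta, lp = prop, lp_prop
            if it >= warmup:
                accepted += 1
        elif it >= warmup:
            pass
        if it < warmup:
            # running moments for the proposal covariance
            n_hist += 1
            delta = theta - hist_mean
            hist_mean = hist_mean + delta / n_hist
            hist_cov = hist_cov + (np.outer(delta, theta - hist_mean) - hist_cov) / n_hist
            mean_acc += (1.0 if accept else 0.0)
            n_acc_window += 1
            if (it + 1) % 50 == 0:
                rate = mean_acc / n_acc_window
                log_scale += 0.5 * (rate - 0.35)
                mean_acc = 0.0
                n_acc_window = 0
                if it + 1 >= 200:
                    try:
                        chol = np.linalg.cholesky(hist_cov + 1e-10 * np.eye(dim))
                    except np.linalg.LinAlgError:
                        pass
        else:
            out[it - warmup] = theta
    acc_rate = accepted / max(iters, 1)
    return out, acc_rate


def fit_survival(dataset: StudyDataset, spec: SurvivalModelSpec,
                 mcmc: McmcSettings = McmcSettings(),
                 heights: Optional[dict] = None) -> SurvivalPosterior:
    """Sample the posterior of the daily nest-survival model.

    Chains start from a posterior-mode search with per-chain jitter; per-chain
    RNGs are split deterministically from ``mcmc.seed``. If any parameter's
    split-chain R-hat exceeds 1.1 the result is flagged (``converged=False``)
    but still returned.
    """
    iset = build_intervals(dataset, spec, heights=heights)
    packed = _PackedData(iset)
    logpost, dim, names = _make_logpost(packed, iset, spec)

    x0 = np.zeros(dim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(lambda t: -logpost(t), x0, method="Nelder-Mead",
                       options={"maxiter": 400 * dim, "xatol": 1e-4, "fatol": 1e-4})
        mode = res.x if np.isfinite(res.fun) else x0
        # Laplace curvature at the mode shapes the initial proposal; without
        # it short warmups can freeze a badly scaled covariance
        res_b = minimize(lambda t: -logpost(t), mode, method="BFGS",
                         options={"maxiter": 200})
        cov0 = np.asarray(res_b.hess_inv)
        if np.isfinite(res_b.fun) and np.isfinite(res_b.x).all():
            mode = res_b.x
        try:
            np.linalg.cholesky(cov0)
        except np.linalg.LinAlgError:
            cov0 = np.eye(dim)
        if not np.all(np.isfinite(cov0)):
            cov0 = np.eye(dim)

    scales = np.sqrt(np.diag(cov0))
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    draws = np.empty((mcmc.chains, mcmc.iters, dim))
    acc = np.empty(mcmc.chains)
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        start = mode + scales * rng.standard_normal(dim)
        draws[c], acc[c] = _run_chain(logpost, dim, mcmc.iters, mcmc.warmup,
                                      rng, start, cov0=cov0)

    summary = _summarize(draws, names)
    converged = bool((summary["rhat"] <= 1.1).all())
    return SurvivalPosterior(
        draws=draws, param_names=names, warmup=mcmc.warmup, seed=mcmc.seed,
        acceptance=acc, centers=iset.centers,
        observed_grass_range=iset.observed_grass_range, mean_age=iset.mean_age,
        spec=spec, summary_table=summary, converged=converged,
    )


def success_curve(posterior: SurvivalPosterior, grass_grid,
                  incubation_days: int = 27) -> pd.DataFrame:
    """Posterior nest success (product of daily survival over incubation)
    as a function of grass height, other covariates held at their mean.

    Returns a frame with columns ``grass_cm, mean, lo95, hi95``. Emits a
    warning (not an error) when the grid extends beyond the observed heights.
    """
    if "beta_grass_height" not in posterior.param_names:
        raise ValueError("grass_height is not a covariate of the fitted model")
    grid = np.asarray(grass_grid, float)
    rng_obs = posterior.observed_grass_range
    if rng_obs is not None and (grid.min() < rng_obs[0] or grid.max() > rng_obs[1]):
        warnings.warn("grass grid extends beyond the observed height range; "
                      "curve is an extrapolation there", UserWarning, stacklevel=2)

    b0 = posterior.param("beta0")
    bg = posterior.param("beta_grass_height")
    g_c = grid - posterior.centers.get("grass_height", 0.0)
    eta0 = b0[:, None] + bg[:, None] * g_c[None, :]  # (draws, grid)

    spec = posterior.spec
    if spec.include_age:
        # age follows its within-incubation trajectory day by day
        ages = np.arange(1, incubation_days + 1, float) - posterior.mean_age
        ba = posterior.param("beta_age")[:, None, None]
        eta = eta0[:, :, None] + ba * ages[None, None, :]
        if spec.include_age2:
            eta = eta + posterior.param("beta_age2")[:, None, None] * (ages ** 2)[None, None, :]
        log_success = _log_expit(eta).sum(axis=2)
    else:
        log_success = incubation_days * _log_expit(eta0)
    succ = np.exp(log_success)
    return pd.DataFrame({
        "grass_cm": grid,
        "mean": succ.mean(axis=0),
        "lo95": np.percentile(succ, 2.5, axis=0),
        "hi95": np.percentile(succ, 97.5, axis=0),
    })


def daily_survival_at_mean(posterior: SurvivalPosterior) -> np.ndarray:
    """Posterior draws of daily survival at mean covariate values."""
    return expit(posterior.param("beta0"))
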