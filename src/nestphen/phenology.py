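"""Per-stratum grass-growth regressions and hatch-date height correction.

For each study-area x year stratum an ordinary least-squares regression of
nest-mean measured grass height on day of measurement estimates the
within-season growth rate ``beta_grass`` (cm/day). Each nest's measured
height is then standardized to its hatch date::

    height_hatch = height_measured - (measurement_day - hatch_day) * beta_grass

which removes the timing component of the fate-date measurement protocol.
The day covariate is centered at the stratum median measurement day for
conditioning; the slope is invariant to the centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nestphen.simulate import StudyDataset

logger = logging.getLogger(__name__)

MIN_STRATUM_SIZE = 3


@dataclass(frozen=True)
class PhenologyFit:
    """OLS fit of mean grass height on measurement day within one stratum."""

    site_id: str
    year: int
    slope_beta_grass: float  # cm/day
    intercept: float         # cm, at the centering origin (stratum median day)
    center_day: float        # day the regression was centered at
    n_obs: int
    residual_sd: float
    r_squared: float

    @property
    def key(self) -> str:
        return f"{self.site_id}:{self.year}"

    def predict(self, day) -> np.ndarray:
        return self.intercept + self.slope_beta_grass * (np.asarray(day, float) - self.center_day)


@dataclass
class CorrectedDataset:
    """Hatch-date-corrected heights, one row per nest.

    Columns: nest_id, site_id, year, fate, initiation_day, hatch_day,
    measurement_day, grass_height_measured, grass_height_corrected,
    correction (corrected - measured), fit_id.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CorrectionSummary:
    mean_correction: float
    mean_abs_correction: float
    sd_abs_correction: float


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope/intercept/residual sd/R^2 of y on x via statsmodels OLS;
    degenerate spreads handled explicitly rather than as NaN."""
    import statsmodels.api as sm

    n = x.size
    if float(((x - x.mean()) ** 2).sum()) == 0.0:
        raise ValueError("all measurements on the same day; slope not estimable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = (float(v) for v in res.params)
    ssr = float(res.ssr)
    residual_sd = float(np.sqrt(ssr / (n - 2))) if n > 2 else 0.0
    tss = float(((y - y.mean()) ** 2).sum())
    tiny = np.finfo(float).eps * (float(y @ y) + 1.0)
    if tss <= tiny:
        r2 = 1.0 if ssr <= tiny else 0.0
    else:
        r2 = 1.0 - ssr / tss
    return slope, intercept, residual_sd, max(0.0, min(1.0, r2))


def fit_phenology(dataset: StudyDataset) -> list:
    """Fit height-on-day OLS independently in every stratum.

    Raises ``ValueError`` listing every stratum with fewer than
    ``MIN_STRATUM_SIZE`` usable nests — no silent pooling across strata.
    """
    groups: dict = {}
    for nest in dataset.nests:
        if nest.measurement_day is None:
            continue
        groups.setdefault(nest.stratum, []).append(nest)

    small = sorted(k for k, v in groups.items() if len(v) < MIN_STRATUM_SIZE)
    for s in dataset.strata:
        if s.key not in groups:
            small.append(s.key)
    if small:
        raise ValueError(
            "strata below the minimum of "
            f"{MIN_STRATUM_SIZE} nests: {', '.join(sorted(small))}"
        )

    fits = []
    for stratum in dataset.strata:
        nests = groups[stratum.key]
        days = np.array([n.measurement_day for n in nests], float)
        heights = np.array([n.grass_height_mean for n in nests], float)
        center = float(np.median(days))
        slope, intercept_c, resid_sd, r2 = _ols_line(days - center, heights)
        fits.append(PhenologyFit(
            site_id=stratum.site_id, year=stratum.year,
            slope_beta_grass=slope, intercept=intercept_c, center_day=center,
            n_obs=len(nests), residual_sd=resid_sd, r_squared=r2,
        ))
    return fits


def correct_heights(dataset: StudyDataset, fits: list) -> CorrectedDataset:
    """Standardize each nest's measured height to its hatch date.

    ``corrected = measured - (measurement_day - hatch_day) * slope`` using the
    nest's own stratum fit. Nests with a missing measurement day are excluded
    (and logged); measured values are never modified.
    """
    by_key = {f.key: f for f in fits}
    rows = []
    for nest in dataset.nests:
        if nest.measurement_day is None:
            logger.warning("nest %s has no measurement day; excluded from correction",
                           nest.nest_id)
            continue
        if nest.stratum not in by_key:
            raise ValueError(f"no phenology fit for stratum {nest.stratum}")
        fit = by_key[nest.stratum]
        lag = nest.measurement_day - nest.hatch_day
        corrected = nest.grass_height_mean - lag * fit.slope_beta_grass
        rows.append({
            "nest_id": nest.nest_id,
            "site_id": nest.site_id,
            "year": nest.year,
            "fate": nest.fate.value,
            "initiation_day": nest.initiation_day,
            "hatch_day": nest.hatch_day,
            "measurement_day": nest.measurement_day,
            "grass_height_measured": nest.grass_height_mean,
            "grass_height_corrected": float(corrected),
            "correction": float(corrected - nest.grass_height_mean),
            "fit_id": fit.key,
        })
    return CorrectedDataset(table=pd.DataFrame(rows))


def summarize_corrections(cd: CorrectedDataset) -> CorrectionSummary:
    """Mean correction, mean |correction| and the sd of |correction|."""
    if len(cd) == 0:
        raise ValueError("empty corrected dataset")
    c = cd.table["correction"].to_numpy()
    abs_c = np.abs(c)
    sd = float(abs_c.std(ddof=1)) if c.size > 1 else 0.0
    return CorrectionSummary(
        mean_correction=float(c.mean()),
        mean_abs_correction=float(abs_c.mean()),
        sd_abs_correction=sd,
    )


def fits_to_frame(fits: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": f.site_id, "year": f.year, "slope_cm_per_day": f.slope_beta_grass,
        "intercept_cm": f.intercept, "center_day": f.center_day,
        "n_obs": f.n_obs, "residual_sd_cm": f.residual_sd, "r_squared": f.r_squared,
    } for f in fits])
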