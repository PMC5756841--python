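import numpy as np
import pytest

from nestphen.simulate import (Fate, NestRecord, StratumTruth, StudyDataset,
                               VisitState)


def make_nest(nest_id="n1", site_id="A", year=2000, initiation_day=120,
              incubation_days=27, fate=Fate.HATCHED, end_day=None,
              visits=None, measurement_day=None, heights=(15.0,),
              true_height=None, covariates=None):
    """Hand-built NestRecord with sensible defaults for unit tests."""
    hatch = initiation_day + incubation_days
    if end_day is None:
        end_day = hatch if fate is Fate.HATCHED else hatch - 5
    if visits is None:
        state_last = VisitState.ALIVE if fate is Fate.HATCHED else VisitState.FAILED
        visits = [(initiation_day, VisitState.ALIVE), (end_day, state_last)]
    if measurement_day is None:
        measurement_day = end_day
    heights = list(heights)
    return NestRecord(
        nest_id=nest_id, site_id=site_id, year=year,
        initiation_day=initiation_day, hatch_day=hatch, fate=fate,
        end_day=end_day, visits=visits, measurement_day=measurement_day,
        grass_heights_measured=heights,
        grass_height_mean=float(np.mean(heights)),
        true_height_at_hatch=true_height,
        covariates=dict(covariates or {}),
    )


def make_study(nests):
    strata = [StratumTruth(site_id=s, year=y)
              for s, y in sorted({(n.site_id, n.year) for n in nests})]
    return StudyDataset(nests=nests, strata=strata)


@pytest.fixture
def line_study():
    """One stratum with heights exactly on the line 10 + 0.25*(day - 140)."""
    nests = []
    for i, day in enumerate([130, 140, 150, 160, 170]):
        h = 10.0 + 0.25 * (day - 140)
        nests.append(make_nest(nest_id=f"n{i}", initiation_day=day - 30,
                               measurement_day=day, heights=(h,)))
    return make_study(nests)
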