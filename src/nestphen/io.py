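"""CSV readers/writers for nest studies and analysis outputs.

``nests.csv`` holds one row per nest (ids, days, fate, mean height, replicate
heights as a semicolon-joined list, optional ``cov_*`` columns); ``visits.csv``
holds the encounter history as (nest_id, day, state). The pair round-trips
through :func:`write_study` / :func:`read_study`; simulator-only latents
(true hatch-date height, stratum truth) are preserved when present but are
not required on input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from nestphen.simulate import Fate, NestRecord, StratumTruth, StudyDataset, VisitState


def study_to_frames(ds: StudyDataset):
    nest_rows, visit_rows = [], []
    cov_names = sorted({k for n in ds.nests for k in n.covariates})
    for n in ds.nests:
        row = {
            "nest_id": n.nest_id, "site_id": n.site_id, "year": n.year,
            "initiation_day": n.initiation_day, "hatch_day": n.hatch_day,
            "fate": n.fate.value, "end_day": n.end_day,
            "measurement_day": n.measurement_day,
            "grass_height_mean": n.grass_height_mean,
            "grass_heights": ";".join(f"{h:.17g}" for h in n.grass_heights_measured),
            "true_height_at_hatch": "" if n.true_height_at_hatch is None
                                    else n.true_height_at_hatch,
        }
        for k in cov_names:
            row[f"cov_{k}"] = n.covariates.get(k, "")
        nest_rows.append(row)
        for d, s in n.visits:
            visit_rows.append({"nest_id": n.nest_id, "day": d,
                               "state": VisitState(s).value})
    return pd.DataFrame(nest_rows), pd.DataFrame(visit_rows)


def write_study(ds: StudyDataset, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nests, visits = study_to_frames(ds)
    paths = {"nests": outdir / "nests.csv", "visits": outdir / "visits.csv"}
    nests.to_csv(paths["nests"], index=False)
    visits.to_csv(paths["visits"], index=False)
    return paths


def read_study(nests_path, visits_path) -> StudyDataset:
    nests_df = pd.read_csv(nests_path)
    visits_df = pd.read_csv(visits_path)
    visits_by_nest: dict = {}
    for r in visits_df.itertuples(index=False):
        visits_by_nest.setdefault(r.nest_id, []).append((int(r.day), VisitState(r.state)))
    cov_cols = [c for c in nests_df.columns if c.startswith("cov_")]

    nests = []
    for r in nests_df.itertuples(index=False):
        heights = [float(h) for h in str(r.grass_heights).split(";") if h != ""]
        true_h = getattr(r, "true_height_at_hatch", None)
        if true_h is not None and (pd.isna(true_h) or true_h == ""):
            true_h = None
        covs = {}
        for c in cov_cols:
            v = getattr(r, c)
            if not pd.isna(v):
                covs[c[len("cov_"):]] = float(v)
        # mean recomputed from replicates so the invariant holds exactly
        nests.append(NestRecord(
            nest_id=str(r.nest_id), site_id=str(r.site_id), year=int(r.year),
            initiation_day=int(r.initiation_day), hatch_day=int(r.hatch_day),
            fate=Fate(r.fate), end_day=int(r.end_day),
            visits=sorted(visits_by_nest.get(str(r.nest_id), []), key=lambda v: v[0]),
            measurement_day=int(r.measurement_day),
            grass_heights_measured=heights,
            grass_height_mean=float(np.mean(heights)),
            true_height_at_hatch=None if true_h is None else float(true_h),
            covariates=covs,
        ))
    strata = [StratumTruth(site_id=s, year=y)
              for s, y in sorted({(n.site_id, n.year) for n in nests})]
    ds = StudyDataset(nests=nests, strata=strata, config_echo=None)
    ds.validate()
    return ds
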