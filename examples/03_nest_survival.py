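"""Fit the Bayesian daily nest-survival model with and without correction.

Daily survival is logit-linear in grass height; nest success is the product
of daily survival over the 27-day incubation. The same encounter histories
are fitted twice: once with the heights as measured (biased covariate) and
once with hatch-date-corrected heights.
"""

import numpy as np

from nestphen import (McmcSettings, SimConfig, SurvivalModelSpec,
                      correct_heights, fit_phenology, fit_survival,
                      simulate_study, success_curve)
from nestphen.simulate import Protocol

cfg = SimConfig(seed=11, n_sites=4, n_years=3, nests_per_stratum=40,
                beta_grass_surv=0.0, grass_slope_mean=0.3,
                protocol=Protocol.FATE_DATE)
ds = simulate_study(cfg)
cd = correct_heights(ds, fit_phenology(ds))
corrected = dict(zip(cd.table["nest_id"], cd.table["grass_height_corrected"]))

mcmc = McmcSettings(chains=3, iters=4000, warmup=1500, seed=1)
for label, heights in (("uncorrected", None), ("corrected", corrected)):
    post = fit_survival(ds, SurvivalModelSpec(), mcmc=mcmc, heights=heights)
    lo, hi = post.credible_interval("beta_grass_height")
    mean = post.param("beta_grass_height").mean()
    print(f"{label:>12}: grass coefficient {mean:+.4f} per cm, "
          f"95% CrI [{lo:+.4f}, {hi:+.4f}]  (R-hat ok: {post.converged})")
    grid = np.array([10.0, 15.0, 20.0])
    curve = success_curve(post, grid)
    for _, row in curve.iterrows():
        print(f"              27-day success at {row.grass_cm:4.1f} cm: "
              f"{row['mean']:.3f} [{row.lo95:.3f}, {row.hi95:.3f}]")

print("\nTrue effect is zero: the uncorrected interval sits above zero (the")
print("timing artifact), the corrected one brackets zero and its curve is flat.")
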