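"""Simulate one nest study per measurement protocol and show the artifact.

With grass growing within the season and no true effect of height on
survival, measuring vegetation on the day a nest's fate is discovered makes
grass look taller at successful nests; measuring at the predicted hatch date
does not.
"""

import numpy as np

from nestphen import SimConfig, simulate_study
from nestphen.simulate import Fate, Protocol

for protocol in (Protocol.FATE_DATE, Protocol.HATCH_DATE):
    cfg = SimConfig(seed=11, n_sites=4, n_years=3, nests_per_stratum=50,
                    beta_grass_surv=0.0, grass_slope_mean=0.3,
                    protocol=protocol)
    ds = simulate_study(cfg)
    h = np.array([n.grass_height_mean for n in ds.nests])
    hatched = np.array([n.fate is Fate.HATCHED for n in ds.nests])
    gap = h[hatched].mean() - h[~hatched].mean()
    print(f"{protocol.value:>10}: mean measured height "
          f"hatched {h[hatched].mean():5.2f} cm, "
          f"failed {h[~hatched].mean():5.2f} cm, gap {gap:+5.2f} cm")

print("\nThe true effect of grass height on survival is zero in both runs;")
print("the fate-date gap is purely an artifact of measurement timing.")
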