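"""Eigengene-environment association: RDA and Spearman/FDR.

Computes module eigengenes from the planted truth, ordinates them against
standardized physicochemical variables and prints each module's strongest
environmental partner per year.
"""

import pandas as pd

import oligonet as on

ENV_COLS = ["temperature", "chl_a", "SiO2", "PO4", "DIN", "salinity"]

spec = on.CommunitySimSpec(seed=1)
env = on.generate_env(spec)
t1, t2, truth = on.generate_community(spec, env)
mem = pd.Series(truth)

for year, tab in ((1, t1), (2, t2)):
    clr = on.clr_transform(tab)
    mes = pd.DataFrame({
        m: on.module_eigengene(clr, mem.index[mem == m])[0]
        for m in range(1, spec.n_modules + 1)
    })
    envy = env[env["year"] == year][ENV_COLS]
    res = on.rda(mes, on.zscore(envy))
    assoc = on.spearman_bh(mes, envy)
    print(f"year {year}: RDA explains {100 * res.proportion_explained:.0f}% "
          f"of eigengene variance")
    for m in mes.columns:
        sub = assoc[assoc["me"] == m]
        best = sub.loc[sub["rho"].abs().idxmax()]
        print(f"  module {m} ({spec.module_driver_map[m]}-driven): "
              f"strongest partner {best.variable}, rho={best.rho:.2f}, "
              f"BH-adjusted p={best.p_adj:.1e}")
# A recurrent association -- the same partner in both years -- is the
# signature of a seasonally structured module.
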