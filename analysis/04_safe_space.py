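"""Safe space for the test product's particle surface pH.

With the reference product fixed at surface pH 6.02 (its estimate in the
selected maleate + HCl pH 2.0 condition), the test product's surface pH is
swept and, at each value, the typical-subject Cmax GMR is combined with
the in vivo within-subject CVs (14.89% R, 13.65% S) to predict the 90% CI
of a 24-subject crossover. The safe space is the surface-pH interval whose
CI stays inside 80-125%; endpoints are refined by bisection to 0.01 pH.

Writes results/safe_space.csv and results/safe_space_dissolution.csv.
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ibupbbm.dlm_dissolution import ibuprofen, lognormal_psd, simulate_dissolution, two_stage_protocol
from ibupbbm.population_vbe import TrialDesign
from ibupbbm.vbe_engine import map_safe_space

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

drug = ibuprofen()
psd = lognormal_psd(drug, d50_um=300.0, n_bins=5)
REF_PH = 6.02
GRID = [5.5, 5.7, 5.9, 6.1, 6.3, 6.5]

t0 = time.time()
ss = map_safe_space(REF_PH, GRID, drug, psd, design=TrialDesign(n_subjects=24, seed=SEED))
df = pd.DataFrame({
    "test_surface_pH": ss.grid_pH,
    **{f"gmr_{a}_pct": np.round(ss.gmr_pct[a], 2) for a in ss.gmr_pct},
    **{f"ll_{a}_pct": np.round(ss.ci90_pct[a][:, 0], 2) for a in ss.ci90_pct},
    **{f"ul_{a}_pct": np.round(ss.ci90_pct[a][:, 1], 2) for a in ss.ci90_pct},
})
df.to_csv(OUT / "safe_space.csv", index=False)
print(df.to_string(index=False))
for a in ("R", "S", "racemate"):
    iv = ss.safe_interval[a]
    print(f"safe space ({a}): " + (f"{iv[0]:.2f} - {iv[1]:.2f}" if iv else "empty"))
r_iv, s_iv = ss.safe_interval["R"], ss.safe_interval["S"]
if r_iv and s_iv:
    print(f"R-enantiomer is the discriminative analyte "
          f"(interval width {r_iv[1]-r_iv[0]:.2f} vs {s_iv[1]-s_iv[0]:.2f} pH)")

# dissolution profiles spanning the R safe space, after HCl pH 2.0 pretreatment
rows = []
proto = two_stage_protocol(2.0, 6.5, treatment_duration_h=2.5)
for pH in (r_iv if r_iv else (5.6, 6.4)):
    prof = simulate_dissolution(
        drug, psd, proto, float(pH), times_h=[1.0, 1.25, 1.5, 2.0, 2.5],
        warn_supersaturation=False,
    )
    rows.append(dict(
        surface_pH=round(float(pH), 2),
        f_30min_pct=round(float(prof.fraction_dissolved_pct[0]), 1),
        f_45min_pct=round(float(prof.fraction_dissolved_pct[1]), 1),
        f_60min_pct=round(float(prof.fraction_dissolved_pct[2]), 1),
        f_120min_pct=round(float(prof.fraction_dissolved_pct[4]), 1),
    ))
edge = pd.DataFrame(rows)
edge.to_csv(OUT / "safe_space_dissolution.csv", index=False)
print("\nfraction dissolved (%, time after start of the acid stage) at the "
      "safe-space edges:")
print(edge.to_string(index=False))
print(f"\ndone in {time.time()-t0:.0f}s")
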