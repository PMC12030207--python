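"""Surface-pH estimation across the nine in vitro conditions.

Synthetic mean dissolution profiles are generated for three buffers
(phosphate 50 mM pH 6.8, phosphate 5 mM pH 6.7, maleate 7 mM pH 6.5) with
no pretreatment or an HCl pH 1.2 / pH 2.0 pretreatment, for a reference
and a test product whose true particle surface pHs follow the estimates
reported for the corresponding experimental conditions. Each profile is
then re-fitted blind (Nelder-Mead on the surface pH, r^2 quality), and the
mechanistic Cmax/tmax prediction errors are computed against the selected
reference condition (maleate + HCl pH 2.0).

Writes results/dissolution_fit_table.csv.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from ibupbbm.dlm_dissolution import fit_surface_pH, ibuprofen, lognormal_psd
from ibupbbm.gi_pbpk import (
    default_dispositions, default_gi_physiology, extract_cmax_tmax,
    prediction_error, simulate_oral_dose,
)
from ibupbbm.synthetic_data import SyntheticDissolutionSpec, generate_dissolution_profile

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

# (pretreatment pH, buffer label, medium pH, true surface pH ref, test) —
# the true values used by the generator follow the per-condition estimates
# reported for these media
CONDITIONS = [
    (None, "PB50", 6.8, 5.71, 5.85),
    (1.2, "PB50", 6.8, 6.29, 6.25),
    (2.0, "PB50", 6.8, 6.30, 6.20),
    (None, "PB5", 6.7, 5.81, 5.58),
    (1.2, "PB5", 6.7, 6.28, 5.30),
    (2.0, "PB5", 6.7, 6.25, 5.42),
    (None, "MB7", 6.5, 5.64, 5.40),
    (1.2, "MB7", 6.5, 6.33, 5.49),
    (2.0, "MB7", 6.5, 6.02, 5.57),
]
TIMES = (0.58, 0.75, 0.92, 1.08, 1.25, 1.5, 1.75, 2.0, 2.5)

drug = ibuprofen()
psd = lognormal_psd(drug, d50_um=300.0, n_bins=6)
gi = default_gi_physiology()
disp = default_dispositions()

# "observed" typical profile: the selected condition's reference product
obs_prof = simulate_oral_dose(drug, psd, gi, 6.02, disp)
obs_cmax, obs_tmax = extract_cmax_tmax(obs_prof, "racemate")

rows = []
t0 = time.time()
for pre_pH, buffer, med_pH, ref_pH, test_pH in CONDITIONS:
    for product, true_pH in (("reference", ref_pH), ("test", test_pH)):
        spec = SyntheticDissolutionSpec(
            true_surface_pH=true_pH, medium_pH=med_pH, pretreatment_pH=pre_pH,
            sampling_times=TIMES, noise_sd=1.0, seed=SEED + hash((buffer, product)) % 1000,
            medium_name=buffer,
        )
        prof = generate_dissolution_profile(spec, drug, psd, product_label=product)
        est, r2 = fit_surface_pH(prof, drug, psd, spec.protocol(), init=5.7, xatol=1e-3)
        pk = simulate_oral_dose(drug, psd, gi, est, disp, rtol=1e-5)
        cmax, tmax = extract_cmax_tmax(pk, "racemate")
        pe_c, ok_c = prediction_error(cmax, obs_cmax, "cmax_ratio")
        pe_t, ok_t = prediction_error(tmax, obs_tmax, "tmax_pct")
        rows.append(dict(
            pretreatment=("None" if pre_pH is None else f"HCl pH {pre_pH}"),
            medium=buffer, medium_pH=med_pH, product=product,
            true_surface_pH=true_pH, estimated_surface_pH=round(est, 2),
            r2=round(r2, 3), cmax_pe=round(pe_c, 2), tmax_pe_pct=round(pe_t, 0),
            accepted=ok_c and ok_t,
        ))

df = pd.DataFrame(rows)
df.to_csv(OUT / "dissolution_fit_table.csv", index=False)
print(df.to_string(index=False))
worst = (df.estimated_surface_pH - df.true_surface_pH).abs().max()
print(f"\n{len(df)} fits in {time.time()-t0:.0f}s; worst |estimate - truth| = {worst:.3f} pH")
print(f"all r^2 > 0.90: {bool((df.r2 > 0.90).all())}")
print("conditions passing the Cmax 0.9-1.11 and |dtmax| <= 30% filter:",
      ", ".join(sorted({f'{r.medium}/{r.pretreatment}' for r in df.itertuples() if r.accepted})) or "none")
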