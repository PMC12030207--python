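"""Sample sizes and predicted CIs over the anticipated GMR range.

For each enantiomer (within-subject CV 14.89% R / 13.65% S, the values
observed in the reference in vivo BE study) and each anticipated Cmax
test/reference GMR, the TOST crossover sample size at 80% and 90% power is
computed with the normal-quantile closed form (rounded up to even), plus
the 90% CI predicted at the 80%-power n. Larger test-vs-reference surface
pH differences mean lower GMRs and sharply larger trials; the
higher-variability R-enantiomer always needs more subjects at equal GMR.

Writes results/sample_size_table.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from ibupbbm import be_stats

OUT = Path("results")
OUT.mkdir(exist_ok=True)

# (analyte, CV%, anticipated GMR %, associated test surface pH)
ROWS = [
    ("R", 14.89, 84.0, 5.64), ("R", 14.89, 85.0, 5.66), ("R", 14.89, 87.0, 5.70),
    ("R", 14.89, 90.0, 5.75), ("R", 14.89, 93.0, 5.80), ("R", 14.89, 95.0, 5.85),
    ("S", 13.65, 85.0, 5.64), ("S", 13.65, 86.0, 5.66), ("S", 13.65, 87.0, 5.70),
    ("S", 13.65, 90.0, 5.73), ("S", 13.65, 93.0, 5.80), ("S", 13.65, 95.0, 5.84),
]

records = []
for analyte, cv, gmr_pct, surface_ph in ROWS:
    plan = be_stats.plan(gmr_pct / 100.0, cv)
    records.append(dict(
        analyte=analyte, test_surface_pH=surface_ph, gmr_pct=gmr_pct,
        wsv_cv_pct=cv, n_power80=plan.n_80, n_power90=plan.n_90,
        ci90_ll_pct=round(plan.ci90_at_n80_pct[0], 2),
        ci90_ul_pct=round(plan.ci90_at_n80_pct[1], 2),
    ))
df = pd.DataFrame(records)
df.to_csv(OUT / "sample_size_table.csv", index=False)
print(df.to_string(index=False))

r85 = df[(df.analyte == "R") & (df.gmr_pct == 85.0)].iloc[0]
s85 = df[(df.analyte == "S") & (df.gmr_pct == 85.0)].iloc[0]
print(f"\nat GMR 85%: R needs {r85.n_power80}/{r85.n_power90} subjects "
      f"(80/90% power), S needs {s85.n_power80}/{s85.n_power90} — the higher "
      f"R variability costs {r85.n_power80 - s85.n_power80} extra subjects.")
r95 = df[(df.analyte == "R") & (df.gmr_pct == 95.0)].iloc[0]
s95 = df[(df.analyte == "S") & (df.gmr_pct == 95.0)].iloc[0]
print(f"at GMR 95%: only {r95.n_power80}/{r95.n_power90} (R) and "
      f"{s95.n_power80}/{s95.n_power90} (S) subjects are needed.")
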