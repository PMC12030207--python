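# ibupbbm

Physiologically based biopharmaceutics modeling (PBBM/PBPK) and virtual
bioequivalence (VBE) for immediate-release 200 mg racemic ibuprofen
tablets.

Ibuprofen is a weakly acidic, highly permeable drug whose absorption rate
is set by how fast its particles dissolve — and, because the drug
self-buffers, the pH at the particle *surface* (not the bulk medium pH)
controls that rate. This package implements the full workflow that turns
that observation into regulatory-style decisions for generic (test)
versus reference products:

1. **Dissolution modeling** — a diffusion layer model (DLM) for a
   polydisperse particle population,
   `dr_i/dt = −(D/(ρ h_i)) (S_surf − C_bulk)` with `h_i = min(r_i, h_max)`
   and weak-acid surface solubility
   `S_surf = S0 (1 + 10^{pH_surf − pKa})`, fitted to in vitro profiles
   (staged acid-pretreatment protocols) by Nelder–Mead on the particle
   surface pH with an r² quality criterion.
2. **Mechanistic absorption/disposition** — stomach, seven small-intestine
   segments and colon with first-order fluid/particle transit, in-lumen
   DLM dissolution, `ka = 2 Peff/R` absorption, and one-compartment
   disposition per enantiomer with unidirectional R→S chiral inversion.
3. **Sensitivity screening** — Morris elementary effects (μ*, σ) to rank
   physiological drivers of Cmax and formulation drivers of dissolution
   (particle surface pH ranks first).
4. **BE statistics** — log-scale GMR with 90% CI (`df = n−2`), the TOST
   decision against 80.00–125.00%, WSV/BSV variance components
   (`σ² = ln(1+CV²)`), planning CIs, and the TOST sample size
   `n = 2 (z_{1−α}+z_{1−β})² ln(1+CV²)/(ln GMR − ln θ)²` rounded up to
   even.
5. **Safe space and VBE** — the interval of test-product surface pH whose
   predicted 90% CI stays inside 80–125%, and replicated virtual
   crossover campaigns (runs × replicates, fresh populations, recorded
   seeds) with success rates compared against closed-form power.

Everything runs from synthetic inputs generated by the package itself
(`ibupbbm.synthetic_data`): dissolution profiles with known true surface
pH, and lognormal Cmax datasets with known variance components.

## Worked example

Sample size for a test product expected to show a Cmax GMR of 85% against
the reference, at the within-subject CV observed for R-ibuprofen (14.89%):

```text
$ ibupbbm sample-size --gmr 0.85 --cv 14.89
n = 74 (power 80%); predicted CI90 81.62-88.52%
```

74 subjects give 80% power, and at that size the 90% CI of an 85% GMR is
expected to span 81.62–88.52% — inside the BE limits, so such a trial
passes if the point estimate holds. At 90% power the same call with
`--power 0.9` returns n = 104; the S-enantiomer (CV 13.65%) needs 64/88.

Mapping the safe space (`python analysis/04_safe_space.py 1`) with the
reference product at surface pH 6.02 prints:

```text
safe space (R): 5.69 - 6.50
safe space (S): 5.54 - 6.50
R-enantiomer is the discriminative analyte (interval width 0.81 vs 0.96 pH)
```

i.e. a test product whose particle surface pH in the acid-pretreatment
maleate condition stays above ≈5.7 is predicted bioequivalent at n = 24,
the R-enantiomer being the stricter analyte; above ≈6.3 the GMR saturates
near 105% because dissolution is already complete before absorption
limits. The matching dissolution targets at the interval edges (fraction
dissolved 70% vs ~100% at 30 min into the buffer stage) are written to
`results/safe_space_dissolution.csv`.

The analysis drivers under `analysis/` run the remaining stages in
workflow order (physiology screening, dissolution screening, surface-pH
estimation across nine media conditions, sample-size table, VBE
campaigns), each writing its tables under `results/` and printing what it
found.

## Layout

```
src/ibupbbm/        library: dlm_dissolution, gi_pbpk, be_stats,
                    population_vbe, gsa_morris, vbe_engine,
                    synthetic_data, cli_io
analysis/           numbered narrative drivers (01_screen_physiology ...)
scripts/acceptance.py
tests/              pytest suite incl. closed-form and enumeration oracles
docs/methods.md     models, assumptions, defaults, numerics, limitations
```

Model defaults that stand in for unpublished parameterizations
(disposition clearances, inversion rate, Peff, particle-size distribution)
are documented assumptions — see `docs/methods.md` — and quantities that
depend on them are validated as properties (monotonicity, CI-rule
compliance, power consistency) rather than as numeric reproductions.
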