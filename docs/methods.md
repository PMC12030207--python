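# Methods

This note documents the models, the assumptions behind their defaults, the
numerical choices, and what the synthetic-data generators do and do not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Diffusion layer dissolution model (`dlm_dissolution`)

A polydisperse population of spherical particles (log-spaced bins over a
lognormal volume distribution) dissolves by diffusion across a stagnant
layer:

    dr_i/dt = -(D / (rho * h_i)) * (S_surf - C_bulk),   h_i = min(r_i, h_max)

- `S_surf` is the solubility at the particle surface pH. For a monoprotic
  weak acid, `S_surf = S0 * (1 + SF * 10^(pH_surf - pKa))` with the
  solubility factor `SF = 1` by default. Ibuprofen self-buffers, so its
  surface pH sits below the bulk pH and becomes the single
  product-discriminating parameter estimated per medium and product.
- **Per-stage surface-pH cap.** The fitted surface pH is time-invariant
  within a run, but within each protocol stage the effective value is
  `min(pH_surf, pH_medium)`: an acid's self-buffering can only lower the
  surface pH below bulk, never raise it above. This is what makes an HCl
  pH 2.0 pretreatment stage nearly inert (uptake is capped by saturation
  at ~S0) while the fitted value governs the buffered treatment stage,
  where the data live.
- **Mass bookkeeping.** The solver state is the per-bin radius; dissolved
  mass is `dose - remaining solid`, so in vitro mass conservation is exact
  by construction. Dissolved mass and remaining solid carry across stage
  boundaries; volume and pH switch instantaneously.
- **Numerics.** LSODA with rtol 1e-6, atol 1e-9 (radius in cm). The
  dissolution flux is floored at zero (no precipitation; a supersaturated
  bulk triggers a warning only) and is switched off smoothly over the last
  0.5% of each bin's initial radius, leaving ~1e-7 of the bin mass
  undissolved — far below the 1e-6·dose mass-balance assertion — so the
  right-hand side stays Lipschitz as radii reach zero.

**Surface-pH estimation** minimizes the sum of squared residuals in
fraction-dissolved % with Nelder–Mead in one dimension; proposals are
reflected back into pH (3, 8) by a triangle-wave map, and convergence is
declared on simplex spread (`xatol`, default 1e-4 pH; the function-value
tolerance is disabled because assay noise keeps the SSR spread finite).
Fit quality is the squared Pearson correlation of observed vs predicted
(`r^2 > 0.90` flags an acceptable fit). The estimator is validated by
parameter recovery: noise-free synthetic profiles return the generating
surface pH within ±0.02 across 5.4–6.3, and the mean of replicate fits at
2 percentage-point assay noise stays within ±0.05.

### Drug-substance and PSD defaults (documented assumptions)

The platform values used in the original modeling are not public, so the
package ships literature-informed defaults, all exposed in config:

| parameter | default | basis |
|---|---|---|
| pKa | 4.45 | monoprotic weak acid |
| S0 | 0.068 mg/mL | intrinsic solubility at 37 °C |
| D | 4.5e-4 cm²/min | small-molecule aqueous diffusivity |
| true density | 1.06 g/mL | crystalline ibuprofen |
| dose | 200 mg racemate | tablet strength modeled |
| PSD | volume-median diameter 300 µm, geometric SD 1.6, 20 bins (10 in the pipeline config) | chosen once so that, in buffer after acid pretreatment, dissolution completes by ~0.75 h at surface pH 6.4 and takes >2 h at 5.64 — the reported qualitative behaviour of the products |
| h_max | 30 µm | diffusion-layer thickness cap, config-exposed |

## 2. GI absorption and disposition (`gi_pbpk`)

Stomach → seven small-intestine segments → colon, with separate
first-order fluid and particle transit (`rate = 1/MRT`). Central values
follow the published fasted table: stomach fluid MRT 0.12 h, stomach
fine-particle MRT 0.27 h, total SI MRT 3.4 h (apportioned over segments by
length fraction 0.08/0.19/0.19/4×0.135), stomach fluid 50 mL, distal SI
fluid 105 mL, colon 13 mL, segmental pH 6.4–7.3. Stomach pH (1.5), the
duodenal volume (15 mL) and segment radii (1.2–1.53 cm) are package
assumptions. The same DLM runs inside each lumen (per-bin solid mass and
particle count per compartment; the bin radius is recovered from their
ratio), with the surface pH capped by the local luminal pH — the particle
surface pH itself is constant down the GI tract.

Absorption is first-order from dissolved drug in the small intestine,
`ka = 2 Peff / R_segment` with `Peff = 6e-4 cm/s` (high-permeability
assumption); stomach and colon absorb nothing by default. Absorbed drug
splits 50:50 into the enantiomers of the racemate. Disposition is
one-compartment per enantiomer — `Vss = 0.091249 L/kg` (the published
user-input value), CL_R = 2.0 L/h, CL_S = 2.2 L/h, body weight 70 kg —
with unidirectional R→S inversion as a lumped first-order rate
(0.25 h⁻¹, ≈40% of R eliminated by inversion), standing in for the
cytosolic-racemase clearance. These disposition values are assumptions
tuned only to a ~2 h half-life and the known substantial R→S conversion;
the artifact's contract is the VBE machinery, not disposition fidelity,
and quantities that depend on the unpublished full parameterization
(absolute safe-space endpoints, in vivo CI reproductions, campaign
percentages) are treated as property checks, not numeric targets.

**Numerics.** The coupled system (~190 states at 10 bins) is integrated
with BDF and an analytic Jacobian (verified against finite differences).
Particle counts enter the state scaled by their initial values; the
saturation gradient and a trace-mass gate (dissolution off below 1e-4 mg
per bin per compartment, smoothly) remove spurious stiffness from
near-empty bins. Total mass — solid, dissolved, both central amounts,
eliminated — is asserted at every output time to 1e-6·dose; the realized
worst error is reported on the profile. Cmax/tmax are taken over the
clinical sampling grid (0.33…24 h), earliest time on ties, mirroring the
trial analysis.

Wiring is guarded by closed forms: with instantaneous dissolution, a
single lumped absorption rate and one-compartment disposition, the plasma
profile matches the Bateman equation to <0.5% pointwise; monodisperse
sink-condition dissolution matches the cube-root/r² piecewise solution to
<0.5 percentage points.

## 3. Populations and trials (`population_vbe`)

Parameter variability follows the published fasted table: gastric/SI
residence times at CV 150% and Vss at CV 10% carry within-subject
variability (per-period redraw centred on the subject's value, same CV —
the "WSV equals BSV within plausible limits" convention); GI pH and
volumes are BSV-only with their default CVs. All draws are lognormal about
the central value (median parameterization, `sigma² = ln(1+CV²)`) and
truncated to the table limits by rejection, so no point mass accumulates
at the bounds. Note that truncation shrinks the realized CV: a nominal
150% CV on the SI residence time truncated to (0.5, 12) h realizes ≈73%
(the tests assert the sample CV against the closed-form truncated-moment
value, not the nominal one). Segments are sampled independently; the
screening in `analysis/01` finds pH/volume effects negligible, so
cross-segment correlation would not matter for Cmax.

Trials are two-period two-sequence crossovers; sequences alternate TR/RT
by subject index for exact balance at any even n. Demographics (50%
female, ages 20–50) are recorded but do not enter the simplified
disposition. Test and reference products differ only in particle surface
pH; the PSD is shared.

## 4. Bioequivalence statistics (`be_stats`)

On log-Cmax with period differences `d_j = ln T_j − ln R_j`:

- `GMR = exp(mean d)`, `CI90 = GMR · exp(±t_{0.95, n−2} · sd(d)/√n)`
  (df = n−2 for the sequence term of the crossover ANOVA; a paired
  df = n−1 variant exists but is non-default), BE iff the CI lies in
  80.00–125.00%.
- Within-subject CV from `sd(d)² = 2σ_w²`; the one-way moment
  decomposition on subjects × periods estimates WSV/BSV with negative
  between-components truncated at zero. Both recover generating values to
  ±0.5 CV points at n = 10⁴.
- Planning CI: `GMR · exp(±t_{0.95,n−2} √(ln(1+CV²)) √(2/n))`.
- Sample size: normal-quantile TOST,
  `n = 2 (z_{1−α}+z_{1−β})² ln(1+CV²) / (ln GMR − ln θ_near)²`, rounded up
  to the next even integer (`z_{1−β/2}` at GMR = 1); an exact
  noncentral-t search is available behind `method="exact"` and agrees
  within one even step across the planning grid. This closed form
  reproduces the published planning table (all 24 sample sizes exactly;
  46 of 48 CI bounds to the printed 2 decimals, the other two within 0.01
  with the computed value ~0.005 from the rounding boundary).

The exact TOST power at the 80%-power n is slightly below 0.80 (e.g.
0.794 at n = 74, GMR 0.85, CV 14.89%) because the ceiling-to-even rule
rounds a normal-approximation n; the Monte-Carlo consistency check
compares empirical success against the noncentral-t power, within
binomial error.

## 5. Morris screening (`gsa_morris`)

Randomized one-at-a-time trajectories on a p-level grid
(Δ = p/(2(p−1)); defaults p = 4, r = 50, config-exposed since the
original settings are not published). Elementary effects are computed in
unit-scaled space so μ* is comparable across units; σ flags
nonlinearity/interactions. On an additive-linear model μ* equals |aᵢ|
exactly and σ = 0 to floating point; a brute-force enumeration of all
trajectory configurations for f = x₁x₂ at p = 4 fixes E|EE| = 0.5 and the
sampled estimate agrees within Monte-Carlo error. Driver selection takes
the μ*-maximum with ties broken by larger σ, then lexicographic order.

## 6. Safe space and VBE campaigns (`vbe_engine`)

The safe space is mapped in `predicted_ci` mode by default: the
typical-subject Cmax ratio at each test surface pH is combined with the in
vivo within-subject CVs (14.89% R, 13.65% S; the racemate is assigned the
larger) and the planning CI at n = 24 — the same construction used to
anticipate CI bounds from an observed variability. Interval endpoints are
refined by bisection to 0.01 pH against the same passing rule, and the
reported interval is re-asserted against the CI rule at every grid point
inside it. A full-simulation mode runs a virtual trial per grid point
instead. The headline analyte is R, which the GMR-vs-pH curves show to be
at least as discriminative as S.

Campaigns replicate whole trials in a runs × replicates layout with a
distinct recorded seed per replicate (`(base + 7919·run) XOR replicate`),
so the layout dependence of success rates can be investigated rather than
assumed away. The success rate per analyte is compared with the
closed-form TOST power at matched GMR/CV/n, with a Clopper–Pearson 95%
band on the empirical rate — a diagnostic for the known over-optimism of
simulation-based BE success rates, not a pass/fail.

## 7. Synthetic data (`synthetic_data`)

- **Dissolution**: the forward DLM at a known true surface pH plus
  additive Gaussian noise in fraction-dissolved % (homoscedastic on the %
  scale, matching dissolution assay error), clipped to [0, 100]. With zero
  noise the output is bitwise the forward model. The generator emulates
  *mean* profiles of the two-stage acid-pretreatment protocols
  (HCl pH 1.2/2.0 → PB50/PB5/MB7 buffers); it does not emulate per-vessel
  variability, autocorrelated assay error, or bioanalytical error — so
  passing recovery tests speak to estimator correctness under the stated
  noise model, not to robustness against structured assay artifacts.
- **Cmax datasets**: the standard lognormal mixed model
  (subject effect `N(0, ln(1+BSV²))`, formulation effect `ln GMR`,
  residual `N(0, ln(1+WSV²))`), 2-period TR/RT or 4-period replicate
  layouts. This is the independent route for validating `be_stats`
  without the mechanistic pipeline.

Every generator is deterministic under its seed.

## 8. Problem sizes used by the shipped runs

Chosen as the package's own defaults for its bundled analyses: the
Monte-Carlo consistency check runs 10⁴ trials of n = 74; surface-pH
recovery uses a 6-bin PSD, 9 sampling times, 4 truth values and 20 (tests)
or 5 (acceptance script) noisy replicates; in vivo simulations in
population work use a 3-bin PSD (the typical-subject Cmax changes by
<0.3% between 3 and 10 bins at matched conditions); the bundled VBE
campaigns run N = 10–20 trials of 4–12 subjects with binomial bands
reported alongside. All sizes are config parameters; nothing in the
library caps them.

## 9. Known limitations

- Disposition is deliberately reduced (one compartment per enantiomer, no
  stereoselective protein binding or CYP kinetics, no enterohepatic
  recirculation, no gut-wall metabolism); absolute exposures and GMR-vs-pH
  steepness therefore differ from any specific published parameterization.
- No precipitation/supersaturation kinetics: a supersaturated lumen or
  vessel warns and dissolution simply stops at the gradient.
- Particle surface pH is constant in time and along the GI tract (capped
  by local pH), and is assumed equal for both enantiomers and both
  products' non-estimated DLM parameters.
- Mean-profile dissolution modeling only; vessel-level variability is an
  option of the generator, off by default.
- The trace-mass gate and radius shutoff leave O(1e-7) of bin mass
  undissolved by design; fraction dissolved asymptotes at ~99.99%, not
  exactly 100%.
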