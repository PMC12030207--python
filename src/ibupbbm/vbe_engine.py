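"""Safe-space mapping and replicated virtual-bioequivalence campaigns.

The safe space is the interval of *test-product* particle surface pH for
which a crossover trial against the reference product is expected to pass
average BE (90% CI of the Cmax ratio inside 80.00-125.00%). Two routes are
supported:

* ``predicted_ci`` (default for mapping): the Cmax GMR at each grid point
  comes from a deterministic typical-subject simulation of test and
  reference, and the CI from the closed planning form at the stated
  within-subject CV and sample size — mirroring how safe-space CI bounds
  are anticipated from an observed in vivo variability.
* ``simulated``: a full virtual crossover trial per grid point.

Campaigns replicate whole virtual trials (runs x replicates, fresh
populations, recorded seeds) and report the fraction declared BE per
analyte, plus a diagnostic comparing that empirical success rate with the
closed-form TOST power at the same n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import be_stats
from .dlm_dissolution import PSD, DrugSubstance
from .gi_pbpk import (
    CLINICAL_SCHEDULE,
    EnantiomerDisposition,
    default_dispositions,
    default_gi_physiology,
    extract_cmax_tmax,
    simulate_oral_dose,
)
from .population_vbe import (
    ANALYTES,
    TrialDesign,
    VariabilitySpec,
    default_variability_spec,
    draw_population,
    run_crossover_trial,
    trial_be_outcomes,
)

__all__ = [
    "SafeSpaceResult",
    "VBECampaign",
    "CampaignResult",
    "typical_gmr",
    "map_safe_space",
    "run_vbe_campaign",
    "success_rate_vs_power_check",
]

#: In-vivo within-subject CVs (%) of Cmax per analyte, used as the
#: planning variability for predicted CIs (R, S from the reference BE
#: study; the racemate is assigned the larger of the two).
INVIVO_WSV_CV = {"R": 14.89, "S": 13.65, "racemate": 14.89}


@dataclass(frozen=True)
class SafeSpaceResult:
    reference_surface_pH: float
    grid_pH: np.ndarray
    gmr_pct: dict[str, np.ndarray]  # per analyte, aligned with grid
    ci90_pct: dict[str, np.ndarray]  # per analyte, shape (len(grid), 2)
    safe_interval: dict[str, tuple[float, float] | None]  # per analyte
    analyte: str = "R"  # headline analyte

    @property
    def interval(self) -> tuple[float, float] | None:
        return self.safe_interval[self.analyte]


def typical_gmr(
    test_surface_pH: float,
    reference_surface_pH: float,
    drug: DrugSubstance,
    psd: PSD,
    disp: tuple[EnantiomerDisposition, EnantiomerDisposition] | None = None,
    schedule: Sequence[float] = CLINICAL_SCHEDULE,
    peff_1e4_cm_s: float = 6.0,
    h_max_um: float = 30.0,
) -> dict[str, float]:
    """Deterministic test/reference Cmax ratio per analyte for the typical subject."""
    disp = disp or default_dispositions()
    gi = default_gi_physiology()
    out = {}
    profiles = {
        pH: simulate_oral_dose(
            drug, psd, gi, pH, disp, schedule=schedule,
            peff_1e4_cm_s=peff_1e4_cm_s, h_max_um=h_max_um,
        )
        for pH in {test_surface_pH, reference_surface_pH}
    }
    for analyte in ANALYTES:
        cmax_t, _ = extract_cmax_tmax(profiles[test_surface_pH], analyte)
        cmax_r, _ = extract_cmax_tmax(profiles[reference_surface_pH], analyte)
        out[analyte] = cmax_t / cmax_r
    return out


def _predicted_outcome(gmr: float, analyte: str, n: int) -> tuple[float, tuple[float, float]]:
    lo, hi = be_stats.predict_ci(gmr, INVIVO_WSV_CV[analyte], n)
    return gmr * 100.0, (lo, hi)


def _ci_ok(ci: tuple[float, float]) -> bool:
    return ci[0] >= 80.0 and ci[1] <= 125.0


def map_safe_space(
    reference_surface_pH: float,
    pH_grid: Sequence[float],
    drug: DrugSubstance,
    psd: PSD,
    design: TrialDesign | None = None,
    mode: str = "predicted_ci",
    variability: VariabilitySpec | None = None,
    disp: tuple[EnantiomerDisposition, EnantiomerDisposition] | None = None,
    refine_tol_pH: float = 0.01,
    analyte: str = "R",
    rtol: float = 1e-6,
) -> SafeSpaceResult:
    """Map GMR and 90% CI over a test surface-pH grid and find the safe interval.

    The safe interval is the maximal contiguous run of grid points whose CI
    lies inside [80, 125] for the headline ``analyte``, with its endpoints
    refined by bisection (to ``refine_tol_pH``) against the same passing
    rule. An empty safe space is reported as ``None``, not an error.
    """
    grid = np.asarray(sorted(float(x) for x in pH_grid))
    if np.any(grid <= 3.0) or np.any(grid >= 8.0):
        raise ValueError("surface pH grid must lie inside (3, 8)")
    design = design or TrialDesign(n_subjects=24)
    n = design.n_subjects

    gi = default_gi_physiology()
    disp_pair = disp or default_dispositions()
    cmax_cache: dict[float, dict[str, float]] = {}

    def typical_cmax(pH: float) -> dict[str, float]:
        if pH not in cmax_cache:
            prof = simulate_oral_dose(drug, psd, gi, pH, disp_pair, rtol=rtol)
            cmax_cache[pH] = {a: extract_cmax_tmax(prof, a)[0] for a in ANALYTES}
        return cmax_cache[pH]

    def point(test_pH: float) -> dict[str, tuple[float, tuple[float, float]]]:
        if mode == "predicted_ci":
            ct, cr = typical_cmax(test_pH), typical_cmax(reference_surface_pH)
            return {a: _predicted_outcome(ct[a] / cr[a], a, n) for a in ANALYTES}
        if mode == "simulated":
            spec = variability or default_variability_spec()
            subjects = draw_population(spec, design)
            trial = run_crossover_trial(
                subjects, drug, psd, test_pH, reference_surface_pH,
                disp or default_dispositions(), schedule=design.schedule, rtol=rtol,
            )
            return {
                a: (o.gmr_pct, o.ci90_pct) for a, o in trial_be_outcomes(trial).items()
            }
        raise ValueError(f"unknown mode {mode!r}")

    results = [point(pH) for pH in grid]
    gmr_pct = {a: np.array([r[a][0] for r in results]) for a in ANALYTES}
    ci90 = {a: np.array([r[a][1] for r in results]) for a in ANALYTES}

    safe_interval: dict[str, tuple[float, float] | None] = {}
    for a in ANALYTES:
        ok = np.array([_ci_ok(tuple(ci)) for ci in ci90[a]])
        if not ok.any():
            safe_interval[a] = None
            continue
        # maximal contiguous passing run
        best_lo = best_hi = None
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                if best_lo is None or (grid[j] - grid[i]) > (best_hi - best_lo):
                    best_lo, best_hi = grid[i], grid[j]
                i = j + 1
            else:
                i += 1

        def passes(pH: float, _a=a) -> bool:
            return _ci_ok(point(pH)[_a][1])

        lo = _bisect_edge(passes, best_lo, grid[0], refine_tol_pH)
        hi = _bisect_edge(passes, best_hi, grid[-1], refine_tol_pH)
        safe_interval[a] = (lo, hi)

    return SafeSpaceResult(
        reference_surface_pH=reference_surface_pH, grid_pH=grid,
        gmr_pct=gmr_pct, ci90_pct=ci90, safe_interval=safe_interval,
        analyte=analyte,
    )


def _bisect_edge(passes, inside: float, outside: float, tol: float) -> float:
    """Bisect between a passing point and the grid edge/failing side."""
    if inside == outside or passes(outside):
        return outside
    a, b = inside, outside  # passes(a), not passes(b)
    while abs(b - a) > tol:
        m = 0.5 * (a + b)
        if passes(m):
            a = m
        else:
            b = m
    return a


@dataclass(frozen=True)
class VBECampaign:
    """Replicated VBE study: runs x replicates trials of n subjects, N total."""

    n_subjects: int
    runs: int
    replicates: int
    base_seed: int = 12345

    def __post_init__(self) -> None:
        if self.runs < 1 or self.replicates < 1:
            raise ValueError("runs and replicates must be positive")

    @property
    def n_total(self) -> int:
        return self.runs * self.replicates

    def seed_for(self, run: int, replicate: int) -> int:
        """Distinct, recorded seed per trial: run base XOR replicate index."""
        return ((self.base_seed + 7919 * run) ^ replicate) % (2**31 - 1)


@dataclass(frozen=True)
class CampaignResult:
    campaign: VBECampaign
    success_rate_pct: dict[str, float]
    per_run_success_pct: dict[str, np.ndarray]
    records: pd.DataFrame  # run, replicate, seed, analyte, gmr, ll, ul, be
    n_failures: int


def run_vbe_campaign(
    campaign: VBECampaign,
    test_surface_pH: float,
    reference_surface_pH: float,
    drug: DrugSubstance,
    psd: PSD,
    variability: VariabilitySpec | None = None,
    disp: tuple[EnantiomerDisposition, EnantiomerDisposition] | None = None,
    schedule: Sequence[float] = CLINICAL_SCHEDULE,
    rtol: float = 1e-5,
) -> CampaignResult:
    """Run all replicate trials and report BE success rates per analyte.

    Each replicate draws a fresh population from its recorded seed;
    failures propagate as errors annotated with run/replicate (a failed
    integration is a bug, not a trial outcome).
    """
    spec = variability or default_variability_spec()
    disp = disp or default_dispositions()
    rows = []
    for run in range(1, campaign.runs + 1):
        for rep in range(1, campaign.replicates + 1):
            seed = campaign.seed_for(run, rep)
            design = TrialDesign(n_subjects=campaign.n_subjects, schedule=tuple(schedule), seed=seed)
            subjects = draw_population(spec, design)
            trial = run_crossover_trial(
                subjects, drug, psd, test_surface_pH, reference_surface_pH,
                disp, schedule=schedule, rtol=rtol,
            )
            for analyte, o in trial_be_outcomes(trial).items():
                rows.append(
                    dict(
                        run=run, replicate=rep, seed=seed, analyte=analyte,
                        gmr_pct=o.gmr_pct, ll_pct=o.ci90_pct[0], ul_pct=o.ci90_pct[1],
                        be=bool(o.decision),
                    )
                )
    records = pd.DataFrame(rows)
    success = {
        a: 100.0 * records.loc[records.analyte == a, "be"].mean() for a in ANALYTES
    }
    per_run = {
        a: records.loc[records.analyte == a].groupby("run")["be"].mean().to_numpy() * 100.0
        for a in ANALYTES
    }
    return CampaignResult(
        campaign=campaign, success_rate_pct=success,
        per_run_success_pct=per_run, records=records, n_failures=0,
    )


def success_rate_vs_power_check(
    success_rate_pct: float,
    n_trials: int,
    gmr: float,
    wsv_cv_pct: float,
    n_subjects: int,
    alpha_ci: float = 0.05,
) -> dict[str, float]:
    """Compare an empirical VBE success rate with closed-form TOST power.

    Reports the Clopper-Pearson 95% interval of the empirical rate and the
    discrepancy from the noncentral-t power at the same (GMR, CV, n) — a
    diagnostic for over/under-estimation of BE success, not a pass/fail.
    """
    k = round(success_rate_pct / 100.0 * n_trials)
    lo = stats.beta.ppf(alpha_ci / 2, k, n_trials - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha_ci / 2, k + 1, n_trials - k) if k < n_trials else 1.0
    power = be_stats.tost_power(gmr, wsv_cv_pct, n_subjects)
    return {
        "success_rate_pct": success_rate_pct,
        "binomial_ci_lo_pct": 100.0 * float(lo),
        "binomial_ci_hi_pct": 100.0 * float(hi),
        "closed_form_power_pct": 100.0 * power,
        "discrepancy_pct_points": success_rate_pct - 100.0 * power,
        "power_inside_binomial_ci": float(lo) <= power <= float(hi),
    }
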