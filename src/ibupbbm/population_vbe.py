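"""Virtual populations and crossover trial simulation.

Builds populations of virtual subjects whose physiological and disposition
parameters carry between-subject variability (BSV, a subject-level draw)
and, for a designated subset, within-subject variability (WSV, an
independent per-period redraw centred on the subject's value) — the
convention that WSV equals BSV for physiological parameters within
plausible limits. Draws are lognormal about the central value with the
stated CV and truncated to physiological limits by rejection sampling.

Two-period, two-sequence (TR/RT) crossover trials of a test vs a reference
product are then simulated subject by subject through the mechanistic
absorption model, the two products differing only in particle surface pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import be_stats
from .dlm_dissolution import PSD, DrugSubstance
from .gi_pbpk import (
    CLINICAL_SCHEDULE,
    EnantiomerDisposition,
    GICompartment,
    default_gi_physiology,
    extract_cmax_tmax,
    simulate_oral_dose,
)

ANALYTES = ("R", "S", "racemate")

__all__ = [
    "ParameterVariability",
    "VariabilitySpec",
    "TrialDesign",
    "VirtualSubject",
    "default_variability_spec",
    "draw_population",
    "run_crossover_trial",
    "trial_be_outcomes",
]


@dataclass(frozen=True)
class ParameterVariability:
    """Central value, lognormal CV (%) and truncation limits of one parameter."""

    central: float
    cv_pct: float
    lo: float
    hi: float
    wsv: bool = False  # redrawn each period when True

    def __post_init__(self) -> None:
        if self.cv_pct < 0:
            raise ValueError("CV must be nonnegative")
        if not (self.lo < self.central < self.hi):
            raise ValueError(
                f"central {self.central} outside truncation limits ({self.lo}, {self.hi})"
            )


VariabilitySpec = Mapping[str, ParameterVariability]


def default_variability_spec() -> dict[str, ParameterVariability]:
    """Fasted-state variability table used for the Cmax variability model.

    The starred WSV parameters are the gastric/SI residence times and Vss
    (optimized CVs 150% and 10%); GI pH and volume CVs are platform
    defaults and BSV-only.
    """
    P = ParameterVariability
    return {
        "mrt_stomach_fluid_h": P(0.12, 150.0, 0.01, 12.0, wsv=True),
        "mrt_si_fluid_h": P(3.4, 150.0, 0.5, 12.0, wsv=True),
        "mrt_stomach_particles_h": P(0.27, 150.0, 0.01, 12.0, wsv=True),
        "mrt_si_particles_h": P(3.4, 150.0, 0.5, 12.0, wsv=True),
        "vss_l_per_kg": P(0.091249, 10.0, 0.05, 1000.0, wsv=True),
        "ph_duodenum": P(6.4, 16.0, 1.0, 15.0),
        "ph_jejunum1": P(6.5, 13.0, 1.0, 15.0),
        "ph_jejunum2": P(6.6, 11.0, 1.0, 15.0),
        "ph_ileum1": P(6.8, 10.0, 1.0, 15.0),
        "ph_ileum2": P(7.0, 10.0, 1.0, 15.0),
        "ph_ileum3": P(7.1, 7.0, 1.0, 15.0),
        "ph_ileum4": P(7.3, 6.0, 1.0, 15.0),
        "ph_colon": P(6.6, 13.0, 3.18, 9.8),
        "stomach_volume_ml": P(50.0, 30.0, 20.0, 1000.0),
        "si_volume_ml": P(105.0, 30.0, 10.0, 1000.0),
        "colon_volume_ml": P(13.0, 0.0, 1.0, 250.0),
    }


@dataclass(frozen=True)
class TrialDesign:
    """Two-period, two-sequence crossover design."""

    n_subjects: int
    schedule: tuple[float, ...] = CLINICAL_SCHEDULE
    seed: int = 0
    n_periods: int = 2
    female_proportion: float = 0.5
    age_range: tuple[float, float] = (20.0, 50.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 2 for a balanced 2x2 design")
        if self.n_periods != 2:
            raise ValueError("only two-period designs are supported")
        if not (0.0 <= self.female_proportion <= 1.0):
            raise ValueError("female proportion must lie in [0, 1]")


@dataclass(frozen=True)
class VirtualSubject:
    subject_id: int
    sequence: str  # "TR" or "RT"
    sex: str
    age: float
    subject_params: dict[str, float]
    period_params: tuple[dict[str, float], ...]  # one dict per period


def _truncated_lognormal(
    rng: np.random.Generator, center: float, cv_pct: float, lo: float, hi: float,
    max_tries: int = 10_000,
) -> float:
    """One lognormal draw about ``center`` truncated to (lo, hi) by rejection."""
    if cv_pct == 0.0:
        return center
    sigma = math.sqrt(be_stats.cv_to_sigma2(cv_pct))
    for _ in range(max_tries):
        x = center * math.exp(sigma * rng.standard_normal())
        if lo < x < hi:
            return x
    raise RuntimeError(
        f"rejection sampling failed: center {center}, CV {cv_pct}%, limits ({lo}, {hi})"
    )


def draw_population(spec: VariabilitySpec, design: TrialDesign) -> list[VirtualSubject]:
    """Draw a balanced virtual population, deterministic under ``design.seed``.

    Subject-level values are truncated-lognormal about the central value;
    WSV-flagged parameters are redrawn for each period about the subject's
    own value with the same CV (hierarchical lognormal). Sequences
    alternate TR/RT by subject index for exact balance.
    """
    rng = np.random.default_rng(design.seed)
    subjects = []
    for i in range(design.n_subjects):
        subj = {
            name: _truncated_lognormal(rng, p.central, p.cv_pct, p.lo, p.hi)
            for name, p in spec.items()
        }
        periods = []
        for _ in range(design.n_periods):
            per = dict(subj)
            for name, p in spec.items():
                if p.wsv:
                    per[name] = _truncated_lognormal(rng, subj[name], p.cv_pct, p.lo, p.hi)
            periods.append(per)
        sex = "F" if rng.uniform() < design.female_proportion else "M"
        age = float(rng.uniform(*design.age_range))
        subjects.append(
            VirtualSubject(
                subject_id=i + 1,
                sequence="TR" if i % 2 == 0 else "RT",
                sex=sex,
                age=age,
                subject_params=subj,
                period_params=tuple(periods),
            )
        )
    return subjects


def _model_inputs(
    params: Mapping[str, float],
    disp_template: tuple[EnantiomerDisposition, EnantiomerDisposition],
) -> tuple[list[GICompartment], tuple[EnantiomerDisposition, EnantiomerDisposition]]:
    """Instantiate GI physiology and disposition from one parameter draw."""
    gi = default_gi_physiology(
        stomach_volume_ml=params["stomach_volume_ml"],
        mrt_stomach_fluid_h=params["mrt_stomach_fluid_h"],
        mrt_stomach_particles_h=params["mrt_stomach_particles_h"],
        mrt_si_fluid_h=params["mrt_si_fluid_h"],
        mrt_si_particles_h=params["mrt_si_particles_h"],
        si_volume_ml=params["si_volume_ml"],
        si_ph=[
            params["ph_duodenum"], params["ph_jejunum1"], params["ph_jejunum2"],
            params["ph_ileum1"], params["ph_ileum2"], params["ph_ileum3"],
            params["ph_ileum4"],
        ],
        colon_ph=params["ph_colon"],
        colon_volume_ml=params["colon_volume_ml"],
    )
    disp_r, disp_s = disp_template
    vss = params["vss_l_per_kg"]
    disp = (
        EnantiomerDisposition("R", vss, disp_r.cl_l_per_h, disp_r.k_inversion_per_h,
                              disp_r.body_weight_kg),
        EnantiomerDisposition("S", vss, disp_s.cl_l_per_h, 0.0, disp_s.body_weight_kg),
    )
    return gi, disp


def run_crossover_trial(
    subjects: Sequence[VirtualSubject],
    drug: DrugSubstance,
    psd: PSD,
    surface_pH_test: float,
    surface_pH_ref: float,
    disp_template: tuple[EnantiomerDisposition, EnantiomerDisposition],
    schedule: Sequence[float] = CLINICAL_SCHEDULE,
    peff_1e4_cm_s: float = 6.0,
    h_max_um: float = 30.0,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Simulate every subject-period and return per-analyte Cmax/tmax records.

    Columns: subject, sequence, period, treatment, analyte, cmax, tmax.
    """
    for pH in (surface_pH_test, surface_pH_ref):
        if not (3.0 < pH < 8.0):
            raise ValueError("surface pH must lie in (3, 8)")
    rows = []
    for subj in subjects:
        for period, params in enumerate(subj.period_params, start=1):
            treatment = subj.sequence[period - 1]
            pH = surface_pH_test if treatment == "T" else surface_pH_ref
            gi, disp = _model_inputs(params, disp_template)
            try:
                profile = simulate_oral_dose(
                    drug, psd, gi, pH, disp, schedule=schedule,
                    peff_1e4_cm_s=peff_1e4_cm_s, h_max_um=h_max_um, rtol=rtol,
                )
            except RuntimeError as exc:
                raise RuntimeError(
                    f"simulation failed for subject {subj.subject_id}, period {period}"
                ) from exc
            for analyte in ANALYTES:
                cmax, tmax = extract_cmax_tmax(profile, analyte)
                rows.append(
                    dict(
                        subject=subj.subject_id, sequence=subj.sequence,
                        period=period, treatment=treatment, analyte=analyte,
                        cmax=cmax, tmax=tmax,
                    )
                )
    return pd.DataFrame(rows)


def trial_be_outcomes(trial: pd.DataFrame) -> dict[str, be_stats.BEOutcome]:
    """2x2 crossover BE analysis of a simulated trial, per analyte."""
    out = {}
    for analyte, g in trial.groupby("analyte"):
        wide = g.pivot_table(index="subject", columns="treatment", values="cmax")
        if wide.isna().any().any():
            raise ValueError("every subject needs one T and one R observation")
        out[analyte] = be_stats.crossover_be(
            np.log(wide["T"].to_numpy()), np.log(wide["R"].to_numpy()), analyte=analyte
        )
    return out
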