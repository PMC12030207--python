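"""Synthetic input generators for the whole pipeline.

Nothing in this package requires downloads: the dissolution profiles that
would come from a two-stage USP-type assay are forward-simulated from the
diffusion layer model with a *known* true particle surface pH and additive
Gaussian assay noise, and crossover Cmax datasets with known variance
components are drawn from the standard lognormal mixed model. Both
generators are deterministic under their seeds, which makes them usable as
oracles: with zero noise the dissolution generator returns exactly the
deterministic forward model, and the PK generator's variance components
are recoverable by moment estimation at large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .dlm_dissolution import (
    PSD,
    DissolutionProfile,
    DrugSubstance,
    simulate_dissolution,
    single_stage_protocol,
    two_stage_protocol,
)

__all__ = [
    "SyntheticDissolutionSpec",
    "SyntheticPopulationSpec",
    "PKDataset",
    "generate_dissolution_profile",
    "generate_pk_dataset",
]


@dataclass(frozen=True)
class SyntheticDissolutionSpec:
    """Conditions of one synthetic dissolution experiment.

    ``pretreatment_pH=None`` means a single-stage run in the treatment
    medium; otherwise an acid stage of ``pretreatment_duration`` precedes
    it (the two-stage acid-pretreatment protocol). ``noise_sd`` is the
    additive Gaussian assay error in percentage points of fraction
    dissolved.
    """

    true_surface_pH: float
    medium_pH: float
    sampling_times: tuple[float, ...]
    pretreatment_pH: float | None = None
    pretreatment_duration: float = 0.5
    medium_name: str = "buffer"
    treatment_volume_ml: float = 900.0
    pretreatment_volume_ml: float = 500.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.sampling_times)
        if len(t) == 0:
            raise ValueError("sampling_times must be nonempty")
        if any(x < 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling_times must be nonnegative and strictly increasing")
        object.__setattr__(self, "sampling_times", t)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 < self.true_surface_pH < 14.0):
            raise ValueError("true surface pH must lie in (0, 14)")
        if self.pretreatment_pH is not None and self.pretreatment_duration <= 0:
            raise ValueError("pretreatment duration must be positive")

    def protocol(self, treatment_duration_h: float | None = None):
        """Staged protocol realizing these conditions."""
        end = self.sampling_times[-1]
        if self.pretreatment_pH is None:
            return single_stage_protocol(
                self.medium_pH, volume_ml=self.treatment_volume_ml,
                duration_h=treatment_duration_h or end, name=self.medium_name,
            )
        return two_stage_protocol(
            self.pretreatment_pH, self.medium_pH,
            pretreatment_duration_h=self.pretreatment_duration,
            treatment_duration_h=treatment_duration_h or (end - self.pretreatment_duration),
            pretreatment_volume_ml=self.pretreatment_volume_ml,
            treatment_volume_ml=self.treatment_volume_ml,
            treatment_name=self.medium_name,
        )


def generate_dissolution_profile(
    spec: SyntheticDissolutionSpec,
    drug: DrugSubstance,
    psd: PSD,
    h_max_um: float = 30.0,
    product_label: str = "reference",
) -> DissolutionProfile:
    """Forward-simulate the DLM at the true surface pH and add assay noise.

    With ``noise_sd == 0`` the output is exactly the deterministic forward
    solution at the sampling times. Noisy fractions are clipped to
    [0, 100]%.
    """
    clean = simulate_dissolution(
        drug, psd, spec.protocol(), spec.true_surface_pH,
        h_max_um=h_max_um, times_h=np.asarray(spec.sampling_times),
        warn_supersaturation=False,
    )
    f = clean.fraction_dissolved_pct
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = np.clip(f + rng.normal(0.0, spec.noise_sd, size=f.shape), 0.0, 100.0)
    return DissolutionProfile(
        times_h=clean.times_h, fraction_dissolved_pct=f, product_label=product_label
    )


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Size and demographics of a synthetic trial population."""

    n_subjects: int
    female_proportion: float = 0.5
    age_range: tuple[float, float] = (20.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not (0.0 <= self.female_proportion <= 1.0):
            raise ValueError("female proportion must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must be increasing")


@dataclass(frozen=True)
class PKDataset:
    """Long-format log-Cmax records of a simulated crossover trial."""

    subject: np.ndarray
    period: np.ndarray
    sequence: np.ndarray
    treatment: np.ndarray
    log_cmax: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                subject=self.subject, period=self.period, sequence=self.sequence,
                treatment=self.treatment, log_cmax=self.log_cmax,
            )
        )

    def paired_logs(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (log T, log R) averages, aligned by subject."""
        df = self.to_frame()
        wide = df.pivot_table(index="subject", columns="treatment", values="log_cmax")
        return wide["T"].to_numpy(), wide["R"].to_numpy()


def generate_pk_dataset(
    pop: SyntheticPopulationSpec,
    true_gmr: float,
    wsv_cv_pct: float,
    bsv_cv_pct: float,
    n_periods: int = 2,
    baseline_log_cmax: float = math.log(10.0),
) -> PKDataset:
    """Lognormal Cmax generator with known variance components.

    Per subject *j* and period *p*::

        log Cmax_jp = mu + s_j + ln(GMR) * [treatment_jp == T] + e_jp

    with ``s_j ~ N(0, ln(1+BSV^2))`` and ``e_jp ~ N(0, ln(1+WSV^2))``.
    ``n_periods=2`` gives the TR/RT crossover; ``n_periods=4`` the TRTR/RTRT
    full replicate. Deterministic under ``pop.seed``.
    """
    if true_gmr <= 0:
        raise ValueError("true GMR must be positive")
    if wsv_cv_pct < 0 or bsv_cv_pct < 0:
        raise ValueError("CVs must be nonnegative")
    if n_periods not in (2, 4):
        raise ValueError("crossover designs supported: 2 or 4 periods")
    if pop.n_subjects < 3:
        raise ValueError("fewer than 3 subjects cannot support a downstream CI")

    from .be_stats import cv_to_sigma2  # local import avoids cycle at module load

    rng = np.random.default_rng(pop.seed)
    n = pop.n_subjects
    sd_b = math.sqrt(cv_to_sigma2(bsv_cv_pct))
    sd_w = math.sqrt(cv_to_sigma2(wsv_cv_pct))
    log_gmr = math.log(true_gmr)

    base_seq = ("TR", "RT") if n_periods == 2 else ("TRTR", "RTRT")
    sequences = np.array([base_seq[j % 2] for j in range(n)])
    s = rng.normal(0.0, sd_b, size=n) if sd_b > 0 else np.zeros(n)
    e = rng.normal(0.0, sd_w, size=(n, n_periods)) if sd_w > 0 else np.zeros((n, n_periods))

    subject = np.repeat(np.arange(1, n + 1), n_periods)
    period = np.tile(np.arange(1, n_periods + 1), n)
    treatment = np.array([seq[p] for seq in sequences for p in range(n_periods)])
    log_cmax = (
        baseline_log_cmax
        + np.repeat(s, n_periods)
        + log_gmr * (treatment == "T")
        + e.ravel()
    )
    return PKDataset(
        subject=subject, period=period,
        sequence=np.repeat(sequences, n_periods), treatment=treatment,
        log_cmax=log_cmax,
    )
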