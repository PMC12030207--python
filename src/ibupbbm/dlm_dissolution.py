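"""Diffusion layer model (DLM) for polydisperse particle dissolution.

A population of spherical drug particles dissolves by diffusion across a
stagnant layer of effective thickness ``h``: per particle-size bin *i*,

    dr_i/dt = -(D / (rho * h_i)) * (S_surf - C_bulk),   h_i = min(r_i, h_max)

where ``S_surf`` is the solubility at the particle *surface* pH — for a
monoprotic weak acid ``S0 * (1 + 10^(pH_surf - pKa))`` — and ``C_bulk`` the
bulk concentration. The surface pH of a self-buffered weak acid such as
ibuprofen sits below the bulk pH and is the single product-discriminating
parameter fitted here per medium/product; it is treated as time-invariant
within a run, capped per stage by the stage's medium pH (self-buffering can
only lower the surface pH of an acid below bulk, never raise it above).

Staged protocols (acid pretreatment followed by buffer treatment) carry the
dissolved mass and the remaining solid across stage boundaries; volume and
pH switch instantaneously.

Internal units: length cm, mass mg, volume mL, time h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.special import erf

UM_PER_CM = 1.0e4
R_MIN_UM = 1.0e-3  # bins below this radius count as fully dissolved

__all__ = [
    "DrugSubstance",
    "PSD",
    "DissolutionStage",
    "DissolutionProtocol",
    "DissolutionProfile",
    "DLMState",
    "ibuprofen",
    "lognormal_psd",
    "monodisperse_psd",
    "surface_solubility",
    "simulate_dissolution",
    "fit_surface_pH",
    "goodness_r2",
    "DegenerateProfileError",
    "EstimationFailure",
]


class DegenerateProfileError(ValueError):
    """Observed profile has zero variance; r^2 is undefined."""


class EstimationFailure(RuntimeError):
    """Optimizer did not converge; carries the best value found so far."""

    def __init__(self, message: str, best_pH: float, best_r2: float):
        super().__init__(message)
        self.best_pH = best_pH
        self.best_r2 = best_r2


@dataclass(frozen=True)
class DrugSubstance:
    """Physicochemical identity of a monoprotic weak acid drug substance."""

    name: str
    pKa: float  # pH units
    intrinsic_solubility: float  # S0, mg/mL
    diffusion_coefficient: float  # D, cm^2/min
    true_density: float  # rho, g/mL
    dose: float  # mg (total racemic dose in the dosage form)
    molecular_weight: float  # g/mol

    def __post_init__(self) -> None:
        for name in (
            "pKa",
            "intrinsic_solubility",
            "diffusion_coefficient",
            "true_density",
            "dose",
            "molecular_weight",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.pKa < 14.0):
            raise ValueError("pKa must lie in (0, 14)")

    @property
    def density_mg_per_ml(self) -> float:
        return self.true_density * 1000.0

    @property
    def diffusion_cm2_per_h(self) -> float:
        return self.diffusion_coefficient * 60.0


def ibuprofen(dose: float = 200.0) -> DrugSubstance:
    """Racemic ibuprofen with literature physicochemical defaults.

    S0 = 0.068 mg/mL, pKa 4.45, D 4.5e-4 cm^2/min, density 1.06 g/mL.
    These stand in for platform defaults that are not public; see the
    methods note.
    """
    return DrugSubstance(
        name="ibuprofen",
        pKa=4.45,
        intrinsic_solubility=0.068,
        diffusion_coefficient=4.5e-4,
        true_density=1.06,
        dose=dose,
        molecular_weight=206.28,
    )


@dataclass(frozen=True)
class PSD:
    """Polydisperse particle population: per-bin radius (um) and count.

    Total particle mass must equal the drug dose to within 0.1%.
    """

    radii_um: np.ndarray
    counts: np.ndarray
    dose_mg: float

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_um, dtype=float)
        n = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "radii_um", r)
        object.__setattr__(self, "counts", n)
        if r.ndim != 1 or r.shape != n.shape:
            raise ValueError("radii and counts must be aligned 1-D arrays")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly positive and increasing")
        if np.any(n < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.radii_um.size

    def masses_mg(self, density_mg_per_ml: float) -> np.ndarray:
        r_cm = self.radii_um / UM_PER_CM
        return self.counts * (4.0 / 3.0) * math.pi * density_mg_per_ml * r_cm**3

    def validate_mass(self, drug: DrugSubstance, tol: float = 1e-3) -> None:
        total = float(self.masses_mg(drug.density_mg_per_ml).sum())
        if abs(total - self.dose_mg) > tol * self.dose_mg:
            raise ValueError(
                f"PSD mass {total:.4f} mg differs from dose {self.dose_mg} mg by >{tol:.1%}"
            )


def monodisperse_psd(radius_um: float, drug: DrugSubstance) -> PSD:
    """Single-bin PSD whose particle count carries exactly the dose."""
    r_cm = radius_um / UM_PER_CM
    m_particle = (4.0 / 3.0) * math.pi * drug.density_mg_per_ml * r_cm**3
    return PSD(
        radii_um=np.array([radius_um]),
        counts=np.array([drug.dose / m_particle]),
        dose_mg=drug.dose,
    )


def lognormal_psd(
    drug: DrugSubstance,
    d50_um: float = 100.0,
    geo_sd: float = 1.6,
    n_bins: int = 20,
    n_sigma: float = 3.0,
) -> PSD:
    """Log-spaced bins spanning a lognormal *volume* distribution.

    ``d50_um`` is the volume-median diameter; bin counts are chosen so the
    per-bin masses follow the lognormal volume weights and sum to the dose.
    """
    if d50_um <= 0 or geo_sd <= 1.0 or n_bins < 1:
        raise ValueError("need d50 > 0, geometric SD > 1 and n_bins >= 1")
    mu = math.log(d50_um / 2.0)  # radius scale
    s = math.log(geo_sd)
    edges = np.exp(np.linspace(mu - n_sigma * s, mu + n_sigma * s, n_bins + 1))
    centers = np.sqrt(edges[:-1] * edges[1:])
    z = (np.log(edges) - mu) / s
    cdf = 0.5 * (1.0 + erf(z / math.sqrt(2.0)))
    weights = np.diff(cdf)
    weights = weights / weights.sum()
    r_cm = centers / UM_PER_CM
    m_particle = (4.0 / 3.0) * math.pi * drug.density_mg_per_ml * r_cm**3
    counts = drug.dose * weights / m_particle
    return PSD(radii_um=centers, counts=counts, dose_mg=drug.dose)


@dataclass(frozen=True)
class DissolutionStage:
    medium_name: str
    medium_pH: float
    volume_ml: float
    duration_h: float
    buffer_label: str = ""

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.duration_h <= 0:
            raise ValueError("stage volume and duration must be positive")


@dataclass(frozen=True)
class DissolutionProtocol:
    """Ordered media stages (e.g. acid pretreatment then buffer treatment)."""

    stages: tuple[DissolutionStage, ...]
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def total_duration_h(self) -> float:
        return sum(s.duration_h for s in self.stages)


def single_stage_protocol(
    medium_pH: float, volume_ml: float = 900.0, duration_h: float = 2.0, name: str = "buffer"
) -> DissolutionProtocol:
    return DissolutionProtocol(
        stages=(DissolutionStage(name, medium_pH, volume_ml, duration_h),)
    )


def two_stage_protocol(
    pretreatment_pH: float,
    treatment_pH: float,
    pretreatment_duration_h: float = 0.5,
    treatment_duration_h: float = 2.0,
    pretreatment_volume_ml: float = 500.0,
    treatment_volume_ml: float = 900.0,
    treatment_name: str = "buffer",
) -> DissolutionProtocol:
    """Acid pretreatment followed by a buffer treatment stage."""
    return DissolutionProtocol(
        stages=(
            DissolutionStage("HCl", pretreatment_pH, pretreatment_volume_ml, pretreatment_duration_h),
            DissolutionStage(treatment_name, treatment_pH, treatment_volume_ml, treatment_duration_h),
        )
    )


@dataclass(frozen=True)
class DissolutionProfile:
    times_h: np.ndarray
    fraction_dissolved_pct: np.ndarray
    product_label: str = "reference"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.fraction_dissolved_pct, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "fraction_dissolved_pct", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fractions must be aligned 1-D arrays")
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("times must be nonnegative and strictly increasing")


@dataclass
class DLMState:
    """Solver state snapshot: per-bin radii, dissolved mass, bulk concentration."""

    radii_um: np.ndarray
    dissolved_mg: float
    bulk_conc_mg_ml: float
    surface_pH: float
    h_eff_um: np.ndarray
    supersaturated: bool = False


def surface_solubility(
    drug: DrugSubstance, surface_pH: float, solubility_factor: float = 1.0
) -> float:
    """Weak-acid solubility at the particle surface, mg/mL.

    Henderson-Hasselbalch total solubility ``S0 * (1 + SF * 10^(pH - pKa))``
    with the solubility factor SF scaling the ionized contribution
    (default 1); strictly increasing in surface pH.
    """
    if not (0.0 < surface_pH < 14.0):
        raise ValueError("surface pH must lie in (0, 14)")
    if solubility_factor <= 0:
        raise ValueError("solubility factor must be positive")
    return drug.intrinsic_solubility * (
        1.0 + solubility_factor * 10.0 ** (surface_pH - drug.pKa)
    )


def _stage_effective_surface_pH(surface_pH: float, medium_pH: float) -> float:
    # a weak acid's self-buffering lowers surface pH below bulk, never above
    return min(surface_pH, medium_pH)


def simulate_dissolution(
    drug: DrugSubstance,
    psd: PSD,
    protocol: DissolutionProtocol,
    surface_pH: float,
    h_max_um: float = 30.0,
    times_h: Sequence[float] | None = None,
    solubility_factor: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    return_state: bool = False,
    warn_supersaturation: bool = True,
):
    """Integrate the staged DLM and return fraction dissolved vs time.

    Parameters
    ----------
    surface_pH
        Particle surface pH, constant in time; within each stage the
        effective value is capped at the stage medium pH.
    h_max_um
        Diffusion-layer thickness cap; ``h_i = min(r_i, h_max)``.
    times_h
        Observation times (cumulative over stages). Defaults to a dense
        grid over the protocol.

    Returns
    -------
    DissolutionProfile (and the final DLMState when ``return_state``).
    Mass is conserved by construction (dissolved = dose - remaining solid);
    the dissolution flux is floored at zero so a saturated bulk never
    redeposits mass.
    """
    psd.validate_mass(drug)
    if times_h is None:
        times_h = np.linspace(0.0, protocol.total_duration_h, 121)[1:]
    t_obs = np.asarray(times_h, dtype=float)
    if t_obs.size == 0:
        raise ValueError("at least one observation time is required")
    if np.any(t_obs < 0) or np.any(np.diff(t_obs) <= 0):
        raise ValueError("observation times must be nonnegative and strictly increasing")
    if t_obs[-1] > protocol.total_duration_h + 1e-9:
        raise ValueError("observation times extend beyond the protocol duration")

    rho = drug.density_mg_per_ml
    D = drug.diffusion_cm2_per_h
    h_max_cm = h_max_um / UM_PER_CM
    r_min_cm = R_MIN_UM / UM_PER_CM
    counts = psd.counts
    vol_coef = (4.0 / 3.0) * math.pi * rho  # mass = vol_coef * N * r^3

    def solid_mass(r_cm: np.ndarray) -> float:
        return float(vol_coef * np.sum(counts * np.clip(r_cm, 0.0, None) ** 3))

    r_cm = psd.radii_um / UM_PER_CM
    # per-bin shutoff band: freeze below 0.5% of the initial radius (mass
    # error 1.25e-7 of bin mass) but never below the global r_min floor
    band_cm = np.maximum(0.005 * r_cm, 2.0 * r_min_cm)
    carry_mg = 0.0  # dissolved mass carried across stages
    frac_out = np.empty_like(t_obs)
    t0 = 0.0
    saw_supersat = False

    for stage in protocol.stages:
        s_eff_pH = _stage_effective_surface_pH(surface_pH, stage.medium_pH)
        s_surf = surface_solubility(drug, s_eff_pH, solubility_factor)
        s_bulk = surface_solubility(drug, stage.medium_pH, solubility_factor)
        vol = stage.volume_ml
        solid_at_entry = solid_mass(r_cm)

        def rhs(t, y, _solid0=solid_at_entry, _ssurf=s_surf, _vol=vol, _carry=carry_mg):
            r = np.clip(y, 0.0, None)
            dissolved = _carry + (_solid0 - solid_mass(r))
            c_bulk = dissolved / _vol
            h = np.minimum(np.maximum(r, r_min_cm), h_max_cm)
            grad = max(_ssurf - c_bulk, 0.0)
            drdt = -(D / (rho * h)) * grad
            # smooth shutoff keeps the RHS Lipschitz at r -> 0
            x = np.clip((r - r_min_cm) / band_cm, 0.0, 1.0)
            drdt *= x * x * (3.0 - 2.0 * x)
            return drdt

        t1 = t0 + stage.duration_h
        mask = (t_obs > t0 + 1e-12) & (t_obs <= t1 + 1e-12)
        eval_ts = np.clip(t_obs[mask] - t0, 0.0, stage.duration_h)
        sol = solve_ivp(
            rhs,
            (0.0, stage.duration_h),
            r_cm,
            method="LSODA",
            t_eval=np.unique(np.concatenate([eval_ts, [stage.duration_h]])),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"DLM integration failed in stage {stage.medium_name}: {sol.message}")
        radii_traj = np.clip(sol.y, 0.0, None)
        diss_traj = carry_mg + (solid_at_entry - np.array([solid_mass(radii_traj[:, k]) for k in range(radii_traj.shape[1])]))
        if eval_ts.size:
            # map observation times onto the solver grid
            idx = np.searchsorted(sol.t, eval_ts)
            frac_out[mask] = 100.0 * diss_traj[idx] / drug.dose
        r_cm = radii_traj[:, -1]
        carry_mg = float(diss_traj[-1])
        if carry_mg / vol > s_bulk + 1e-12:
            saw_supersat = True
        t0 = t1

    frac_out = np.clip(frac_out, 0.0, 100.0)
    if np.any(t_obs <= 1e-12):
        frac_out[t_obs <= 1e-12] = 0.0

    if saw_supersat and warn_supersaturation:
        warnings.warn(
            "bulk concentration exceeded medium-pH solubility; precipitation is not modeled",
            RuntimeWarning,
            stacklevel=2,
        )

    profile = DissolutionProfile(times_h=t_obs, fraction_dissolved_pct=frac_out)
    if return_state:
        last_stage = protocol.stages[-1]
        r_um = r_cm * UM_PER_CM
        state = DLMState(
            radii_um=r_um,
            dissolved_mg=carry_mg,
            bulk_conc_mg_ml=carry_mg / last_stage.volume_ml,
            surface_pH=surface_pH,
            h_eff_um=np.minimum(np.maximum(r_um, R_MIN_UM), h_max_um),
            supersaturated=saw_supersat,
        )
        return profile, state
    return profile


def goodness_r2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted fractions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("observed and predicted must be aligned with >= 3 points")
    if np.ptp(obs) == 0.0:
        raise DegenerateProfileError("observed profile has zero variance")
    if np.ptp(pred) == 0.0:
        return 0.0
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def fit_surface_pH(
    profile: DissolutionProfile,
    drug: DrugSubstance,
    psd: PSD,
    protocol: DissolutionProtocol,
    init: float = 5.5,
    bounds: tuple[float, float] = (3.0, 8.0),
    h_max_um: float = 30.0,
    xatol: float = 1e-4,
    max_iter: int = 200,
    r2_threshold: float = 0.90,
) -> tuple[float, float]:
    """Estimate particle surface pH by least squares on fraction dissolved.

    A Nelder-Mead simplex search (proposals reflected back into ``bounds``)
    minimizes the sum of squared residuals between the observed profile and
    the DLM forward simulation; the fit quality is the squared Pearson
    correlation of observed vs predicted (acceptable when r^2 exceeds
    ``r2_threshold``).

    Returns ``(surface_pH_hat, r2)``. Raises EstimationFailure (carrying the
    best-so-far values) on non-convergence.
    """
    if profile.times_h.size < 3:
        raise ValueError("need at least 3 observed time points")
    if not (bounds[0] < init < bounds[1]):
        raise ValueError("initial surface pH must lie inside the bounds")
    if np.ptp(profile.fraction_dissolved_pct) == 0.0:
        raise DegenerateProfileError("observed profile has zero variance")

    obs = profile.fraction_dissolved_pct
    t_obs = profile.times_h

    def predict(pH: float) -> np.ndarray:
        sim = simulate_dissolution(
            drug, psd, protocol, pH, h_max_um=h_max_um, times_h=t_obs,
            warn_supersaturation=False,
        )
        return sim.fraction_dissolved_pct

    lo, hi = bounds
    width = hi - lo

    def reflect(x: float) -> float:
        # fold proposals back into (lo, hi): triangle-wave reflection
        y = (x - lo) % (2.0 * width)
        return lo + (y if y <= width else 2.0 * width - y)

    def ssr(x: np.ndarray) -> float:
        return float(np.sum((obs - predict(reflect(float(x[0])))) ** 2))

    # convergence on simplex spread alone (fatol disabled): with noisy data
    # the SSR spread across an xatol-sized simplex never shrinks to zero
    res = minimize(
        ssr, x0=np.array([init]), method="Nelder-Mead",
        options={"xatol": xatol, "fatol": float("inf"), "maxiter": max_iter},
    )
    pH_hat = reflect(float(res.x[0]))
    r2 = goodness_r2(obs, predict(pH_hat))
    if not res.success:
        raise EstimationFailure("surface-pH estimation did not converge", pH_hat, r2)
    return pH_hat, r2
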