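"""Average-bioequivalence statistics for 2x2 crossover trials.

Implements the log-scale analysis of Cmax used in standard average-BE
testing: geometric mean ratio (GMR) with its 90% confidence interval,
the two one-sided tests (TOST) decision against 80.00-125.00% limits,
within-/between-subject variance-component estimation, planning-mode CI
prediction at a given sample size, and the normal-quantile TOST sample
size rounded up to the next even integer.

Conventions
-----------
* Variability is expressed as a lognormal CV in percent; the log-scale
  variance is ``sigma^2 = ln(1 + CV^2)``.
* The crossover CI uses ``df = n - 2`` (sequence term in the crossover
  ANOVA); a paired ``df = n - 1`` variant is available but non-default.
* Sample sizes use the normal-quantile approximation; an exact
  noncentral-t iteration is available behind ``method="exact"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

BE_LIMITS: tuple[float, float] = (0.80, 1.25)
ALPHA = 0.05

__all__ = [
    "BEOutcome",
    "SampleSizePlan",
    "cv_to_sigma2",
    "sigma2_to_cv",
    "crossover_be",
    "estimate_variance_components",
    "sample_size",
    "tost_power",
    "predict_ci",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a BE analysis is attempted with too few subjects."""


def cv_to_sigma2(cv_pct: float) -> float:
    """Log-scale variance for a lognormal CV given in percent."""
    if cv_pct < 0:
        raise ValueError("CV must be nonnegative")
    cv = cv_pct / 100.0
    return math.log1p(cv * cv)


def sigma2_to_cv(sigma2: float) -> float:
    """Lognormal CV in percent from a log-scale variance."""
    return math.sqrt(math.expm1(sigma2)) * 100.0


@dataclass(frozen=True)
class BEOutcome:
    """Result of a 2x2 crossover average-BE analysis of one analyte."""

    analyte: str
    gmr_pct: float
    ci90_pct: tuple[float, float]
    decision: bool
    n: int
    wsv_cv_pct: float
    df: int

    def __post_init__(self) -> None:
        lo, hi = self.ci90_pct
        if not (lo <= self.gmr_pct <= hi):
            raise ValueError("GMR must lie inside its CI")


@dataclass(frozen=True)
class SampleSizePlan:
    """Planning assumptions and the resulting sample sizes and predicted CI."""

    gmr_pct: float
    wsv_cv_pct: float
    n_80: int
    n_90: int
    ci90_at_n80_pct: tuple[float, float]
    alpha: float = ALPHA


def crossover_be(
    log_test: Sequence[float],
    log_ref: Sequence[float],
    analyte: str = "racemate",
    df_rule: Literal["sequence", "paired"] = "sequence",
    limits: tuple[float, float] = BE_LIMITS,
) -> BEOutcome:
    """Average-BE analysis of paired log-Cmax values from a 2x2 crossover.

    Parameters
    ----------
    log_test, log_ref
        Per-subject natural-log Cmax under test and reference, aligned by
        subject.
    df_rule
        ``"sequence"`` uses ``df = n - 2`` (crossover ANOVA with a sequence
        term, the default); ``"paired"`` uses ``df = n - 1``.

    Returns
    -------
    BEOutcome with GMR (%), the 90% CI (%), the TOST decision against
    ``limits``, and the within-subject CV implied by the period differences
    (``sd(d)^2 = 2 sigma_w^2``).
    """
    t = np.asarray(log_test, dtype=float)
    r = np.asarray(log_ref, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("log_test and log_ref must be 1-D and aligned")
    n = t.size
    if n < 3:
        raise InsufficientDataError(f"n={n} subjects; need at least 3")
    d = t - r
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 2 if df_rule == "sequence" else n - 1
    tcrit = stats.t.ppf(0.95, df)
    half = tcrit * sd_d / math.sqrt(n)
    gmr = math.exp(mean_d)
    lo, hi = gmr * math.exp(-half), gmr * math.exp(half)
    decision = (limits[0] * 100.0 <= lo * 100.0) and (hi * 100.0 <= limits[1] * 100.0)
    wsv_cv = sigma2_to_cv(sd_d * sd_d / 2.0)
    return BEOutcome(
        analyte=analyte,
        gmr_pct=gmr * 100.0,
        ci90_pct=(lo * 100.0, hi * 100.0),
        decision=decision,
        n=n,
        wsv_cv_pct=wsv_cv,
        df=df,
    )


def estimate_variance_components(log_values: np.ndarray) -> tuple[float, float]:
    """Within- and between-subject CVs from a subjects x periods log matrix.

    One-way random-effects moment decomposition on the log scale:
    the within mean square estimates ``sigma_w^2`` and the between mean
    square estimates ``sigma_w^2 + p sigma_b^2``. Negative moment estimates
    of ``sigma_b^2`` are truncated at zero.

    Returns ``(WSV_CV %, BSV_CV %)``.
    """
    y = np.asarray(log_values, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a subjects x periods matrix")
    n, p = y.shape
    if p < 2:
        raise InsufficientDataError("at least 2 periods per subject are needed for WSV")
    subj_means = y.mean(axis=1)
    msw = float(((y - subj_means[:, None]) ** 2).sum() / (n * (p - 1)))
    msb = float(p * ((subj_means - subj_means.mean()) ** 2).sum() / (n - 1))
    sigma2_w = msw
    sigma2_b = max((msb - msw) / p, 0.0)
    return sigma2_to_cv(sigma2_w), sigma2_to_cv(sigma2_b)


def _theta_near(gmr: float, limits: tuple[float, float]) -> float:
    lo, hi = limits
    return lo if abs(math.log(gmr) - math.log(lo)) <= abs(math.log(gmr) - math.log(hi)) else hi


def sample_size(
    gmr: float,
    wsv_cv_pct: float,
    power: float,
    alpha: float = ALPHA,
    limits: tuple[float, float] = BE_LIMITS,
    method: Literal["normal", "exact"] = "normal",
) -> int:
    """Total crossover sample size (rounded up to even) to declare BE.

    The default normal-quantile rule is

        ``n = 2 (z_{1-a} + z_{1-b})^2 ln(1+CV^2) / (ln GMR - ln theta)^2``

    with ``theta`` the BE limit nearer to the GMR on the log scale, and
    ``z_{1-b/2}`` when GMR is exactly 1. ``method="exact"`` instead searches
    for the smallest even n whose noncentral-t TOST power reaches ``power``.
    """
    if not (limits[0] < gmr < limits[1]):
        raise ValueError("GMR on or outside the BE limits has zero power")
    if not (0.0 < power < 1.0):
        raise ValueError("power must be in (0, 1)")
    sigma2 = cv_to_sigma2(wsv_cv_pct)
    log_dist = abs(math.log(gmr) - math.log(_theta_near(gmr, limits)))
    za = stats.norm.ppf(1 - alpha)
    beta = 1 - power
    zb = stats.norm.ppf(1 - beta / 2) if math.isclose(gmr, 1.0) else stats.norm.ppf(1 - beta)
    n_real = 2.0 * (za + zb) ** 2 * sigma2 / (log_dist**2)
    n = int(math.ceil(n_real))
    if n % 2:
        n += 1
    n = max(n, 4)
    if method == "exact":
        while n > 4 and tost_power(gmr, wsv_cv_pct, n - 2, alpha, limits) >= power:
            n -= 2
        while tost_power(gmr, wsv_cv_pct, n, alpha, limits) < power:
            n += 2
    return n


def tost_power(
    gmr: float,
    wsv_cv_pct: float,
    n: int,
    alpha: float = ALPHA,
    limits: tuple[float, float] = BE_LIMITS,
) -> float:
    """Noncentral-t TOST power of a 2x2 crossover with n subjects total.

    Uses the two shifted noncentral-t rejection probabilities; the small
    joint-event correction is ignored (standard practice for planning).
    """
    if n < 4:
        return 0.0
    sigma = math.sqrt(cv_to_sigma2(wsv_cv_pct))
    se = sigma * math.sqrt(2.0 / n)
    df = n - 2
    tcrit = stats.t.ppf(1 - alpha, df)
    ncp_lo = (math.log(gmr) - math.log(limits[0])) / se
    ncp_hi = (math.log(gmr) - math.log(limits[1])) / se
    p = stats.nct.cdf(-tcrit, df, ncp_hi) - stats.nct.cdf(tcrit, df, ncp_lo)
    return max(float(p), 0.0)


def predict_ci(
    gmr: float,
    wsv_cv_pct: float,
    n: int,
    df_rule: Literal["sequence", "paired"] = "sequence",
) -> tuple[float, float]:
    """Expected 90% CI (in %) of the GMR at sample size n.

    ``CI = GMR exp(+- t_{0.95, n-2} sqrt(ln(1+CV^2)) sqrt(2/n))``, the
    planning-mode counterpart of :func:`crossover_be`.
    """
    if n < 4:
        raise InsufficientDataError("n must be at least 4 for a planning CI")
    sigma = math.sqrt(cv_to_sigma2(wsv_cv_pct))
    df = n - 2 if df_rule == "sequence" else n - 1
    half = stats.t.ppf(0.95, df) * sigma * math.sqrt(2.0 / n)
    return gmr * math.exp(-half) * 100.0, gmr * math.exp(half) * 100.0


def plan(gmr: float, wsv_cv_pct: float) -> SampleSizePlan:
    """Sample sizes at 80/90% power plus the predicted CI at the 80%-power n."""
    n80 = sample_size(gmr, wsv_cv_pct, 0.80)
    n90 = sample_size(gmr, wsv_cv_pct, 0.90)
    return SampleSizePlan(
        gmr_pct=gmr * 100.0,
        wsv_cv_pct=wsv_cv_pct,
        n_80=n80,
        n_90=n90,
        ci90_at_n80_pct=predict_ci(gmr, wsv_cv_pct, n80),
    )
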