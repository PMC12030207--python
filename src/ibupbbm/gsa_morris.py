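"""Morris elementary-effects screening (one-at-a-time global sensitivity).

The classic randomized-trajectory design on a p-level grid in the unit
hypercube: each trajectory perturbs every factor once by Delta =
p / (2(p-1)), and the elementary effects EE_i = (f(x +- Delta e_i) - f(x))
/ (+-Delta) are summarized per factor as mu (mean), mu* (mean absolute)
and sigma (SD). mu* ranks overall influence; sigma flags nonlinearity or
interactions. Factors are screened on their unit-scaled ranges so mu* is
comparable across parameters with different units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["MorrisPlan", "MorrisResult", "morris_screen", "select_driver"]


@dataclass(frozen=True)
class MorrisPlan:
    """Screening design: factor ranges, grid levels p and trajectories r."""

    parameters: tuple[tuple[str, float, float], ...]  # (name, min, max)
    levels: int = 4
    trajectories: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        params = tuple((str(n), float(a), float(b)) for n, a, b in self.parameters)
        object.__setattr__(self, "parameters", params)
        if not params:
            raise ValueError("need at least one parameter")
        if any(a >= b for _, a, b in params):
            raise ValueError("every parameter needs min < max")
        if self.levels < 4 or self.levels % 2:
            raise ValueError("levels p must be even and >= 4")
        if self.trajectories < 2:
            raise ValueError("need at least 2 trajectories")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.parameters)


@dataclass(frozen=True)
class MorrisResult:
    names: tuple[str, ...]
    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray
    n_evaluations: int

    def ranking(self) -> list[str]:
        """Names in descending mu*; ties broken by larger sigma, then name."""
        order = sorted(
            range(len(self.names)),
            key=lambda i: (-self.mu_star[i], -self.sigma[i], self.names[i]),
        )
        return [self.names[i] for i in order]


def morris_screen(
    model: Callable[[np.ndarray], float],
    plan: MorrisPlan,
) -> MorrisResult:
    """Run the screening; ``model`` maps a physical parameter vector to a scalar.

    Elementary effects are computed in unit-scaled space, so a parameter's
    mu* is per unit of its own full range. Costs ``r * (k + 1)`` model
    evaluations for k parameters. Raises on non-finite model output.
    """
    rng = np.random.default_rng(plan.seed)
    k = len(plan.parameters)
    p = plan.levels
    delta = p / (2.0 * (p - 1.0))
    lo = np.array([a for _, a, _ in plan.parameters])
    span = np.array([b - a for _, a, b in plan.parameters])
    grid = np.arange(p) / (p - 1.0)

    def evaluate(x_unit: np.ndarray) -> float:
        y = float(model(lo + span * x_unit))
        if not math.isfinite(y):
            raise ValueError(f"model returned non-finite output at {lo + span * x_unit}")
        return y

    ee = np.empty((plan.trajectories, k))
    n_eval = 0
    for t in range(plan.trajectories):
        direction = rng.choice([-1.0, 1.0], size=k)
        x = np.empty(k)
        for i in range(k):
            feasible = grid[(grid + direction[i] * delta >= -1e-12) & (grid + direction[i] * delta <= 1.0 + 1e-12)]
            x[i] = rng.choice(feasible)
        order = rng.permutation(k)
        f_cur = evaluate(x)
        n_eval += 1
        for i in order:
            x_new = x.copy()
            x_new[i] = min(max(x[i] + direction[i] * delta, 0.0), 1.0)
            f_new = evaluate(x_new)
            n_eval += 1
            ee[t, i] = (f_new - f_cur) / (direction[i] * delta)
            x, f_cur = x_new, f_new

    return MorrisResult(
        names=plan.names,
        mu=ee.mean(axis=0),
        mu_star=np.abs(ee).mean(axis=0),
        sigma=ee.std(axis=0, ddof=1),
        n_evaluations=n_eval,
    )


def select_driver(result: MorrisResult) -> str:
    """The mu*-maximal parameter (ties: larger sigma, then lexicographic)."""
    if len(result.names) == 0:
        raise ValueError("empty screening result")
    return result.ranking()[0]
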