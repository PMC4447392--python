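"""Calibration of under-documented parameters against summary statistics.

The p21->senescence accumulation rate, the Ku/PARP depletion kinetics, the
DSB yield and the pulse-detector thresholds are only weakly constrained by
mechanism; they are fitted here by minimizing a weighted squared relative
error between simulated summary statistics and target values.  The
objective is stochastic, so evaluation uses common random numbers (a fixed
seed shared across evaluations) and the optimizer is a derivative-free
bounded Nelder–Mead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .model import ModelSpec

__all__ = ["CalibrationTarget", "summary_loss", "fit_parameters", "FitResult"]


@dataclass(frozen=True)
class CalibrationTarget:
    """A named summary statistic with target value, weight and tolerance."""

    name: str
    value: float
    weight: float = 1.0
    tolerance: float = 0.0   # informational; not used by the loss

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("target weight must be > 0")


SummaryFn = Callable[[ModelSpec, int, int], Mapping[str, float]]
"""Signature: (model, n_replicates, seed) -> {statistic name: value}."""


def summary_loss(
    model: ModelSpec,
    overlay: Mapping[str, float],
    targets: Sequence[CalibrationTarget],
    summary_fn: SummaryFn,
    n: int = 50,
    seed: int = 0,
) -> float:
    """Weighted squared relative error of simulated summaries vs targets.

    Deterministic given (overlay, seed, n).  A failed simulation yields an
    infinite loss.
    """
    try:
        sim = summary_fn(model.with_overrides(dict(overlay)), n, seed)
    except Exception as exc:  # noqa: BLE001 - any engine failure is a bad point
        import warnings

        warnings.warn(f"simulation failed during calibration: {exc}")
        return float("inf")
    loss = 0.0
    for tgt in targets:
        v = sim[tgt.name]
        if not np.isfinite(v):
            return float("inf")
        denom = abs(tgt.value) if tgt.value != 0 else 1.0
        loss += tgt.weight * ((v - tgt.value) / denom) ** 2
    return float(loss)


@dataclass(frozen=True)
class FitResult:
    overlay: dict[str, float]
    loss: float
    n_evaluations: int
    trace: tuple[tuple[dict[str, float], float], ...]


def fit_parameters(
    model: ModelSpec,
    free: Mapping[str, tuple[float, float]],
    targets: Sequence[CalibrationTarget],
    summary_fn: SummaryFn,
    budget: int = 500,
    n: int = 50,
    seed: int = 0,
) -> FitResult:
    """Bounded derivative-free local fit of ``free`` parameters.

    ``free`` maps parameter names to (lower, upper) bounds; the initial
    point is the model's current value, which must lie inside the bounds.
    The returned overlay never has a loss above the initial point's.
    ``budget`` caps the number of objective evaluations; budget 0 returns
    the initial point.
    """
    names = list(free)
    lo = np.array([free[k][0] for k in names], dtype=float)
    hi = np.array([free[k][1] for k in names], dtype=float)
    x0 = np.array([model.parameters.value(k) for k in names], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial parameter values violate the given bounds")

    trace: list[tuple[dict[str, float], float]] = []

    def objective(x: np.ndarray) -> float:
        overlay = {k: float(v) for k, v in zip(names, x)}
        L = summary_loss(model, overlay, targets, summary_fn, n=n, seed=seed)
        trace.append((overlay, L))
        return L

    f0 = objective(x0)
    if budget <= 1:
        return FitResult({k: float(v) for k, v in zip(names, x0)}, f0, len(trace), tuple(trace))

    optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=optimize.Bounds(lo, hi),
        options={"maxfev": budget - 1, "xatol": 1e-8, "fatol": 1e-10},
    )
    best_overlay, best_loss = min(trace, key=lambda t: t[1])
    return FitResult(dict(best_overlay), float(best_loss), len(trace), tuple(trace))
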