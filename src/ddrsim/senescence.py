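"""Senescent-fraction statistics: dose–response and protocol comparisons.

Senescence is called from the model's Sen state flag (the irreversible
counter switch), not from a staining proxy.  Default horizons follow the
study design: 84 h after irradiation for dose–response runs, 30 h from the
start for background-ROS runs.  Confidence intervals are exact
Clopper–Pearson.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TrajectorySet, simulate_population
from .model import ModelSpec
from .protocols import Protocol

__all__ = [
    "senescent_fraction",
    "clopper_pearson",
    "dose_response_table",
    "chi_square_compare",
    "SenescenceError",
]


class SenescenceError(ValueError):
    pass


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n <= 0:
        raise SenescenceError("n must be positive")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def senescent_fraction(
    trajectories: TrajectorySet | Sequence, at: float
) -> tuple[float, tuple[float, float]]:
    """Fraction of cells senescent at time ``at`` (min), with exact 95% CI."""
    trs = list(trajectories)
    if not trs:
        raise SenescenceError("empty trajectory set")
    for tr in trs:
        if tr.times[-1] + 1e-9 < at:
            raise SenescenceError("trajectory does not cover the requested time")
    k = sum(tr.senescent_at(at) for tr in trs)
    n = len(trs)
    return k / n, clopper_pearson(k, n)


def dose_response_table(
    model: ModelSpec,
    protocols: Sequence[Protocol],
    duration: float,
    n: int,
    base_seed: int,
    at: float | None = None,
    sample_every: float = 5.0,
) -> pd.DataFrame:
    """Senescent fractions for a list of protocols (deterministic in seed).

    ``at`` defaults to 84 h after the first irradiation event of each
    protocol (or 30 h from start for unirradiated protocols).
    """
    rows = []
    for j, protocol in enumerate(protocols):
        pop = simulate_population(
            model, protocol, duration, n=n, base_seed=base_seed + j * n,
            sample_every=sample_every,
        )
        t0 = protocol.first_irradiation_min
        horizon = at if at is not None else (
            t0 + 84 * 60.0 if t0 is not None else 30 * 60.0
        )
        frac, (lo, hi) = senescent_fraction(pop, horizon)
        rows.append(
            {
                "protocol": protocol.label or f"protocol_{j}",
                "n_cells": len(pop),
                "n_senescent": int(round(frac * len(pop))),
                "fraction": frac,
                "ci_low": lo,
                "ci_high": hi,
                "horizon_min": horizon,
            }
        )
    return pd.DataFrame(rows)


def chi_square_compare(
    observed: Sequence[float], expected: Sequence[float] | None = None,
    second_sample: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Pearson chi-square.

    With ``expected``: goodness-of-fit against expected counts.  With
    ``second_sample``: 2xk homogeneity test of two count vectors (e.g.
    senescent/non-senescent in two groups).
    """
    obs = np.asarray(observed, dtype=float)
    if (expected is None) == (second_sample is None):
        raise SenescenceError("give exactly one of expected / second_sample")
    if len(obs) < 2 or np.any(obs < 0):
        raise SenescenceError("need >= 2 non-negative counts")
    if expected is not None:
        exp = np.asarray(expected, dtype=float)
        if np.any(exp == 0):
            raise SenescenceError("zero expected count")
        exp = exp * obs.sum() / exp.sum()
        stat, p = stats.chisquare(obs, exp)
        return float(stat), float(p)
    table = np.vstack([obs, np.asarray(second_sample, dtype=float)])
    if np.any(table.sum(axis=0) == 0):
        raise SenescenceError("zero expected count in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
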