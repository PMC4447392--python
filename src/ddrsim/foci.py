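"""Focus-lifetime survival analysis.

Per-focus lifetimes are read from the trajectory's exact event log (the
sampling grid is for plotting only); episodes still open at the end of a
run are right-censored.  Survival curves use the Kaplan–Meier estimator
and groups are compared with the standard log-rank test, both via
``lifelines``.  Ties follow the usual convention: censored observations at
a tied time are taken to occur after the deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .engine import Trajectory

__all__ = [
    "FocusInterval",
    "SurvivalCurve",
    "extract_focus_intervals",
    "km_estimate",
    "logrank_test",
    "FociError",
]


class FociError(ValueError):
    pass


@dataclass(frozen=True)
class FocusInterval:
    site: int
    formation: float
    resolution: float  # censor time when censored
    censored: bool

    def __post_init__(self) -> None:
        if not self.censored and self.resolution <= self.formation:
            raise FociError("resolution must follow formation")

    @property
    def lifetime(self) -> float:
        return self.resolution - self.formation


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray         # ordered event times
    survival: np.ndarray      # S(t) right after each time
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise FociError("survival must be non-increasing")

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def extract_focus_intervals(
    trajectory: Trajectory, censor_at: float | None = None
) -> list[FocusInterval]:
    """One interval per focus episode; same-site episodes count separately."""
    log = trajectory.focus_episodes
    if log.ndim != 2 or (log.size and log.shape[1] != 3):
        raise FociError("malformed focus event log")
    t_end = censor_at if censor_at is not None else float(trajectory.times[-1])
    out = []
    for site, t0, t1 in log:
        if t0 > t_end:
            continue
        if np.isnan(t1) or t1 > t_end:
            out.append(FocusInterval(int(site), float(t0), t_end, True))
        else:
            out.append(FocusInterval(int(site), float(t0), float(t1), False))
    return out


def _durations(intervals: Sequence[FocusInterval]) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([iv.lifetime for iv in intervals], dtype=float)
    observed = np.array([not iv.censored for iv in intervals], dtype=bool)
    return d, observed


def km_estimate(intervals: Sequence[FocusInterval]) -> SurvivalCurve:
    """Kaplan–Meier survival of focus lifetimes with right-censoring."""
    if len(intervals) == 0:
        raise FociError("need at least one interval")
    d, observed = _durations(intervals)
    if not observed.any():
        import warnings

        warnings.warn("all intervals censored; survival is constant at 1")
        return SurvivalCurve(
            times=np.array([0.0]), survival=np.array([1.0]),
            at_risk=np.array([len(intervals)]),
        )
    kmf = KaplanMeierFitter()
    kmf.fit(d, event_observed=observed)
    # drop the t=0 anchor row unless an event happened at 0
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def logrank_test(
    group_a: Sequence[FocusInterval], group_b: Sequence[FocusInterval]
) -> tuple[float, float]:
    """Log-rank chi-square (1 df) comparing two interval sets."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise FociError("both groups must be non-empty")
    da, oa = _durations(group_a)
    db, ob = _durations(group_b)
    res = _ll_logrank(da, db, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


def intervals_from_frame(df: pd.DataFrame) -> list[FocusInterval]:
    """Read externally supplied lifetimes (columns lifetime_min, censored)."""
    return [
        FocusInterval(-1, 0.0, float(r.lifetime_min), bool(r.censored))
        for r in df.itertuples()
    ]
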