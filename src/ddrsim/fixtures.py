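"""Synthetic inputs with known ground truth for testing the analysis stages.

These generators emulate the *shape* of simulator output (p53 traces with
pulses of prescribed width/amplitude, per-site focus event logs) without
running the mechanistic model, so the pulse detector and survival analysis
can be tested against exact ground truth.  They intentionally do not
emulate the mechanistic correlations between ROS, foci and p53 — that is
the simulator's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import Trajectory, TRAJECTORY_COLUMNS
from .protocols import Protocol
from .pulses import Pulse

__all__ = ["SyntheticTraceSpec", "make_p53_trace", "make_focus_log", "FixtureError"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Ground-truth description of a synthetic p53 trace.

    Pulses are triangular or gaussian bumps added to a constant baseline
    with iid gaussian noise.  Overlapping pulses are rejected so the truth
    stays unambiguous.
    """

    baseline: float = 25.0
    noise_sd: float = 0.0
    peak_times: tuple[float, ...] = ()
    amplitudes: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()       # full width at half maximum, min
    shape: str = "triangular"            # "triangular" | "gaussian"
    duration: float = 1800.0
    sample_every: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise FixtureError("noise SD must be >= 0")
        if not (len(self.peak_times) == len(self.amplitudes) == len(self.widths)):
            raise FixtureError("peak_times, amplitudes, widths must align")
        if self.shape not in ("triangular", "gaussian"):
            raise FixtureError(f"unknown pulse shape {self.shape!r}")
        order = np.argsort(self.peak_times)
        tp = np.asarray(self.peak_times, float)[order]
        w = np.asarray(self.widths, float)[order]
        for t, width in zip(tp, w):
            if not 0 < t < self.duration:
                raise FixtureError("pulse peak outside trace duration")
        # a triangular pulse of FWHM w has base width 2w
        for (t1, w1), (t2, w2) in zip(zip(tp, w), zip(tp[1:], w[1:])):
            if t1 + w1 > t2 - w2:
                raise FixtureError("overlapping pulses make the truth ambiguous")


def make_p53_trace(spec: SyntheticTraceSpec) -> tuple[np.ndarray, np.ndarray, list[Pulse]]:
    """Generate (times, values, truth) for a synthetic trace.

    The returned truth lists one :class:`~ddrsim.pulses.Pulse` per bump
    with exact peak time, amplitude and FWHM.
    """
    times = np.arange(0.0, spec.duration + 1e-9, spec.sample_every)
    values = np.full_like(times, float(spec.baseline))
    truth = []
    for tp, amp, w in sorted(zip(spec.peak_times, spec.amplitudes, spec.widths)):
        if spec.shape == "triangular":
            # triangle with FWHM w -> half-base w
            contrib = amp * np.clip(1.0 - np.abs(times - tp) / w, 0.0, None)
            start, end = tp - w / 2, tp + w / 2
        else:
            sigma = w / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            contrib = amp * np.exp(-0.5 * ((times - tp) / sigma) ** 2)
            start, end = tp - w / 2, tp + w / 2
        values += contrib
        truth.append(Pulse(start, float(tp), end, float(amp), float(w)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=len(times))
    return times, values, truth


def make_focus_log(
    lifetimes: Sequence[float],
    censor_at: float,
    start_times: Sequence[float] | None = None,
    sites: Sequence[int] | None = None,
    sample_every: float = 5.0,
) -> Trajectory:
    """Build a synthetic trajectory carrying a per-site focus event log.

    Episode ``i`` starts at ``start_times[i]`` (default 0) and resolves
    after ``lifetimes[i]`` minutes; resolutions past ``censor_at`` are left
    open, exactly as the simulator records a focus that outlives the run.
    ``extract_focus_intervals`` inverts this construction exactly.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if np.any(lifetimes <= 0):
        raise FixtureError("lifetimes must be positive")
    n = len(lifetimes)
    starts = (
        np.zeros(n) if start_times is None else np.asarray(start_times, dtype=float)
    )
    site_ids = np.arange(n) % 50 if sites is None else np.asarray(sites)
    log = np.empty((n, 3))
    for i in range(n):
        t1 = starts[i] + lifetimes[i]
        log[i] = (site_ids[i], starts[i], t1 if t1 <= censor_at else np.nan)
    # two-row sample table: analyses only need the time span, not a dense grid
    data = np.zeros((2, len(TRAJECTORY_COLUMNS)))
    data[:, 0] = (0.0, censor_at)
    return Trajectory(
        data=data,
        focus_episodes=log,
        break_episodes=np.empty((0, 4)),
        sen_switch_time=float("nan"),
        seed=0,
        protocol=Protocol(),
        sample_every=sample_every,
    )
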