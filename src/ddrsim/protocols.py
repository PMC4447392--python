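"""Timed-perturbation protocols: irradiation, Nutlin-3, background ROS.

A :class:`Protocol` is an ordered list of scheduled events applied
atomically during simulation: instantaneous irradiation pulses (Gy), a
piecewise-constant Nutlin-3 inhibition factor multiplying the p53–MDM2
association, and a background-ROS production multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IrradiationEvent",
    "NutlinPhase",
    "Protocol",
    "ProtocolError",
    "build_protocol",
    "fractionated",
    "single_dose",
    "irradiation_damage_draw",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class IrradiationEvent:
    time_min: float
    dose_gy: float

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ProtocolError("dose must be >= 0 Gy")
        if self.time_min < 0:
            raise ProtocolError("event time must be >= 0")


@dataclass(frozen=True)
class NutlinPhase:
    """Inhibition factor in [0, 1] from ``from_min`` to ``to_min``.

    Factor 1 means no inhibition, 0 a complete block of the p53–MDM2
    interaction.
    """

    from_min: float
    to_min: float
    factor: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor <= 1.0:
            raise ProtocolError("nutlin factor must lie in [0, 1]")
        if self.to_min <= self.from_min:
            raise ProtocolError("nutlin phase must have to_min > from_min")


@dataclass(frozen=True)
class Protocol:
    irradiation: tuple[IrradiationEvent, ...] = ()
    nutlin: tuple[NutlinPhase, ...] = ()
    ros_multiplier: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        times = [e.time_min for e in self.irradiation]
        if times != sorted(times):
            raise ProtocolError("irradiation events must be time-sorted")
        if self.ros_multiplier < 0:
            raise ProtocolError("ros_multiplier must be >= 0")
        spans = sorted((p.from_min, p.to_min) for p in self.nutlin)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ProtocolError("nutlin phases overlap")

    @property
    def total_dose_gy(self) -> float:
        return sum(e.dose_gy for e in self.irradiation)

    @property
    def first_irradiation_min(self) -> float | None:
        return self.irradiation[0].time_min if self.irradiation else None

    def timed_events(self, duration_min: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to sorted (time, kind, value) arrays for the engine.

        kinds: 0 irradiation dose, 1 nutlin factor, 2 ros multiplier.
        """
        evs: list[tuple[float, int, float]] = []
        for e in self.irradiation:
            if e.time_min > duration_min:
                raise ProtocolError(
                    f"irradiation at {e.time_min} min is outside the "
                    f"{duration_min} min horizon"
                )
            evs.append((e.time_min, 0, e.dose_gy))
        for ph in self.nutlin:
            evs.append((ph.from_min, 1, ph.factor))
            if ph.to_min < duration_min:
                evs.append((ph.to_min, 1, 1.0))
        evs.sort(key=lambda x: (x[0], x[1]))
        t = np.array([e[0] for e in evs], dtype=np.float64)
        k = np.array([e[1] for e in evs], dtype=np.int64)
        v = np.array([e[2] for e in evs], dtype=np.float64)
        return t, k, v


def single_dose(dose_gy: float, at_min: float = 180.0, label: str = "") -> Protocol:
    """The standard protocol: one pulse after a 3 h equilibration."""
    if dose_gy == 0:
        return Protocol(label=label or "0Gy")
    return Protocol(
        irradiation=(IrradiationEvent(at_min, dose_gy),),
        label=label or f"1x{dose_gy:g}Gy",
    )


def fractionated(
    n: int, dose_gy: float, every_min: float, start_min: float = 180.0, label: str = ""
) -> Protocol:
    """``n`` pulses of ``dose_gy`` every ``every_min`` minutes."""
    if n < 1:
        raise ProtocolError("need at least one fraction")
    events = tuple(
        IrradiationEvent(start_min + i * every_min, dose_gy) for i in range(n)
    )
    return Protocol(
        irradiation=events,
        label=label or f"{n}x{dose_gy:g}Gy@{every_min:g}min",
    )


def build_protocol(spec: Mapping) -> Protocol:
    """Build a protocol from a configuration mapping.

    Recognized keys::

        irradiation: [{t_min: 180, gy: 20}, ...]
        fractions:   {n: 5, gy: 1, every_min: 60, start_min: 180}
        nutlin:      [{from_min: 180, to_min: 5040, factor: 0.0}, ...]
        ros_multiplier: 10
        label: "5x1Gy"
    """
    known = {"irradiation", "fractions", "nutlin", "ros_multiplier", "label"}
    unknown = set(spec) - known
    if unknown:
        raise ProtocolError(f"unknown protocol keys: {sorted(unknown)}")
    if "irradiation" in spec and "fractions" in spec:
        raise ProtocolError("give either 'irradiation' or 'fractions', not both")
    events: tuple[IrradiationEvent, ...] = ()
    if "irradiation" in spec:
        events = tuple(
            IrradiationEvent(float(e["t_min"]), float(e["gy"]))
            for e in spec["irradiation"]
        )
    elif "fractions" in spec:
        f = spec["fractions"]
        events = fractionated(
            int(f["n"]), float(f["gy"]), float(f["every_min"]),
            float(f.get("start_min", 180.0)),
        ).irradiation
    nutlin = tuple(
        NutlinPhase(float(p["from_min"]), float(p["to_min"]), float(p["factor"]))
        for p in spec.get("nutlin", ())
    )
    return Protocol(
        irradiation=events,
        nutlin=nutlin,
        ros_multiplier=float(spec.get("ros_multiplier", 1.0)),
        label=str(spec.get("label", "")),
    )


def nutlin_block(from_min: float, to_min: float) -> tuple[NutlinPhase, ...]:
    """Default Nutlin regimen: complete block over the given window."""
    return (NutlinPhase(from_min, to_min, 0.0),)


def irradiation_damage_draw(
    dose_gy: float,
    sites: np.ndarray,
    rng: np.random.Generator,
    dsb_yield: float,
    fc_max: float,
    fc_half: float,
) -> np.ndarray:
    """Draw per-site damage for an instantaneous dose.

    Each intact site (code 0) independently becomes damaged with
    probability ``1 - exp(-y * dose / n_sites)`` where ``y`` is the DSB
    yield (breaks per Gy per cell); a damaged site is complex (code 2)
    with probability ``fc_max * dose / (dose + fc_half)`` — non-decreasing
    in dose — and simple (code 1) otherwise.  Already-broken sites are
    unchanged.  Returns the new site-state array (input not modified).
    """
    if dose_gy < 0:
        raise ProtocolError("dose must be >= 0")
    out = sites.copy()
    if dose_gy == 0:
        return out
    n = len(sites)
    p_hit = 1.0 - math.exp(-dsb_yield * dose_gy / n)
    fc = fc_max * dose_gy / (dose_gy + fc_half)
    intact = out == 0
    hit = intact & (rng.random(n) < p_hit)
    complex_break = rng.random(n) < fc
    out[hit & complex_break] = 2
    out[hit & ~complex_break] = 1
    return out
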