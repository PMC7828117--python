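"""Dose events, regimens and PTX-equivalent dose arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import BODY_WEIGHT_KG

__all__ = [
    "DoseEvent",
    "Regimen",
    "to_ptx_equivalent",
    "UG_PER_MILLION_MSC",
    "solution_efficacy_regimen",
    "msc_efficacy_regimen",
    "single_bolus",
]

#: PTX-equivalent payload of 1e6 nano-MSCs (ug), from the reported dose
#: equivalence 1e6 MSCs == 25 ug == 1.25 mg/kg PTX
UG_PER_MILLION_MSC = 25.0


@dataclass(frozen=True)
class DoseEvent:
    """One instantaneous IV bolus: ``amount`` ng PTX-equivalent added to the
    central compartment of ``layer`` ('free' | 'np' | 'msc') at ``time`` h."""

    time: float
    amount: float
    layer: str

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")
        if not (math.isfinite(self.amount) and self.amount > 0):
            raise ValueError(f"dose amount must be > 0, got {self.amount!r}")
        if self.layer not in ("free", "np", "msc"):
            raise ValueError(f"unknown dose layer {self.layer!r}")


@dataclass(frozen=True)
class Regimen:
    """An ordered, nonempty sequence of dose events with a label."""

    events: tuple
    label: str = ""

    def __post_init__(self):
        events = tuple(self.events)
        if not events:
            raise ValueError("a regimen must contain at least one dose event")
        if any(not isinstance(e, DoseEvent) for e in events):
            raise TypeError("regimen events must be DoseEvent instances")
        if list(e.time for e in events) != sorted(e.time for e in events):
            raise ValueError("regimen events must be sorted by time")
        object.__setattr__(self, "events", events)

    @property
    def times(self):
        return [e.time for e in self.events]

    @property
    def total_amount(self) -> float:
        return sum(e.amount for e in self.events)


def to_ptx_equivalent(value: float, unit: str,
                      body_weight_kg: float = BODY_WEIGHT_KG) -> float:
    """Convert a dose specification to ng PTX-equivalent.

    Supported units: 'ug' (micrograms PTX), 'mg_per_kg' (scaled by body
    weight), 'msc' (cell count, at 25 ug PTX per 1e6 MSCs).
    """
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"dose value must be > 0, got {value!r}")
    if not (math.isfinite(body_weight_kg) and body_weight_kg > 0):
        raise ValueError(f"body weight must be > 0, got {body_weight_kg!r}")
    if unit == "ug":
        return value * 1e3
    if unit == "mg_per_kg":
        return value * body_weight_kg * 1e6
    if unit == "msc":
        return value * (UG_PER_MILLION_MSC / 1e6) * 1e3
    raise ValueError(f"unknown dose unit {unit!r}; expected ug|mg_per_kg|msc")


def single_bolus(amount_ng: float, layer: str, label: str = "") -> Regimen:
    return Regimen(events=(DoseEvent(0.0, amount_ng, layer),),
                   label=label or f"single {amount_ng:g} ng {layer}")


def solution_efficacy_regimen(layer: str,
                              body_weight_kg: float = BODY_WEIGHT_KG) -> Regimen:
    """The free-PTX / PTX-PLGA-NP efficacy regimen: 40 mg/kg on days 0, 4, 8."""
    amt = to_ptx_equivalent(40.0, "mg_per_kg", body_weight_kg)
    return Regimen(events=tuple(DoseEvent(24.0 * d, amt, layer) for d in (0, 4, 8)),
                   label=f"40 mg/kg q4d x3 ({layer})")


def msc_efficacy_regimen(loading_millions: float = 1.0,
                         maintenance_millions: float = 0.5,
                         interval_days: float = 14.0,
                         horizon_h: float = 1512.0) -> Regimen:
    """The nano-MSC efficacy regimen: a loading dose of MSCs on day 0 and
    maintenance doses every ``interval_days`` within the horizon."""
    events = [DoseEvent(0.0, to_ptx_equivalent(loading_millions * 1e6, "msc"), "msc")]
    t = interval_days * 24.0
    while t < horizon_h:
        events.append(DoseEvent(t, to_ptx_equivalent(maintenance_millions * 1e6, "msc"), "msc"))
        t += interval_days * 24.0
    return Regimen(events=tuple(events),
                   label=f"{loading_millions:g}e6 MSC d0 + {maintenance_millions:g}e6 q{interval_days:g}d")
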