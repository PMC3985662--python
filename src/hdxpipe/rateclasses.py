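"""Discrete exchange-rate classes defined by the experimental time grid.

Class Cj means "exchanges by 10^j s": its representative first-order rate
is chosen so a site is 95% exchanged (relative to the plateau) at 10^j s.
The final class, C6, holds sites not exchanged by the last time point; its
representative rate continues the decade pattern two decades further out so
such sites show only a few percent uptake at 10^5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RateClass", "RATE_CLASSES", "CLASS_BY_LABEL", "class_rate"]

_LN20 = 2.995732273553991  # -ln(0.05)


@dataclass(frozen=True)
class RateClass:
    label: str
    rep_rate: float  # s^-1
    by_time_s: float | None  # exchanged by this time; None for "never"


RATE_CLASSES: tuple[RateClass, ...] = (
    RateClass("C1", _LN20 / 1e1, 1e1),
    RateClass("C2", _LN20 / 1e2, 1e2),
    RateClass("C3", _LN20 / 1e3, 1e3),
    RateClass("C4", _LN20 / 1e4, 1e4),
    RateClass("C5", _LN20 / 1e5, 1e5),
    RateClass("C6", _LN20 / 1e7, None),
)

CLASS_BY_LABEL = {c.label: c for c in RATE_CLASSES}


def class_rate(label: str) -> float:
    return CLASS_BY_LABEL[label].rep_rate
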