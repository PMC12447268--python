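"""Ordered sampling-schedule vocabulary shared by every module.

Blood and marrow draws in the trial design follow a fixed visit schedule:
screening (``pre``), days 7/14/28/42/56, and months 6 and 12.  The schedule
is represented as an ordered enum carrying the nominal study day, which is
what the longevity rules and the "persistent over >= 3 months" progression
rule reason about.
"""

from __future__ import annotations

import enum


class Timepoint(enum.Enum):
    """Scheduled visit, ordered by nominal study day."""

    PRE = ("pre", 0)
    D7 = ("d7", 7)
    D14 = ("d14", 14)
    D28 = ("d28", 28)
    D42 = ("d42", 42)
    D56 = ("d56", 56)
    M6 = ("m6", 180)
    M12 = ("m12", 360)

    def __init__(self, label: str, days: int) -> None:
        self.label = label
        self.days = days

    @classmethod
    def parse(cls, value: "str | Timepoint") -> "Timepoint":
        if isinstance(value, Timepoint):
            return value
        key = str(value).strip().lower()
        for tp in cls:
            if tp.label == key:
                return tp
        raise ValueError(f"unknown timepoint {value!r}; expected one of "
                         f"{[tp.label for tp in cls]}")

    def __lt__(self, other: "Timepoint") -> bool:
        if not isinstance(other, Timepoint):
            return NotImplemented
        return self.days < other.days

    def __le__(self, other: "Timepoint") -> bool:
        if not isinstance(other, Timepoint):
            return NotImplemented
        return self.days <= other.days

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Visit order used when a stable sort over timepoints is needed.
TIMEPOINT_ORDER = tuple(tp.label for tp in Timepoint)
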