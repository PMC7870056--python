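"""Five-year age groups covering adults aged 30 and over.

Transitions are counted in twelve groups: the eleven closed bands 30-34
through 80-84 plus the open-ended 85+ band, partitioning [30, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True, order=True)
class AgeGroup:
    """One 5-year age band (open-ended for 85+).

    ``lower`` is inclusive; ``upper`` is inclusive and ``None`` for the
    open-ended top group.
    """

    lower: int
    upper: Optional[int]

    def __post_init__(self) -> None:
        if self.lower < 30:
            raise ValueError(f"age groups start at 30, got lower={self.lower}")
        if self.upper is not None and self.upper - self.lower != 4:
            raise ValueError(f"age group must span 5 years: {self.lower}-{self.upper}")

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}" if self.upper is not None else f"{self.lower}+"

    @property
    def midpoint(self) -> int:
        """Integer midpoint age; 87 for the open-ended 85+ group."""
        return self.lower + 2

    def contains(self, age: float) -> bool:
        if self.upper is None:
            return age >= self.lower
        return self.lower <= age <= self.upper

    @classmethod
    def from_label(cls, label: str) -> "AgeGroup":
        label = label.strip().replace("–", "-").replace("—", "-")
        if label.endswith("+"):
            return cls(int(label[:-1]), None)
        lo, hi = label.split("-")
        return cls(int(lo), int(hi))


#: The twelve groups used throughout: 30-34, 35-39, ..., 80-84, 85+.
AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    [AgeGroup(lo, lo + 4) for lo in range(30, 85, 5)] + [AgeGroup(85, None)]
)

AGE_GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in AGE_GROUPS)

_LABEL_TO_GROUP = {g.label: g for g in AGE_GROUPS}


def group_for_age(age: float) -> AgeGroup:
    """Return the age group containing ``age`` (ages beyond 85 map to 85+)."""
    if age < 30:
        raise ValueError(f"age {age} below the modelled range (30+)")
    if age >= 85:
        return AGE_GROUPS[-1]
    return AGE_GROUPS[int((age - 30) // 5)]


def group_from_label(label: str) -> AgeGroup:
    g = AgeGroup.from_label(label)
    if g.label not in _LABEL_TO_GROUP:
        raise ValueError(f"unknown age group {label!r}")
    return _LABEL_TO_GROUP[g.label]
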