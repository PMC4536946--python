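"""Stratigraphic stage scale.

A :class:`StageScale` is an ordered list of stage codes with integer
ordinals (0 = oldest).  The package ships the 26-stage Carnian-Maastrichtian
scale used for Mesozoic pterosaurs; any ordered code list can be supplied
for other systems.  Stage intervals are closed, ``[first, last]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["StageScale", "MESOZOIC_STAGES", "STAGE_NAMES"]

#: Carnian through Maastrichtian, oldest first.
MESOZOIC_STAGES: tuple[str, ...] = (
    "Car", "Nor", "Rha",                       # Late Triassic
    "Het", "Sin", "Pli", "Toa",                # Early Jurassic
    "Aal", "Baj", "Bat", "Cal",                # Middle Jurassic
    "Oxf", "Kim", "Tth",                       # Late Jurassic
    "Ber", "Val", "Hau", "Bar", "Apt", "Alb",  # Early Cretaceous
    "Cen", "Tur", "Con", "San", "Cam", "Maa",  # Late Cretaceous
)

STAGE_NAMES: dict[str, str] = {
    "Car": "Carnian", "Nor": "Norian", "Rha": "Rhaetian",
    "Het": "Hettangian", "Sin": "Sinemurian", "Pli": "Pliensbachian",
    "Toa": "Toarcian", "Aal": "Aalenian", "Baj": "Bajocian",
    "Bat": "Bathonian", "Cal": "Callovian", "Oxf": "Oxfordian",
    "Kim": "Kimmeridgian", "Tth": "Tithonian", "Ber": "Berriasian",
    "Val": "Valanginian", "Hau": "Hauterivian", "Bar": "Barremian",
    "Apt": "Aptian", "Alb": "Albian", "Cen": "Cenomanian",
    "Tur": "Turonian", "Con": "Coniacian", "San": "Santonian",
    "Cam": "Campanian", "Maa": "Maastrichtian",
}


@dataclass(frozen=True)
class StageScale:
    """Strictly ordered stage codes with total ordinal lookup."""

    codes: tuple[str, ...] = MESOZOIC_STAGES
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("stage codes must be unique")
        object.__setattr__(self, "_index",
                           {c: i for i, c in enumerate(self.codes)})

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def ordinal(self, code: str) -> int:
        """0-based position, oldest stage = 0."""
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"unknown stage code {code!r}") from None

    def older_or_equal(self, a: str, b: str) -> bool:
        return self.ordinal(a) <= self.ordinal(b)

    def span(self, first: str, last: str) -> Sequence[str]:
        i, j = self.ordinal(first), self.ordinal(last)
        if i > j:
            raise ValueError(f"stage interval [{first}, {last}] is reversed")
        return self.codes[i:j + 1]

    def intersects(self, first_a: str, last_a: str,
                   first_b: str, last_b: str) -> bool:
        """Closed-interval overlap on the ordinal scale."""
        return (self.ordinal(first_a) <= self.ordinal(last_b)
                and self.ordinal(first_b) <= self.ordinal(last_a))
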