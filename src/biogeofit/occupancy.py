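"""Stage x area occupancy of the fossil record.

A crude but useful estimate of spatiotemporal sampling: divide the record
into stratigraphic stages and geographic areas and ask which cells contain
any occurrence at all.  The package ships a transcription of the pterosaur
occurrence compendium (26 stages from the Carnian to the Maastrichtian x 9
areas = 234 cells) with clade content codes per cell; cells can optionally
be recounted as empty when their only content is indeterminate pterosaur
material (code ``Pti``), or - behind a flag - when it is any indeterminate
material (``Pti`` or ``Pdi``, the latter indeterminate pterodactyloids).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .stages import StageScale, MESOZOIC_STAGES

__all__ = [
    "OccurrenceRecord",
    "OccupancyMatrix",
    "build_matrix",
    "emptiness_stats",
    "load_pterosaur_occurrences",
    "read_occurrences",
    "PTEROSAUR_OCCUPANCY_AREAS",
]

#: The nine areas of the pterosaur occurrence compendium.
PTEROSAUR_OCCUPANCY_AREAS: tuple[str, ...] = (
    "Africa", "Antarctica", "Australia", "Central Asia", "East Asia",
    "Europe", "India", "North America", "South America",
)

#: indeterminate-material content codes
PTI = "Pti"   # indeterminate pterosaur remains (includes trackways)
PDI = "Pdi"   # indeterminate pterodactyloid remains

DETERMINACY = {
    PTI: "indeterminate-pterosaur",
    PDI: "indeterminate-pterodactyloid",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One (content code, area, stage) occurrence."""

    content: str
    area: str
    stage: str

    @property
    def determinacy(self) -> str:
        return DETERMINACY.get(self.content, "named-clade")


class OccupancyMatrix:
    """Stage x area grid whose cells hold sets of content codes."""

    def __init__(self, stages: StageScale, areas: Sequence[str]):
        self.stages = stages
        self.areas = tuple(areas)
        self._cells: dict[tuple[str, str], set[str]] = {
            (s, a): set() for s in stages.codes for a in self.areas}

    @property
    def n_cells(self) -> int:
        return len(self.stages) * len(self.areas)

    def cell(self, stage: str, area: str) -> frozenset[str]:
        return frozenset(self._cells[(stage, area)])

    def add(self, rec: OccurrenceRecord) -> None:
        key = (rec.stage, rec.area)
        if rec.stage not in self.stages:
            raise ValueError(f"invalid stage code {rec.stage!r}")
        if rec.area not in self.areas:
            raise ValueError(f"invalid area code {rec.area!r}")
        self._cells[key].add(rec.content)

    def to_frame(self) -> pd.DataFrame:
        """Stage-by-area grid of comma-joined content codes."""
        data = {a: [", ".join(sorted(self._cells[(s, a)]))
                    for s in self.stages.codes] for a in self.areas}
        return pd.DataFrame(data, index=list(self.stages.codes))

    def to_tsv(self) -> str:
        frame = self.to_frame()
        frame.index.name = "Stage"
        return frame.to_csv(sep="\t")


def build_matrix(records: Iterable[OccurrenceRecord],
                 stages: Optional[StageScale] = None,
                 areas: Sequence[str] = PTEROSAUR_OCCUPANCY_AREAS,
                 ) -> OccupancyMatrix:
    """Pool occurrence records into an occupancy matrix (sets deduplicate)."""
    matrix = OccupancyMatrix(stages or StageScale(MESOZOIC_STAGES), areas)
    for rec in records:
        matrix.add(rec)
    return matrix


def emptiness_stats(matrix: OccupancyMatrix,
                    indeterminate_rule: str = "off",
                    ) -> tuple[int, int, float]:
    """(n cells, n empty, percent empty rounded to the nearest integer).

    ``indeterminate_rule``:
      * ``"off"`` - a cell is empty iff it holds no content code;
      * ``"pti-only"`` - cells whose only content is indeterminate
        pterosaur material (``Pti``) are also counted empty;
      * ``"pti-or-pdi"`` - cells holding only ``Pti`` and/or ``Pdi`` are
        also counted empty.
    """
    if indeterminate_rule not in ("off", "pti-only", "pti-or-pdi"):
        raise ValueError(f"unknown rule {indeterminate_rule!r}")
    n_cells = matrix.n_cells
    n_empty = 0
    for s in matrix.stages.codes:
        for a in matrix.areas:
            content = matrix.cell(s, a)
            if not content:
                n_empty += 1
            elif indeterminate_rule == "pti-only" and content == {PTI}:
                n_empty += 1
            elif indeterminate_rule == "pti-or-pdi" and content <= {PTI, PDI}:
                n_empty += 1
    return n_cells, n_empty, round(100.0 * n_empty / n_cells)


def empty_fraction(matrix: OccupancyMatrix,
                   indeterminate_rule: str = "off") -> float:
    """Raw (unrounded) fraction of empty cells."""
    n_cells, n_empty, _ = emptiness_stats(matrix, indeterminate_rule)
    return n_empty / n_cells


def read_occurrences(text: str) -> list[OccurrenceRecord]:
    """Read tab-separated occurrence records (stage, area, content)."""
    records = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        stage, area, content = ln.split("\t")[:3]
        records.append(OccurrenceRecord(content.strip(), area.strip(),
                                        stage.strip()))
    return records


def load_pterosaur_occurrences() -> list[OccurrenceRecord]:
    """The packaged pterosaur occurrence compendium transcription."""
    text = (resources.files("biogeofit") / "data"
            / "pterosaur_occurrences.tsv").read_text()
    return read_occurrences(text)
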