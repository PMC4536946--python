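"""Exhaustive search over candidate area cladograms.

For k areas there are (2k-3)!! rooted binary leaf-labelled topologies; the
paper-scale analyses use 3-5 areas (3, 15 and 105 candidates), so every
hypothesis is scored exactly.  Larger universes are refused rather than
searched heuristically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .dataset import BiogeoDataset, DatasetError
from .reconcile import AreaCladogram, EventCosts, FitResult, fit
from .trees import enumerate_topologies, n_rooted_topologies

__all__ = ["SearchResult", "enumerate_area_cladograms", "search"]

_EPS = 1e-9

MIN_AREAS, MAX_AREAS = 3, 7


@dataclass(frozen=True)
class SearchResult:
    """Optimal area cladograms for a data-set under one cost regime."""

    best_cost: float
    optimal: tuple[tuple[AreaCladogram, FitResult], ...]
    n_evaluated: int
    costs: EventCosts
    widespread_policy: str

    @property
    def n_optimal_cladograms(self) -> int:
        return len(self.optimal)

    def cladograms(self) -> list[AreaCladogram]:
        return [H for H, _ in self.optimal]

    def report_rows(self) -> str:
        return "\n".join(res.report_row() for _, res in self.optimal)


def enumerate_area_cladograms(areas: Sequence[str]) -> Iterator[AreaCladogram]:
    """Every rooted binary area cladogram on ``areas``, each exactly once.

    Deterministic order (leaf-insertion construction).  Refuses fewer than
    3 or more than 7 areas; beyond that a heuristic search would be needed
    and none is implemented.
    """
    areas = list(areas)
    if not MIN_AREAS <= len(areas) <= MAX_AREAS:
        raise DatasetError(
            f"{len(areas)} areas outside the exhaustive-search bounds "
            f"[{MIN_AREAS}, {MAX_AREAS}]; a heuristic search is not "
            "implemented")
    for topo in enumerate_topologies(areas):
        yield AreaCladogram(topo)


def search(ds: BiogeoDataset, costs: EventCosts,
           widespread_policy: str = "cheapest-single") -> SearchResult:
    """Fit every candidate area cladogram; return the full optimal set.

    The optimal set is sorted canonically (by the label-sorted canonical
    form of the topology) so results are independent of input area order.
    """
    areas = ds.area_universe
    best_cost = float("inf")
    optimal: list[tuple[AreaCladogram, FitResult]] = []
    n_eval = 0
    for H in enumerate_area_cladograms(areas):
        res = fit(ds, H, costs, widespread_policy)
        n_eval += 1
        if res.min_cost < best_cost - _EPS:
            best_cost = res.min_cost
            optimal = [(H, res)]
        elif abs(res.min_cost - best_cost) <= _EPS:
            optimal.append((H, res))
    assert n_eval == n_rooted_topologies(len(areas))
    optimal.sort(key=lambda pair: pair[0].canonical())
    return SearchResult(best_cost, tuple(optimal), n_eval, costs,
                        widespread_policy)
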