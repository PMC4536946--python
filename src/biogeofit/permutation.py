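"""Permutation-tail-probability tests for cost and event frequencies.

Two randomisations build the null distributions:

* **pterm** — the terminal area assignments are shuffled as whole blocks
  across the pooled terminals of all clades (topologies untouched), so the
  multiset of area sets is preserved exactly;
* **ptree** — each clade's topology is replaced by a uniform draw over
  rooted binary topologies on the same leaf set (assignments untouched),
  the equiprobable/PDA null.

Cost significance follows the classical PTP logic: the observed
reconstruction cost to each globally optimal area cladogram is compared
with the costs of randomised replicates refitted to that same fixed
cladogram; the result is significant when the observed cost beats 95% of
the null (p < 0.05).  Replicates tying the observed cost count toward the
null tail (a conservative convention), and p-values are raw proportions so
that p = 0 is reportable; an add-one corrected variant is available.

Event-frequency tests compare, per event type, the observed optimal count
with the null distribution of optimal counts: ``gtr`` is the fraction of
replicates with at least the observed count, ``ltr`` the fraction with at
most.  When the optimal set realises a count *range*, the conservative end
of the observed range and the favourable end of each replicate's range are
used, so reported tails are upper bounds on both p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import AreaAssignment, BiogeoDataset
from .reconcile import (EVENT_NAMES, AreaCladogram, EventCosts, FitResult,
                        fit, fit_cost)
from .area_search import SearchResult, search
from .trees import random_topology

__all__ = [
    "PermutationConfig",
    "CladogramTest",
    "PermutationReport",
    "permute_terminals",
    "permute_topology",
    "cost_significance",
    "event_significance",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Randomisation-test settings (recorded verbatim in every report)."""

    mode: str = "pterm"              # pterm | ptree | both
    n_replicates: int = 10000
    seed: int = 0
    alpha: float = 0.05
    add_one: bool = False            # (b+1)/(n+1) corrected p-values

    def __post_init__(self):
        if self.mode not in ("pterm", "ptree", "both"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def resolution_warning(self) -> Optional[str]:
        if self.n_replicates < 1.0 / self.alpha:
            return (f"{self.n_replicates} replicates cannot resolve "
                    f"alpha={self.alpha}")
        return None


@dataclass(frozen=True)
class EventTail:
    """Null-tail probabilities for one event type on one cladogram."""

    observed: tuple[int, int]        # (min, max) over optimal embeddings
    gtr_p: float                     # P(null count >= observed), conservative
    ltr_p: float                     # P(null count <= observed), conservative
    gtr_p_ends: tuple[float, float]  # raw tails at (min, max) observed end
    ltr_p_ends: tuple[float, float]


@dataclass(frozen=True)
class CladogramTest:
    """Per-area-cladogram test outcome."""

    area_cladogram: AreaCladogram
    observed_cost: float
    cost_p: float
    null_cost_summary: tuple[float, float, float]   # (min, median, max)
    events: dict[str, EventTail] = field(default_factory=dict)

    def significant(self, alpha: float) -> bool:
        return self.cost_p < alpha


@dataclass(frozen=True)
class PermutationReport:
    """Observed statistics, null tails and the configuration that made them."""

    config: PermutationConfig
    costs: EventCosts
    widespread_policy: str
    tests: tuple[CladogramTest, ...]
    observed_event_ranges: dict[str, tuple[int, int]]
    warnings: tuple[str, ...] = ()

    @property
    def cost_p_values(self) -> list[float]:
        return [t.cost_p for t in self.tests]

    def any_significant(self, alpha: Optional[float] = None) -> bool:
        a = self.config.alpha if alpha is None else alpha
        return any(t.cost_p < a for t in self.tests)

    def event_gtr_p(self, event: str) -> float:
        """Smallest per-cladogram gtr tail for one event type."""
        return min(t.events[event].gtr_p for t in self.tests)

    def event_ltr_p(self, event: str) -> float:
        return min(t.events[event].ltr_p for t in self.tests)


# ---------------------------------------------------------------------------
# Randomisations
# ---------------------------------------------------------------------------

def permute_terminals(ds: BiogeoDataset, rng: np.random.Generator,
                      ) -> BiogeoDataset:
    """Shuffle whole area-set blocks across the pooled terminals."""
    taxa = ds.taxa
    blocks = [ds.assignment.mapping[t] for t in taxa]
    perm = rng.permutation(len(blocks))
    mapping = {t: blocks[perm[i]] for i, t in enumerate(taxa)}
    assignment = AreaAssignment(mapping, ds.assignment.area_universe)
    return BiogeoDataset(ds.clades, assignment, ds.strat, ds.stage_scale)


def permute_topology(ds: BiogeoDataset, rng: np.random.Generator,
                     ) -> BiogeoDataset:
    """Redraw each clade's topology uniformly on the same leaf set."""
    clades = tuple(random_topology(c.leaf_labels(), rng) for c in ds.clades)
    return BiogeoDataset(clades, ds.assignment, ds.strat, ds.stage_scale)


def _permute(ds: BiogeoDataset, mode: str, rng) -> BiogeoDataset:
    out = ds
    if mode in ("ptree", "both"):
        out = permute_topology(out, rng)
    if mode in ("pterm", "both"):
        out = permute_terminals(out, rng)
    return out


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def _p(tail_count: int, n: int, add_one: bool) -> float:
    if add_one:
        return (tail_count + 1) / (n + 1)
    return tail_count / n


def _null_summary(costs: np.ndarray) -> tuple[float, float, float]:
    return (float(costs.min()), float(np.median(costs)), float(costs.max()))


def _hypotheses(ds, costs, widespread_policy, search_result, cladograms):
    """Cladograms to test: an explicit a-priori list, or the optimal set."""
    if cladograms is not None:
        return tuple((H, fit(ds, H, costs, widespread_policy))
                     for H in cladograms)
    if search_result is None:
        search_result = search(ds, costs, widespread_policy)
    return search_result.optimal


def cost_significance(ds: BiogeoDataset, costs: EventCosts,
                      config: PermutationConfig,
                      widespread_policy: str = "cheapest-single",
                      search_result: Optional[SearchResult] = None,
                      cladograms: Optional[list[AreaCladogram]] = None,
                      ) -> PermutationReport:
    """PTP test of reconstruction cost per area cladogram.

    By default the globally optimal cladograms are tested (the search is
    run internally unless a :class:`SearchResult` is given); pass
    ``cladograms`` to test a-priori hypotheses instead.  Each replicate
    data-set is refitted to every *fixed* tested cladogram (no re-search),
    matching the one-p-value-per-optimal-tree convention.  For an a-priori
    cladogram the permutation p-value is exchangeability-exact; for a
    cladogram selected by the search it inherits the selection optimism
    inherent in testing the best-scoring hypothesis.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_replicates
    optimal = _hypotheses(ds, costs, widespread_policy, search_result,
                          cladograms)
    null = np.empty((len(optimal), n))
    for i in range(n):
        rep = _permute(ds, config.mode, rng)
        for j, (H, _) in enumerate(optimal):
            null[j, i] = fit_cost(rep, H, costs, widespread_policy)
    tests = []
    for j, (H, res) in enumerate(optimal):
        tail = int((null[j] <= res.min_cost + 1e-9).sum())
        tests.append(CladogramTest(
            H, res.min_cost, _p(tail, n, config.add_one),
            _null_summary(null[j])))
    warnings = tuple(w for w in [config.resolution_warning()] if w)
    observed = {}
    for k, name in enumerate(EVENT_NAMES):
        observed[name] = (min(res.event_ranges[k][0] for _, res in optimal),
                          max(res.event_ranges[k][1] for _, res in optimal))
    return PermutationReport(config, costs, widespread_policy, tuple(tests),
                             observed, warnings)


def event_significance(ds: BiogeoDataset, costs: EventCosts,
                       config: PermutationConfig,
                       widespread_policy: str = "cheapest-single",
                       search_result: Optional[SearchResult] = None,
                       cladograms: Optional[list[AreaCladogram]] = None,
                       max_cladograms: Optional[int] = None,
                       ) -> PermutationReport:
    """Null tails for per-event optimal counts (pterm by default).

    For each tested area cladogram the replicate's optimal event-count
    range is compared with the observed range: the gtr tail uses the lower
    observed end against the upper replicate end, the ltr tail the upper
    observed end against the lower replicate end (both conservative); the
    raw tails at both observed ends are reported as well.
    ``max_cladograms`` limits testing to the canonically first cladograms
    of a large optimal set (every replicate requires one full refit per
    tested cladogram).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_replicates
    optimal = _hypotheses(ds, costs, widespread_policy, search_result,
                          cladograms)
    if max_cladograms is not None:
        optimal = optimal[:max_cladograms]
    m = len(optimal)
    rep_min = np.empty((m, n, 4), dtype=np.int64)
    rep_max = np.empty((m, n, 4), dtype=np.int64)
    null_cost = np.empty((m, n))
    for i in range(n):
        rep = _permute(ds, config.mode, rng)
        for j, (H, _) in enumerate(optimal):
            r = fit(rep, H, costs, widespread_policy)
            null_cost[j, i] = r.min_cost
            for k in range(4):
                rep_min[j, i, k] = r.event_ranges[k][0]
                rep_max[j, i, k] = r.event_ranges[k][1]
    tests = []
    for j, (H, res) in enumerate(optimal):
        events = {}
        for k, name in enumerate(EVENT_NAMES):
            lo, hi = res.event_ranges[k]
            gtr_ends = tuple(
                _p(int((rep_max[j, :, k] >= end).sum()), n, config.add_one)
                for end in (lo, hi))
            ltr_ends = tuple(
                _p(int((rep_min[j, :, k] <= end).sum()), n, config.add_one)
                for end in (lo, hi))
            events[name] = EventTail((lo, hi), max(gtr_ends), max(ltr_ends),
                                     gtr_ends, ltr_ends)
        tail = int((null_cost[j] <= res.min_cost + 1e-9).sum())
        tests.append(CladogramTest(
            H, res.min_cost, _p(tail, n, config.add_one),
            _null_summary(null_cost[j]), events))
    observed = {}
    for k, name in enumerate(EVENT_NAMES):
        observed[name] = (min(res.event_ranges[k][0] for _, res in optimal),
                          max(res.event_ranges[k][1] for _, res in optimal))
    warnings = tuple(w for w in [config.resolution_warning()] if w)
    return PermutationReport(config, costs, widespread_policy, tuple(tests),
                             observed, warnings)
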