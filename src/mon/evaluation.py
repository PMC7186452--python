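"""Ranking evaluation against a benchmark essential-protein set.

Provides top-K precision, full precision-recall curves over every
cutoff, cumulative (jackknife) curves with their area, seeded random
baselines, and overlap statistics between two rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Tuple

import numpy as np

from mon.network import ProteinUniverse
from mon.ranking import RankedList

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Benchmark:
    """Known essential proteins restricted to the evaluation universe.

    Identifiers outside the universe are dropped with a logged warning:
    recall denominators only count essentials the ranking could reach.
    """

    essential: FrozenSet[str]
    universe: ProteinUniverse

    @classmethod
    def from_ids(cls, ids, universe: ProteinUniverse) -> "Benchmark":
        ids = set(ids)
        inside = frozenset(p for p in ids if p in universe)
        dropped = len(ids) - len(inside)
        if dropped:
            log.warning(
                "%d benchmark protein(s) outside the universe were dropped", dropped
            )
        return cls(essential=inside, universe=universe)

    def __len__(self) -> int:
        return len(self.essential)


@dataclass(frozen=True)
class EvaluationCurves:
    """Per-cutoff evaluation curves for one ranking."""

    pr_points: Tuple[Tuple[float, float], ...] = ()  # (recall, precision), K order
    jackknife: Tuple[int, ...] = ()  # cumulative essential count per rank
    jackknife_fraction: Tuple[float, ...] = ()  # cumulative count / |essential|
    auc_jackknife: float = 0.0


def topk_precision(rl: RankedList, bench: Benchmark, K: int) -> float:
    """Fraction of true essentials among the top K ranked proteins."""
    top = rl.top(K)  # validates K
    return len(set(top) & bench.essential) / K


def pr_curve(rl: RankedList, bench: Benchmark) -> EvaluationCurves:
    """Precision and recall at every cutoff K = 1..n, in K order."""
    if not bench.essential:
        raise ValueError("benchmark is empty within the universe")
    n_essential = len(bench.essential)
    points: List[Tuple[float, float]] = []
    tp = 0
    for k, protein in enumerate(rl.ordering, start=1):
        if protein in bench.essential:
            tp += 1
        points.append((tp / n_essential, tp / k))
    return EvaluationCurves(pr_points=tuple(points))


def jackknife_curve(rl: RankedList, bench: Benchmark) -> EvaluationCurves:
    """Cumulative count of essentials by rank, plus the trapezoidal area.

    Both the raw counts and the fraction of the benchmark recovered are
    reported; the area (over the rank axis) supports method comparison.
    """
    counts: List[int] = []
    seen = 0
    for protein in rl.ordering:
        if protein in bench.essential:
            seen += 1
        counts.append(seen)
    arr = np.asarray(counts, dtype=float)
    auc = float(np.trapezoid(arr)) if len(arr) > 1 else 0.0
    n_essential = len(bench.essential)
    fraction = tuple(
        (c / n_essential) if n_essential else 0.0 for c in counts
    )
    return EvaluationCurves(
        jackknife=tuple(counts), jackknife_fraction=fraction, auc_jackknife=auc
    )


def random_assortment(universe: ProteinUniverse, seed: int) -> RankedList:
    """Uniformly random ranking, deterministic per seed."""
    rng = np.random.default_rng(seed)
    order = [universe.ids[i] for i in rng.permutation(len(universe))]
    n = len(order)
    scores = {p: (n - r) / n for r, p in enumerate(order)}
    return RankedList(ordering=tuple(order), scores=scores)


@dataclass(frozen=True)
class OverlapReport:
    """Top-K set comparison of two rankings over one universe."""

    K: int
    overlap: int
    only_a: FrozenSet[str]
    only_b: FrozenSet[str]
    essential_fraction_only_a: Optional[float]
    essential_fraction_only_b: Optional[float]


def overlap_stats(
    rl_a: RankedList, rl_b: RankedList, bench: Benchmark, K: int
) -> OverlapReport:
    """Top-K intersection / differences and each difference's essential
    fraction (``None`` when a difference set is empty)."""
    if set(rl_a.scores) - set(bench.universe.ids) or set(rl_b.scores) - set(
        bench.universe.ids
    ):
        raise ValueError("rankings must live in the benchmark universe")
    top_a = set(rl_a.top(K))
    top_b = set(rl_b.top(K))
    only_a = frozenset(top_a - top_b)
    only_b = frozenset(top_b - top_a)

    def _ess_frac(diff: FrozenSet[str]) -> Optional[float]:
        if not diff:
            return None
        return len(diff & bench.essential) / len(diff)

    return OverlapReport(
        K=K,
        overlap=len(top_a & top_b),
        only_a=only_a,
        only_b=only_b,
        essential_fraction_only_a=_ess_frac(only_a),
        essential_fraction_only_b=_ess_frac(only_b),
    )
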