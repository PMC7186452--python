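"""Restart-vector assembly and the full protein-ranking pipeline.

The restart distribution blends a conservative score (max-normalized
homolog counts across reference organisms) with an externally supplied
modular score, then the coupled walk is run on the three-layer multiplex
and proteins are sorted by their converged scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from mon.network import (
    DomainMap,
    ExpressionProfile,
    PinGraph,
    ProteinUniverse,
    build_multiplex,
)
from mon.tensor import run_rwr

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.3
DEFAULT_BETA = 0.5
DEFAULT_MODULAR_SCORE = 0.5


@dataclass(frozen=True)
class OrthologTable:
    """Protein -> number of reference organisms containing a homolog."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for p, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative ortholog count for {p!r}: {c}")

    def get(self, protein: str) -> int:
        """Missing proteins default to 0 homologs."""
        return int(self.counts.get(protein, 0))


@dataclass(frozen=True)
class RestartVector:
    """Normalized teleportation distribution with its score provenance."""

    values: np.ndarray
    beta: float
    conservative: np.ndarray
    modular: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if (v < 0).any():
            raise ValueError("restart vector must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("restart vector must sum to 1")


@dataclass(frozen=True)
class RankedList:
    """Proteins sorted by score descending, ties broken by id ascending."""

    ordering: Tuple[str, ...]
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = [self.scores[p] for p in self.ordering]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("ordering is not non-increasing in score")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        ordering = tuple(sorted(scores, key=lambda p: (-scores[p], p)))
        return cls(ordering=ordering, scores=dict(scores))

    def top(self, k: int) -> Tuple[str, ...]:
        if not (0 < k <= len(self.ordering)):
            raise ValueError(f"K must lie in [1, {len(self.ordering)}]")
        return self.ordering[:k]

    def __len__(self) -> int:
        return len(self.ordering)


def conservative_scores(
    universe: ProteinUniverse, orth: OrthologTable
) -> Dict[str, float]:
    """Homolog count divided by the universe maximum; all-zero -> all 0."""
    counts = {p: orth.get(p) for p in universe.ids}
    peak = max(counts.values())
    if peak == 0:
        return {p: 0.0 for p in universe.ids}
    return {p: c / peak for p, c in counts.items()}


def build_restart_vector(
    universe: ProteinUniverse,
    cs: Mapping[str, float],
    ms: Mapping[str, float],
    beta: float = DEFAULT_BETA,
) -> RestartVector:
    """Convex combination beta * cs + (1 - beta) * ms, normalized to sum 1.

    Rescaling to a probability vector keeps the walk's mass conservation
    and cannot change the induced ranking. An all-zero combination falls
    back to the uniform distribution.
    """
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    c = np.array([cs.get(p, 0.0) for p in universe.ids])
    m = np.array([ms.get(p, 0.0) for p in universe.ids])
    if (m < 0).any() or (m > 1).any():
        raise ValueError("modular scores must lie in [0, 1]")
    combined = beta * c + (1.0 - beta) * m
    total = combined.sum()
    if total == 0.0:
        values = np.full(len(universe), 1.0 / len(universe))
    else:
        values = combined / total
    return RestartVector(values=values, beta=beta, conservative=c, modular=m)


def mon_rank(
    pin: PinGraph,
    domains: DomainMap,
    expr: ExpressionProfile,
    orth: OrthologTable,
    ms: Optional[Mapping[str, float]] = None,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    K: Optional[int] = None,
    threshold: float = 1e-9,
    max_iter: int = 1000,
    return_walk: bool = False,
):
    """Run the full pipeline and return the top-K ranked proteins.

    Builds the three-layer multiplex from the interaction network,
    domain annotations and expression profiles; assembles the restart
    vector from ortholog counts and modular scores (uniform 0.5 when no
    modular-score table is supplied); runs the coupled walk; sorts by
    converged node score with deterministic tie-breaking.
    """
    universe = pin.universe
    n = len(universe)
    if K is None:
        K = n
    if not (0 < K <= n):
        raise ValueError(f"K must lie in [1, {n}]")

    net = build_multiplex(pin, domains, expr)
    for layer in net.layers:
        log.info("layer %s: %d edges", layer.layer_name, layer.n_edges)

    cs = conservative_scores(universe, orth)
    if ms is None:
        ms = {p: DEFAULT_MODULAR_SCORE for p in universe.ids}
    rv = build_restart_vector(universe, cs, ms, beta=beta)

    result = run_rwr(net, rv.values, alpha=alpha, threshold=threshold, max_iter=max_iter)
    if not result.converged:
        log.warning(
            "walk did not converge in %d iterations (residual %.3e)",
            result.iterations,
            result.residual_trace[-1] if result.residual_trace else float("nan"),
        )
    log.info(
        "walk finished after %d iterations; layer importances %s",
        result.iterations,
        np.array2string(result.state.y, precision=4),
    )

    scores = dict(zip(universe.ids, result.state.x.tolist()))
    ranked = RankedList.from_scores(scores)
    truncated = RankedList(
        ordering=ranked.ordering[:K],
        scores={p: scores[p] for p in ranked.ordering[:K]},
    )
    if return_walk:
        return truncated, result
    return truncated
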