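"""Construction of the three biological layers and the multiplex network.

The shared protein set is fixed by the physical interaction network; each
layer re-weights (a subset of) its edges from a different data source:

* co-neighbor   — squared common-neighbor count normalized by degrees,
* co-structure  — product of min-max-normalized inverse-domain-frequency
                  scores of the two endpoints,
* co-expression — absolute Pearson correlation of the two time courses.

Edges with weight zero are never stored; absence and zero weight are
semantically identical everywhere downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

Pair = Tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    """Canonical unordered pair (sorted lexicographically)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinUniverse:
    """Ordered set of unique protein identifiers with a stable integer index."""

    ids: Tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValueError("universe must contain at least one protein")
        idx = {p: i for i, p in enumerate(self.ids)}
        if len(idx) != len(self.ids):
            raise ValueError("universe contains duplicate identifiers")
        object.__setattr__(self, "index", idx)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "ProteinUniverse":
        return cls(tuple(ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, protein: str) -> bool:
        return protein in self.index

    def position(self, protein: str) -> int:
        return self.index[protein]


@dataclass(frozen=True)
class PinGraph:
    """Undirected physical interaction network over a protein universe.

    Self-interactions and duplicate pairs are rejected at construction;
    input hygiene (deduplication) is the loader's job.
    """

    universe: ProteinUniverse
    edges: FrozenSet[Pair]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-interaction not allowed: {a!r}")
            if a > b:
                raise ValueError(f"edge pair not in canonical order: ({a!r}, {b!r})")
            if a not in self.universe or b not in self.universe:
                raise ValueError(f"edge endpoint outside universe: ({a!r}, {b!r})")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        universe: Optional[ProteinUniverse] = None,
    ) -> "PinGraph":
        """Build from raw (possibly duplicated / self-looped) pairs.

        Self-pairs and duplicates are silently dropped here; the universe
        defaults to the sorted set of endpoint identifiers.
        """
        canon = {_pair(a, b) for a, b in edges if a != b}
        if universe is None:
            nodes = sorted({p for e in canon for p in e})
            if not nodes:
                raise ValueError("cannot infer a universe from an empty edge set")
            universe = ProteinUniverse.from_ids(nodes)
        return cls(universe, frozenset(canon))

    def neighbors(self) -> Dict[str, FrozenSet[str]]:
        """Direct-neighbor set per protein (protein itself excluded)."""
        adj: Dict[str, set] = defaultdict(set)
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return {p: frozenset(ns) for p, ns in adj.items()}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DomainMap:
    """Protein -> domain memberships with per-domain protein counts."""

    memberships: FrozenSet[Tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "DomainMap":
        return cls(frozenset(pairs))

    @property
    def domain_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = defaultdict(int)
        for _, dom in self.memberships:
            counts[dom] += 1
        return dict(counts)

    def domains_of(self, protein: str) -> FrozenSet[str]:
        return frozenset(d for p, d in self.memberships if p == protein)


@dataclass(frozen=True)
class ExpressionProfile:
    """Gene-expression time courses keyed by protein id.

    All stored vectors share one length; proteins absent from the profile
    simply have no entry (``get`` returns ``None``).
    """

    values: Mapping[str, np.ndarray]
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("expression profiles need at least 2 time points")
        for p, v in self.values.items():
            if len(v) != self.n_timepoints:
                raise ValueError(
                    f"expression vector for {p!r} has length {len(v)}, "
                    f"expected {self.n_timepoints}"
                )

    @classmethod
    def from_dict(cls, values: Mapping[str, Sequence[float]]) -> "ExpressionProfile":
        arrays = {p: np.asarray(v, dtype=float) for p, v in values.items()}
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged expression vectors: lengths {sorted(lengths)}")
        n_tp = lengths.pop() if lengths else 2
        return cls(arrays, n_tp)

    def get(self, protein: str) -> Optional[np.ndarray]:
        return self.values.get(protein)


@dataclass(frozen=True)
class WeightedLayer:
    """One undirected weighted layer over the shared universe.

    Weights are stored on canonical unordered pairs and lie in (0, 1];
    a pair with weight 0 is absent.
    """

    universe: ProteinUniverse
    weights: Mapping[Pair, float]
    layer_name: str

    def __post_init__(self) -> None:
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValueError(f"self-pair in layer {self.layer_name!r}: {a!r}")
            if a > b:
                raise ValueError(f"non-canonical pair in layer: ({a!r}, {b!r})")
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"layer weight out of (0, 1] for ({a!r}, {b!r}): {w}"
                )
            if a not in self.universe or b not in self.universe:
                raise ValueError(f"layer pair outside universe: ({a!r}, {b!r})")

    def weight(self, a: str, b: str) -> float:
        return self.weights.get(_pair(a, b), 0.0)

    @property
    def n_edges(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered collection of layers sharing one protein universe."""

    universe: ProteinUniverse
    layers: Tuple[WeightedLayer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("multiplex network needs at least one layer")
        for layer in self.layers:
            if layer.universe is not self.universe and layer.universe != self.universe:
                raise ValueError(
                    f"layer {layer.layer_name!r} has a different universe"
                )

    @property
    def n(self) -> int:
        return len(self.universe)

    @property
    def L(self) -> int:
        return len(self.layers)


# ---------------------------------------------------------------------------
# Layer construction


def build_co_neighbor(pin: PinGraph) -> WeightedLayer:
    """Weight each PIN edge by its squared common-neighbor count.

    An edge (a, b) with c > 0 common neighbors gets weight
    c^2 / ((deg(a) - 1) * (deg(b) - 1)); edges with no common neighbor
    are absent. Since a and b interact, c <= min(deg) - 1, so the
    weight always lies in (0, 1].
    """
    nbrs = pin.neighbors()
    weights: Dict[Pair, float] = {}
    for a, b in pin.edges:
        common = nbrs[a] & nbrs[b]
        if not common:
            continue
        c = len(common)
        weights[(a, b)] = (c * c) / ((len(nbrs[a]) - 1) * (len(nbrs[b]) - 1))
    return WeightedLayer(pin.universe, weights, "co_neighbor")


def domain_score_raw(protein: str, domains: DomainMap) -> float:
    """Sum of inverse domain frequencies over the protein's domains."""
    counts = domains.domain_counts
    return sum(1.0 / counts[d] for d in domains.domains_of(protein))


def domain_scores_normalized(
    universe: ProteinUniverse, domains: DomainMap
) -> Dict[str, float]:
    """Min-max normalize raw domain scores over the whole universe.

    Proteins with no annotations score raw 0 and participate in the
    min/max. If all raw scores coincide, every normalized score is 0.
    """
    counts = domains.domain_counts
    by_protein: Dict[str, float] = defaultdict(float)
    for p, d in domains.memberships:
        if p in universe:
            by_protein[p] += 1.0 / counts[d]
    raw = np.array([by_protein.get(p, 0.0) for p in universe.ids])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return {p: 0.0 for p in universe.ids}
    norm = (raw - lo) / (hi - lo)
    return dict(zip(universe.ids, norm.tolist()))


def build_co_structure(pin: PinGraph, domains: DomainMap) -> WeightedLayer:
    """Weight each PIN edge by the product of its endpoints' normalized
    domain scores; zero-product pairs are absent."""
    scores = domain_scores_normalized(pin.universe, domains)
    weights: Dict[Pair, float] = {}
    for a, b in pin.edges:
        w = scores[a] * scores[b]
        if w > 0.0:
            weights[(a, b)] = w
    return WeightedLayer(pin.universe, weights, "co_structure")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Sample Pearson correlation; ``None`` when either vector has zero
    variance (the coefficient is undefined there)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise ValueError("expression vectors must be 1-D and of equal length")
    if len(xa) < 2:
        raise ValueError("correlation needs at least 2 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float(np.dot(xc, xc))
    sy = float(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.dot(xc, yc) / np.sqrt(sx * sy))
    # guard against round-off pushing |r| above 1
    return max(-1.0, min(1.0, r))


def build_co_expression(pin: PinGraph, expr: ExpressionProfile) -> WeightedLayer:
    """Weight each PIN edge by |PCC| of the endpoints' time courses.

    Edges with a missing-expression endpoint, an undefined coefficient
    (zero variance), or a coefficient of exactly 0 are absent.
    """
    weights: Dict[Pair, float] = {}
    for a, b in pin.edges:
        va, vb = expr.get(a), expr.get(b)
        if va is None or vb is None:
            continue
        r = pearson_correlation(va, vb)
        if r is None or r == 0.0:
            continue
        weights[(a, b)] = abs(r)
    return WeightedLayer(pin.universe, weights, "co_expression")


def assemble_multiplex(layers: Sequence[WeightedLayer]) -> MultiplexNetwork:
    """Stack layers (given order preserved) into one multiplex network."""
    if not layers:
        raise ValueError("need at least one layer")
    return MultiplexNetwork(layers[0].universe, tuple(layers))


def build_multiplex(
    pin: PinGraph, domains: DomainMap, expr: ExpressionProfile
) -> MultiplexNetwork:
    """The standard three-layer pipeline: co-neighbor, co-structure,
    co-expression, in that order."""
    return assemble_multiplex(
        [
            build_co_neighbor(pin),
            build_co_structure(pin, domains),
            build_co_expression(pin, expr),
        ]
    )


def coverage_rate(n_covered: int, n_total: int) -> float:
    """Percentage ``100 * n_covered / n_total`` rounded to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_covered <= n_total):
        raise ValueError("n_covered must lie in [0, n_total]")
    return round(100.0 * n_covered / n_total, 2)
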