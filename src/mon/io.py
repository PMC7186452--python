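"""Readers and writers for every flat-file interface format.

All inputs are tab-separated text. The interaction network defines the
protein universe; every other table is joined onto it downstream, with
extra identifiers ignored (and counted in the logs) at assembly time.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Set, Tuple

from mon.network import DomainMap, ExpressionProfile, PinGraph, WeightedLayer
from mon.ranking import OrthologTable, RankedList

log = logging.getLogger(__name__)


def _rows(path) -> List[Tuple[int, List[str]]]:
    """Non-empty lines split on tabs (or any whitespace), 1-based numbered."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.replace("\t", " ").split()]
            out.append((lineno, fields))
    return out


def load_ppi(path, header: bool = False) -> PinGraph:
    """Two-column undirected edge list; self-loops and duplicates dropped
    (counts logged)."""
    rows = _rows(path)
    if header and rows:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: empty interaction file")
    edges: Set[Tuple[str, str]] = set()
    self_loops = duplicates = 0
    for lineno, fields in rows:
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        a, b = fields[0], fields[1]
        if a == b:
            self_loops += 1
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in edges:
            duplicates += 1
            continue
        edges.add(pair)
    if self_loops or duplicates:
        log.info(
            "%s: dropped %d self-interaction(s) and %d duplicate pair(s)",
            path,
            self_loops,
            duplicates,
        )
    if not edges:
        raise ValueError(f"{path}: no usable interactions")
    return PinGraph.from_edges(edges)


def load_domains(path) -> DomainMap:
    """Two-column (protein, domain) membership table."""
    pairs = set()
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        pairs.add((fields[0], fields[1]))
    return DomainMap.from_pairs(pairs)


def load_expression(path) -> ExpressionProfile:
    """TSV with gene id in the first column, numeric time points after."""
    values: Dict[str, List[float]] = {}
    width = None
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected id + >= 2 time points")
        gene = fields[0]
        try:
            vec = [float(v) for v in fields[1:]]
        except ValueError:
            bad = next(
                i for i, v in enumerate(fields[1:], start=2)
                if not _is_number(v)
            )
            raise ValueError(
                f"{path}:{lineno}: non-numeric value in column {bad}"
            ) from None
        if width is None:
            width = len(vec)
        elif len(vec) != width:
            raise ValueError(
                f"{path}:{lineno}: row has {len(vec)} time points, expected {width}"
            )
        values[gene] = vec
    return ExpressionProfile.from_dict(values)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_orthologs(path) -> OrthologTable:
    """Two-column (protein, homolog count) table; counts must be >= 0."""
    counts: Dict[str, int] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        try:
            c = int(fields[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: ortholog count {fields[1]!r} is not an integer"
            ) from None
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative ortholog count {c}")
        counts[fields[0]] = c
    return OrthologTable(counts)


def load_scores(path) -> Dict[str, float]:
    """Two-column (protein, score) table of reals."""
    scores: Dict[str, float] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        try:
            scores[fields[0]] = float(fields[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: score {fields[1]!r} is not numeric"
            ) from None
    return scores


def load_essential(path) -> Set[str]:
    """One protein identifier per line."""
    return {fields[0] for _, fields in _rows(path)}


def load_ranking(path) -> RankedList:
    """Parse a written ranking back (order as stored)."""
    ordering: List[str] = []
    scores: Dict[str, float] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        ordering.append(fields[0])
        scores[fields[0]] = float(fields[1])
    return RankedList(ordering=tuple(ordering), scores=scores)


# ---------------------------------------------------------------------------
# Writers


def write_ppi(pin: PinGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pin.edges):
            fh.write(f"{a}\t{b}\n")


def write_domains(domains: DomainMap, path) -> None:
    with open(path, "w") as fh:
        for p, d in sorted(domains.memberships):
            fh.write(f"{p}\t{d}\n")


def write_expression(expr: ExpressionProfile, path) -> None:
    with open(path, "w") as fh:
        for p in sorted(expr.values):
            vals = "\t".join(repr(float(v)) for v in expr.values[p])
            fh.write(f"{p}\t{vals}\n")


def write_orthologs(orth: OrthologTable, path) -> None:
    with open(path, "w") as fh:
        for p in sorted(orth.counts):
            fh.write(f"{p}\t{orth.counts[p]}\n")


def write_scores(scores: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(scores):
            fh.write(f"{p}\t{scores[p]!r}\n")


def write_essential(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(ids):
            fh.write(f"{p}\n")


def write_layer(layer: WeightedLayer, path) -> None:
    """Three-column edge table with >= 10 significant digits."""
    with open(path, "w") as fh:
        for (a, b) in sorted(layer.weights):
            fh.write(f"{a}\t{b}\t{layer.weights[(a, b)]:.12g}\n")


def write_ranking(rl: RankedList, path) -> None:
    """Ranking TSV, scores printed with 12 significant digits so the
    parsed-back ordering is identical across platforms."""
    with open(path, "w") as fh:
        for p in rl.ordering:
            fh.write(f"{p}\t{rl.scores[p]:.12g}\n")
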