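"""Double-cut-and-join (DCJ) machinery.

The DCJ model treats a genome as its set of adjacencies (pairs of
neighbouring marker extremities) and telomeres (chromosome-end
extremities).  One DCJ operation cuts up to two of those elements and
rejoins the freed extremities differently; reversals, translocations,
fusions and fissions are all single DCJs, a transposition needs two.

Comparing two genomes over the same marker universe builds the adjacency
("breakpoint") graph: vertices are the elements of each genome, and every
marker extremity contributes an edge between the element containing it in
genome A and the one containing it in genome B.  The graph decomposes
into cycles and paths, and the DCJ distance is

    d(A, B) = N - (C + I/2)

with N the number of shared markers, C the number of cycles and I the
number of odd paths (odd number of edges; I is always even).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import (
    Chromosome,
    Extremity,
    Genome,
    GenomeFormatError,
    Marker,
    genome_elements,
    validate_genome_set,
)

__all__ = [
    "AdjacencySet",
    "AdjacencyGraph",
    "GraphComponent",
    "DcjOperation",
    "adjacencies",
    "build_adjacency_graph",
    "dcj_distance",
    "distance_between_element_sets",
    "apply_dcj",
    "apply_dcj_elements",
    "sorting_scenario",
    "elements_to_genome",
]

Element = frozenset  # frozenset[Extremity] of size 1 (telomere) or 2 (adjacency)


def element_sort_key(e: Element) -> tuple:
    return tuple(sorted(e))


@dataclass(frozen=True)
class AdjacencySet:
    """A genome's adjacency/telomere decomposition."""

    adjacencies: frozenset[Element]
    telomeres: frozenset[Extremity]

    @property
    def elements(self) -> frozenset[Element]:
        return self.adjacencies | frozenset(frozenset({t}) for t in self.telomeres)


def adjacencies(genome: Genome) -> AdjacencySet:
    """Adjacency/telomere set of a genome.

    A linear chromosome with m markers contributes m-1 adjacencies and 2
    telomeres; a circular one contributes m adjacencies and none.
    """
    elems = genome_elements(genome)
    adj = frozenset(e for e in elems if len(e) == 2)
    tel = frozenset(next(iter(e)) for e in elems if len(e) == 1)
    return AdjacencySet(adj, tel)


@dataclass(frozen=True)
class GraphComponent:
    kind: str  # "cycle" | "path"
    n_edges: int


@dataclass(frozen=True)
class AdjacencyGraph:
    """Component decomposition of the two-genome adjacency graph."""

    n_markers: int
    n_cycles: int
    n_odd_paths: int
    n_even_paths: int
    components: tuple[GraphComponent, ...]

    @property
    def distance(self) -> int:
        return self.n_markers - self.n_cycles - self.n_odd_paths // 2


def _ext_to_element(elems: Iterable[Element]) -> dict[Extremity, Element]:
    out: dict[Extremity, Element] = {}
    for e in elems:
        for x in e:
            out[x] = e
    return out


def _decompose(
    elems_a: frozenset[Element], elems_b: frozenset[Element], n_markers: int
) -> AdjacencyGraph:
    maps = (_ext_to_element(elems_a), _ext_to_element(elems_b))
    visited: set[tuple[int, Element]] = set()
    comps: list[GraphComponent] = []

    # paths, seeded from telomere vertices on either side
    starts = [(0, e) for e in elems_a if len(e) == 1]
    starts += [(1, e) for e in elems_b if len(e) == 1]
    for side, elem in sorted(starts, key=lambda s: (s[0], element_sort_key(s[1]))):
        if (side, elem) in visited:
            continue
        visited.add((side, elem))
        edges = 0
        incoming: Extremity | None = None
        cur_side, cur = side, elem
        while True:
            outs = [x for x in cur if x != incoming]
            if not outs:
                break
            ext = outs[0]
            nxt_side = 1 - cur_side
            nxt = maps[nxt_side][ext]
            edges += 1
            visited.add((nxt_side, nxt))
            incoming, cur_side, cur = ext, nxt_side, nxt
        comps.append(GraphComponent("path", edges))

    # cycles: whatever remains on side A
    for elem in sorted(elems_a, key=element_sort_key):
        if (0, elem) in visited or len(elem) != 2:
            continue
        visited.add((0, elem))
        edges = 0
        ext = min(elem)
        cur_side, cur = 0, elem
        while True:
            nxt_side = 1 - cur_side
            nxt = maps[nxt_side][ext]
            edges += 1
            if (nxt_side, nxt) == (0, elem):
                break
            visited.add((nxt_side, nxt))
            ext = next(x for x in nxt if x != ext)
            cur_side, cur = nxt_side, nxt
        comps.append(GraphComponent("cycle", edges))

    n_cycles = sum(1 for c in comps if c.kind == "cycle")
    n_odd = sum(1 for c in comps if c.kind == "path" and c.n_edges % 2 == 1)
    n_even = sum(1 for c in comps if c.kind == "path" and c.n_edges % 2 == 0)
    return AdjacencyGraph(n_markers, n_cycles, n_odd, n_even, tuple(comps))


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraph:
    """Adjacency-graph decomposition of two genomes over one universe."""
    rep = validate_genome_set([a, b])
    if rep.duplicated_ids or rep.missing_ids:
        raise GenomeFormatError(
            "genomes do not share a clean marker universe: " + "; ".join(rep.messages)
        )
    return _decompose(genome_elements(a), genome_elements(b), a.n_markers())


def distance_between_element_sets(
    elems_a: frozenset[Element] | set, elems_b: frozenset[Element] | set, n_markers: int
) -> int:
    """DCJ distance straight from two adjacency/telomere sets."""
    return _decompose(frozenset(elems_a), frozenset(elems_b), n_markers).distance


def dcj_distance(a: Genome, b: Genome) -> int:
    """Minimum number of DCJ operations transforming ``a`` into ``b``."""
    return build_adjacency_graph(a, b).distance


# ---------------------------------------------------------------------------
# operations


@dataclass(frozen=True)
class DcjOperation:
    """One cut-and-join: the elements consumed and the elements produced.

    ``kind`` is a coarse descriptor: ``exchange`` (two elements cut, four
    extremities rejoined — covers reversal and translocation), ``join``
    (two telomeres fused into an adjacency) and ``cut`` (an adjacency
    split into two telomeres).
    """

    kind: str
    consumed: tuple[Element, ...]
    produced: tuple[Element, ...]

    def __post_init__(self) -> None:
        before = [x for e in self.consumed for x in e]
        after = [x for e in self.produced for x in e]
        if sorted(before) != sorted(after):
            raise ValueError("DCJ operation must conserve its extremities")
        if not 1 <= len(self.consumed) <= 2:
            raise ValueError("DCJ consumes one or two elements")


def make_operation(consumed: Sequence[Element], produced: Sequence[Element]) -> DcjOperation:
    consumed = tuple(sorted((frozenset(e) for e in consumed), key=element_sort_key))
    produced = tuple(sorted((frozenset(e) for e in produced), key=element_sort_key))
    if len(consumed) == 2 and all(len(e) == 1 for e in consumed):
        kind = "join"
    elif len(consumed) == 1:
        kind = "cut"
    else:
        kind = "exchange"
    return DcjOperation(kind, consumed, produced)


def apply_dcj_elements(elems: set[Element], op: DcjOperation) -> set[Element]:
    out = set(elems)
    for e in op.consumed:
        if e not in out:
            raise ValueError(
                f"operation not applicable: element {sorted(e)} absent from genome"
            )
        out.discard(e)
    out.update(op.produced)
    return out


def apply_dcj(genome: Genome, op: DcjOperation) -> Genome:
    """Apply one DCJ operation, returning a new genome at distance <= 1."""
    elems = apply_dcj_elements(set(genome_elements(genome)), op)
    return elements_to_genome(elems, genome.label)


def elements_to_genome(
    elems: Iterable[Element], label: str, chrom_prefix: str = "chr"
) -> Genome:
    """Rebuild chromosomes from an adjacency/telomere set (deterministic)."""
    partner: dict[Extremity, Extremity | None] = {}
    for e in elems:
        xs = sorted(e)
        if len(xs) == 1:
            partner[xs[0]] = None
        else:
            partner[xs[0]] = xs[1]
            partner[xs[1]] = xs[0]
    used: set[Extremity] = set()
    chroms: list[tuple[str, list[Marker]]] = []

    def walk(start: Extremity) -> list[Marker]:
        markers: list[Marker] = []
        cur = start
        while True:
            sign = 1 if cur.side == "t" else -1
            markers.append(Marker(cur.marker_id, sign))
            used.add(cur)
            far = cur.other()
            used.add(far)
            nxt = partner.get(far)
            if nxt is None or nxt in used:
                return markers
            cur = nxt

    telomeres = sorted(x for x, p in partner.items() if p is None)
    for t in telomeres:
        if t in used:
            continue
        chroms.append(("linear", walk(t)))
    for x in sorted(partner):
        if x in used:
            continue
        chroms.append(("circular", walk(x)))
    g = Genome(label)
    for i, (topo, markers) in enumerate(chroms, 1):
        g.chromosomes.append(Chromosome(f"{chrom_prefix}{i}", tuple(markers), topo))
    return g


def sorting_scenario(a: Genome, b: Genome) -> list[DcjOperation]:
    """An optimal ordered DCJ scenario from ``a`` to ``b``.

    Greedy adjacency completion: every adjacency of the target absent
    from the current genome is created by the unique DCJ that cuts the
    two elements holding its extremities; leftover extremities are
    rejoined (or become telomeres).  Remaining wrong adjacencies whose
    extremities are telomeric in the target are then cut.  Each step
    decreases the distance by one, so the list length equals
    ``dcj_distance(a, b)``.  Ties are resolved lexicographically on the
    target element, which makes the scenario deterministic.
    """
    rep = validate_genome_set([a, b])
    if rep.duplicated_ids or rep.missing_ids:
        raise GenomeFormatError(
            "genomes do not share a clean marker universe: " + "; ".join(rep.messages)
        )
    cur = set(genome_elements(a))
    tgt = genome_elements(b)
    locate = _ext_to_element(cur)
    ops: list[DcjOperation] = []

    def replace(consumed: list[Element], produced: list[Element]) -> None:
        op = make_operation(consumed, produced)
        for e in op.consumed:
            cur.discard(e)
        for e in op.produced:
            cur.add(e)
            for x in e:
                locate[x] = e
        ops.append(op)

    for adj in sorted((e for e in tgt if len(e) == 2), key=element_sort_key):
        if adj in cur:
            continue
        p, q = sorted(adj)
        u, v = locate[p], locate[q]
        leftovers = (u | v) - adj
        produced = [adj]
        if leftovers:
            produced.append(frozenset(leftovers))
        replace([u, v], produced)
    for tel in sorted((e for e in tgt if len(e) == 1), key=element_sort_key):
        (p,) = tel
        u = locate[p]
        if len(u) == 2:
            other = next(x for x in u if x != p)
            replace([u], [frozenset({p}), frozenset({other})])
    return ops
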