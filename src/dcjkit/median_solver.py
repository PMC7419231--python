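"""DCJ median (ancestral genome) reconstruction for three genomes.

Given genomes g1, g2, g3 over one marker universe, the median problem
asks for the genome m minimizing the summed DCJ distance

    d_sigma = d(m, g1) + d(m, g2) + d(m, g3).

The problem is NP-hard, but the pairwise distances bracket the optimum:

    lower = ceil((d12 + d23 + d13) / 2)
    upper = d12 + d23 + d13 - max(d12, d23, d13)

(the upper bound is attained by placing the median at the leaf closest
to the other two).  The exact solver is a branch-and-bound over median
adjacency choices on the multiple breakpoint graph: elements shared by
all three genomes are fixed first (they belong to some optimal median),
remaining extremities are matched depth-first, and partial assignments
are pruned with an admissible committed-breakpoint bound.  The heuristic
is a steepest-descent local search over DCJ moves that create an element
present in at least one input genome, started from each input genome;
its total never exceeds the upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .genome_model import (
    Genome,
    GenomeFormatError,
    ValidationReport,
    genome_elements,
    validate_genome_set,
)
from .dcj_core import (
    Element,
    distance_between_element_sets,
    element_sort_key,
    elements_to_genome,
)

__all__ = [
    "DistanceTriple",
    "MedianResult",
    "median_bounds",
    "solve_median",
    "verify_median",
]


@dataclass(frozen=True)
class DistanceTriple:
    """The three pairwise DCJ distances d12, d23, d13."""

    d12: int
    d23: int
    d13: int

    def __post_init__(self) -> None:
        for d in (self.d12, self.d23, self.d13):
            if d < 0:
                raise ValueError(f"distances must be non-negative, got {d}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.d12, self.d23, self.d13)


def median_bounds(t: DistanceTriple | Sequence[int]) -> tuple[int, int]:
    """Lower/upper bounds on the median total from pairwise distances.

    lower = ceil of half the distance sum; upper = sum minus the largest
    pairwise distance.
    """
    if not isinstance(t, DistanceTriple):
        t = DistanceTriple(*t)
    s = t.d12 + t.d23 + t.d13
    lower = math.ceil(s / 2)
    upper = s - max(t.as_tuple())
    return lower, upper


@dataclass
class MedianResult:
    """A median genome with its per-leaf distances, bounds and provenance."""

    median: Genome
    leaf_labels: tuple[str, str, str]
    per_leaf: tuple[int, int, int]
    total: int
    lower: int
    upper: int
    optimal: bool
    nodes_explored: int
    n_cooptimal: int = 1
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "leaf_labels": list(self.leaf_labels),
            "per_leaf": list(self.per_leaf),
            "total": self.total,
            "lower": self.lower,
            "upper": self.upper,
            "optimal": self.optimal,
            "nodes_explored": self.nodes_explored,
            "n_cooptimal": self.n_cooptimal,
            "status": self.status,
            "n_chromosomes": len(self.median.chromosomes),
        }


def _leaf_distances(
    elems: frozenset[Element], leaves: Sequence[frozenset[Element]], n: int
) -> tuple[int, ...]:
    return tuple(distance_between_element_sets(elems, le, n) for le in leaves)


def _majority_start(leaves: Sequence[frozenset[Element]]) -> frozenset[Element]:
    """Greedy genome from elements ranked by leaf support (3-way, then 2-way...).

    Extremities left unpaired once all supported elements are considered
    become telomeres; the result is a valid adjacency/telomere set that
    tends to sit very close to the true median.
    """
    support: dict[Element, int] = {}
    for le in leaves:
        for e in le:
            support[e] = support.get(e, 0) + 1
    used: set = set()
    chosen: set[Element] = set()
    for e in sorted(support, key=lambda e: (-support[e], element_sort_key(e))):
        if any(x in used for x in e):
            continue
        chosen.add(e)
        used.update(e)
    all_exts = {x for le in leaves for e in le for x in e}
    for x in all_exts - used:
        chosen.add(frozenset({x}))
    return frozenset(chosen)


def _greedy_path_states(
    src: frozenset[Element], dst: frozenset[Element], fracs: Sequence[float]
) -> list[frozenset[Element]]:
    """Intermediate genomes along the greedy sorting path from src to dst.

    Mirrors the deterministic adjacency-completion scenario: target
    adjacencies are created in lexicographic order, then leftover
    adjacencies are cut at target telomeres.  States are recorded after
    every operation and returned at the requested fractions of the path.
    """
    cur = set(src)
    locate = {x: e for e in cur for x in e}
    states: list[frozenset[Element]] = []

    def replace(consumed: list[Element], produced: list[Element]) -> None:
        for e in consumed:
            cur.discard(e)
        for e in produced:
            cur.add(e)
            for x in e:
                locate[x] = e
        states.append(frozenset(cur))

    for adj in sorted((e for e in dst if len(e) == 2), key=element_sort_key):
        if adj in cur:
            continue
        p, q = sorted(adj)
        u, v = locate[p], locate[q]
        leftovers = (u | v) - adj
        produced = [adj] + ([frozenset(leftovers)] if leftovers else [])
        replace([u, v], produced)
    for tel in sorted((e for e in dst if len(e) == 1), key=element_sort_key):
        (p,) = tel
        u = locate[p]
        if len(u) == 2:
            other = next(x for x in u if x != p)
            replace([u], [frozenset({p}), frozenset({other})])
    if not states:
        return []
    return [states[min(len(states) - 1, round(len(states) * f))] for f in fracs]


def _descend(
    leaves: Sequence[frozenset[Element]],
    n: int,
    start: frozenset[Element],
    support: dict[Element, int],
    targets: Sequence[Element],
) -> tuple[frozenset[Element], int, int]:
    """Steepest descent over element-creating DCJ moves from one start.

    Moves are ranked by (new total, -leaf support of the resulting
    element set, lexicographic key): among equally good totals the
    search drifts toward genomes whose elements are seen in more
    leaves, which selects the most parsimonious representative among
    co-optimal medians.
    """
    cur = set(start)
    total = sum(_leaf_distances(frozenset(cur), leaves, n))
    supp = sum(support.get(e, 0) for e in cur)
    while True:
        locate = {x: e for e in cur for x in e}
        best_move: tuple[tuple, set] | None = None
        for e in targets:
            if e in cur:
                continue
            if len(e) == 2:
                p, q = sorted(e)
                u, v = locate.get(p), locate.get(q)
                if u is None or v is None:
                    continue
                new = set(cur)
                new.discard(u)
                new.discard(v)
                new.add(e)
                leftovers = (u | v) - e
                if leftovers:
                    new.add(frozenset(leftovers))
            else:
                (p,) = e
                u = locate.get(p)
                if u is None or len(u) == 1:
                    continue
                other = next(x for x in u if x != p)
                new = set(cur)
                new.discard(u)
                new.add(e)
                new.add(frozenset({other}))
            nt = sum(
                distance_between_element_sets(frozenset(new), le, n) for le in leaves
            )
            ns = sum(support.get(x, 0) for x in new)
            key = (nt, -ns, element_sort_key(e))
            if best_move is None or key < best_move[0]:
                best_move = (key, new)
        if best_move is None or best_move[0][:2] >= (total, -supp):
            break
        cur = best_move[1]
        total, supp = best_move[0][0], -best_move[0][1]
    return frozenset(cur), total, supp


_ESCALATION_FRACS = (0.2, 0.4, 0.6, 0.8)


def _heuristic_search(
    leaves: Sequence[frozenset[Element]], n: int
) -> tuple[frozenset[Element], int, tuple[int, ...]]:
    """Two-phase steepest-descent search for a low-total genome.

    Phase one descends from each input genome and from the
    majority-graph genome.  If the summed distance still exceeds the
    pairwise lower bound, phase two adds intermediate genomes along the
    deterministic pairwise sorting paths (both directions, at several
    fractions) as extra starts and extra move targets — these contain
    "between" adjacencies absent from every input genome, which pure
    leaf-supported moves can never create.  The best endpoint wins.
    """
    support: dict[Element, int] = {}
    for le in leaves:
        for e in le:
            support[e] = support.get(e, 0) + 1
    targets = sorted(support, key=element_sort_key)
    best: tuple[int, int, frozenset[Element]] | None = None
    for start in list(leaves) + [_majority_start(leaves)]:
        cand = _descend(leaves, n, frozenset(start), support, targets)
        cand = (cand[1], -cand[2], cand[0])
        if best is None or cand[:2] < best[:2]:
            best = cand
    d12 = distance_between_element_sets(leaves[0], leaves[1], n)
    d23 = distance_between_element_sets(leaves[1], leaves[2], n)
    d13 = distance_between_element_sets(leaves[0], leaves[2], n)
    lower, _ = median_bounds(DistanceTriple(d12, d23, d13))
    if best[0] > lower:
        mids: list[frozenset[Element]] = []
        for i, j in ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)):
            mids.extend(_greedy_path_states(leaves[i], leaves[j], _ESCALATION_FRACS))
        ext_targets = set(support)
        for m in mids:
            ext_targets |= m
        ext_sorted = sorted(ext_targets, key=element_sort_key)
        for start in mids:
            cand = _descend(leaves, n, start, support, ext_sorted)
            cand = (cand[1], -cand[2], cand[0])
            if best is None or cand[:2] < best[:2]:
                best = cand
            if best[0] <= lower:
                break
    elems = best[2]
    dists = _leaf_distances(elems, leaves, n)
    return elems, sum(dists), dists


class _Budget(Exception):
    pass


class _LeafGraph:
    """Incremental adjacency-graph bookkeeping between a partial median and one leaf.

    Vertices are the leaf's adjacency/telomere elements plus one vertex
    per committed median element; every extremity whose median element
    is decided contributes an edge.  Components are tracked with a
    union-find supporting rollback, carrying per-component counts of
    unconsumed extremity slots (``open``), edges and path-end vertices.
    When a component closes (open = 0) it is a cycle (no ends) or a
    path whose edge parity decides oddness, so the running distance
    bound

        d(m, leaf) >= n - closed_cycles - odd_paths/2 - unassigned/2

    is admissible throughout and exact once every extremity is decided
    (each remaining extremity can contribute at most 1/2 to C + I/2).
    """

    __slots__ = ("n", "ext_vertex", "is_tel", "parent", "open", "edges", "ends",
                 "closed2", "trail", "next_node")

    def __init__(self, elems: frozenset[Element], n_markers: int, ext_index: dict):
        self.n = n_markers
        nv = len(elems)
        self.ext_vertex = {}
        self.is_tel = []
        self.open = []
        self.edges = []
        self.ends = []
        for vid, e in enumerate(sorted(elems, key=element_sort_key)):
            for x in e:
                self.ext_vertex[ext_index[x]] = vid
            self.is_tel.append(len(e) == 1)
            self.open.append(len(e))
            self.edges.append(0)
            self.ends.append(0)
        self.parent = list(range(nv))
        self.closed2 = 0  # 2*cycles + odd paths, doubled to stay integral
        self.trail: list = []
        self.next_node = nv

    def _find(self, v: int) -> int:
        p = self.parent
        while p[v] != v:
            v = p[v]
        return v

    def commit(self, exts: tuple[int, ...], is_telomere: bool) -> int:
        """Add one median element; returns a trail mark for rollback."""
        mark = len(self.trail)
        m = self.next_node
        self.next_node += 1
        self.parent.append(m)
        self.open.append(0)
        self.edges.append(0)
        self.ends.append(1 if is_telomere else 0)
        self.trail.append(("node",))
        for xi in exts:
            v = self._find(self.ext_vertex[xi])
            r = self._find(m)
            if v == r:
                self.trail.append(("loop", r, self.edges[r], self.open[r], self.ends[r]))
                self.edges[r] += 1
                self.open[r] -= 1
                if self.is_tel[self.ext_vertex[xi]]:
                    self.ends[r] += 1
            else:
                self.trail.append(
                    ("union", v, r, self.edges[r], self.open[r], self.ends[r])
                )
                self.parent[v] = r
                self.edges[r] += self.edges[v] + 1
                self.open[r] += self.open[v] - 1
                self.ends[r] += self.ends[v] + (
                    1 if self.is_tel[self.ext_vertex[xi]] else 0
                )
        r = self._find(m)
        if self.open[r] == 0:
            if self.ends[r] == 0:
                self.closed2 += 2
                self.trail.append(("closed", 2))
            elif self.edges[r] % 2 == 1:
                self.closed2 += 1
                self.trail.append(("closed", 1))
        return mark

    def rollback(self, mark: int) -> None:
        while len(self.trail) > mark:
            rec = self.trail.pop()
            tag = rec[0]
            if tag == "union":
                _, v, r, ed, op, en = rec
                self.parent[v] = v
                self.edges[r], self.open[r], self.ends[r] = ed, op, en
            elif tag == "loop":
                _, r, ed, op, en = rec
                self.edges[r], self.open[r], self.ends[r] = ed, op, en
            elif tag == "closed":
                self.closed2 -= rec[1]
            else:  # node
                self.next_node -= 1
                self.parent.pop()
                self.open.pop()
                self.edges.pop()
                self.ends.pop()

    def bound(self, unassigned: int) -> int:
        # ceil(n - closed2/2 - unassigned/2)
        return (2 * self.n - self.closed2 - unassigned + 1) // 2


def _exact_search(
    leaves: Sequence[frozenset[Element]],
    n: int,
    lower: int,
    incumbent_elems: frozenset[Element],
    incumbent_total: int,
    budget: int,
) -> tuple[frozenset[Element], int, int, int, bool]:
    """Branch-and-bound over perfect matchings (with telomeres) of extremities.

    Adjacencies shared by all three leaves are fixed first (they belong
    to some optimal median); remaining extremities are matched
    depth-first, candidates ordered by leaf support, with the
    cycle-aware lower bound pruning partial assignments.  Returns
    (elements, total, nodes_explored, n_cooptimal, completed).
    """
    all_exts = sorted({x for le in leaves for e in le for x in e})
    ext_index = {x: i for i, x in enumerate(all_exts)}
    graphs = [_LeafGraph(le, n, ext_index) for le in leaves]

    shared = leaves[0] & leaves[1] & leaves[2]
    fixed = sorted((e for e in shared if len(e) == 2), key=element_sort_key)
    assigned = [False] * len(all_exts)
    elements: list[Element] = []
    n_unassigned = len(all_exts)
    for e in fixed:
        exts = tuple(ext_index[x] for x in sorted(e))
        for g in graphs:
            g.commit(exts, False)
        for x in e:
            assigned[ext_index[x]] = True
        elements.append(e)
        n_unassigned -= 2
    free = [i for i in range(len(all_exts)) if not assigned[i]]

    # leaf membership for candidate ordering
    elem_support: dict[Element, int] = {}
    for le in leaves:
        for e in le:
            elem_support[e] = elem_support.get(e, 0) + 1

    best_elems = incumbent_elems
    best_total = incumbent_total
    n_coopt = 1
    nodes = 0
    completed = True

    def dfs(idx: int, n_un: int) -> None:
        nonlocal nodes, best_elems, best_total, n_coopt
        nodes += 1
        if nodes > budget:
            raise _Budget
        while idx < len(free) and assigned[free[idx]]:
            idx += 1
        if idx == len(free):
            total = sum((2 * g.n - g.closed2) // 2 for g in graphs)
            if total < best_total or (
                total == best_total
                and sorted(map(element_sort_key, elements))
                < sorted(map(element_sort_key, best_elems))
            ):
                if total < best_total:
                    n_coopt = 1
                elif frozenset(elements) != best_elems:
                    n_coopt += 1
                best_total = total
                best_elems = frozenset(elements)
            elif total == best_total and frozenset(elements) != best_elems:
                n_coopt += 1
            return
        pi = free[idx]
        p = all_exts[pi]
        cands: list[tuple[int, tuple, Element, tuple[int, ...], bool]] = []
        tel = frozenset({p})
        cands.append(
            (-elem_support.get(tel, 0), element_sort_key(tel), tel, (pi,), True)
        )
        for qi in free[idx + 1 :]:
            if assigned[qi]:
                continue
            e = frozenset({p, all_exts[qi]})
            cands.append(
                (-elem_support.get(e, 0), element_sort_key(e), e, (pi, qi), False)
            )
        cands.sort(key=lambda c: (c[0], c[1]))
        for _, _, e, exts, is_tel in cands:
            marks = [g.commit(exts, is_tel) for g in graphs]
            for i in exts:
                assigned[i] = True
            n_left = n_un - len(exts)
            if sum(g.bound(n_left) for g in graphs) <= best_total:
                elements.append(e)
                dfs(idx + 1, n_left)
                elements.pop()
            for g, mk in zip(graphs, marks):
                g.rollback(mk)
            for i in exts:
                assigned[i] = False
            if best_total <= lower:
                return  # bound attained: global optimum certified

    try:
        dfs(0, n_unassigned)
    except _Budget:
        completed = False
    return best_elems, best_total, nodes, n_coopt, completed


def solve_median(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    mode: str = "exact",
    budget: int = 1_000_000,
) -> MedianResult:
    """Find a genome minimizing the summed DCJ distance to three genomes.

    ``mode="exact"`` runs branch-and-bound and certifies optimality
    (bound attainment or exhausted search) unless the node budget runs
    out, in which case the best genome found so far is returned with
    ``optimal=False`` and a flagged status.  ``mode="heuristic"`` runs
    the local search only; its total is always <= the upper bound.
    """
    if mode not in ("exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    genomes = (g1, g2, g3)
    rep = validate_genome_set(genomes)
    if rep.duplicated_ids or rep.missing_ids:
        raise GenomeFormatError(
            "median inputs do not share a clean marker universe: "
            + "; ".join(rep.messages)
        )
    labels = tuple(g.label for g in genomes)
    leaves = [genome_elements(g) for g in genomes]
    n = g1.n_markers()
    d12 = distance_between_element_sets(leaves[0], leaves[1], n)
    d23 = distance_between_element_sets(leaves[1], leaves[2], n)
    d13 = distance_between_element_sets(leaves[0], leaves[2], n)
    lower, upper = median_bounds(DistanceTriple(d12, d23, d13))

    def result(elems, total, per_leaf, optimal, nodes, ncoopt=1, status="ok"):
        return MedianResult(
            median=elements_to_genome(elems, "median"),
            leaf_labels=labels,
            per_leaf=per_leaf,
            total=total,
            lower=lower,
            upper=upper,
            optimal=optimal,
            nodes_explored=nodes,
            n_cooptimal=ncoopt,
            status=status,
        )

    # identity-leaf shortcut: two equal leaves pin the optimal median
    for i, j, k in ((0, 1, 2), (0, 2, 1), (1, 2, 0)):
        if leaves[i] == leaves[j]:
            per = _leaf_distances(leaves[i], leaves, n)
            return result(leaves[i], sum(per), per, True, 0, status="identity-leaf")

    h_elems, h_total, h_dists = _heuristic_search(leaves, n)
    if mode == "heuristic":
        optimal = h_total <= lower
        return result(h_elems, h_total, h_dists, optimal, 0, status="heuristic")
    if h_total <= lower:
        return result(h_elems, h_total, h_dists, True, 0, status="lower-bound-certified")

    elems, total, nodes, ncoopt, completed = _exact_search(
        leaves, n, lower, h_elems, h_total, budget
    )
    per = _leaf_distances(elems, leaves, n)
    status = "exact" if completed else "budget-exhausted"
    return result(elems, total, per, completed, nodes, ncoopt, status)


def verify_median(
    result: MedianResult, g1: Genome, g2: Genome, g3: Genome
) -> ValidationReport:
    """Recompute distances and bounds; check all MedianResult invariants."""
    msgs: list[str] = []
    genomes = (g1, g2, g3)
    leaves = [genome_elements(g) for g in genomes]
    n = g1.n_markers()
    melems = genome_elements(result.median)
    per = _leaf_distances(melems, leaves, n)
    if per != tuple(result.per_leaf):
        msgs.append(f"per-leaf distances {result.per_leaf} != recomputed {per}")
    if result.total != sum(result.per_leaf):
        msgs.append("total != sum(per_leaf)")
    d12 = distance_between_element_sets(leaves[0], leaves[1], n)
    d23 = distance_between_element_sets(leaves[1], leaves[2], n)
    d13 = distance_between_element_sets(leaves[0], leaves[2], n)
    lower, upper = median_bounds(DistanceTriple(d12, d23, d13))
    if (lower, upper) != (result.lower, result.upper):
        msgs.append(f"bounds {(result.lower, result.upper)} != recomputed {(lower, upper)}")
    if result.total < lower:
        msgs.append("total below lower bound: impossible state")
    if result.optimal and result.total > upper:
        msgs.append("optimal total exceeds upper bound")
    return ValidationReport(not msgs, [], [], msgs)
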