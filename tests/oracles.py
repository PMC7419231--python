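"""Independent brute-force oracles for rearrangement arithmetic.

Everything here deliberately avoids the library's graph machinery: a
genome is a frozenset of plain tuples (sorted extremity pairs or
1-tuples), single-DCJ neighbours are enumerated from first principles,
and distances come from bidirectional BFS over that move graph.  The
exhaustive genome enumerator yields every perfect matching (with
telomeres) of the 2n extremities, i.e. every genome on the universe.
"""

from __future__ import annotations

import itertools
from collections import deque

from dcjkit.genome_model import Extremity, Genome

State = frozenset  # frozenset of tuples of Extremity, length 1 or 2


def to_state(g: Genome) -> State:
    """Genome -> adjacency/telomere state, computed straight from marker lists."""
    elems: set[tuple] = set()
    for chrom in g.chromosomes:
        ms = chrom.markers
        ends = []
        for m in ms:
            left = Extremity(m.id, "t" if m.sign > 0 else "h")
            right = Extremity(m.id, "h" if m.sign > 0 else "t")
            ends.append((left, right))
        for (_, r), (l2, _) in zip(ends, ends[1:]):
            elems.add(tuple(sorted((r, l2))))
        if chrom.topology == "linear":
            elems.add((ends[0][0],))
            elems.add((ends[-1][1],))
        else:
            elems.add(tuple(sorted((ends[-1][1], ends[0][0]))))
    return frozenset(elems)


def neighbors(state: State) -> set[State]:
    """All states one DCJ away: cuts, joins and double-cut rejoinings."""
    els = sorted(state)
    out: set[State] = set()
    for e in els:
        if len(e) == 2:
            ns = set(els)
            ns.remove(e)
            ns.add((e[0],))
            ns.add((e[1],))
            out.add(frozenset(ns))
    for e1, e2 in itertools.combinations(els, 2):
        xs = list(e1) + list(e2)
        base = set(els)
        base.discard(e1)
        base.discard(e2)
        if len(xs) == 2:
            ns = set(base)
            ns.add(tuple(sorted(xs)))
            out.add(frozenset(ns))
        elif len(xs) == 3:
            a, b = (e1 if len(e1) == 2 else e2)
            (c,) = e2 if len(e1) == 2 else e1
            for pair, single in (((a, c), b), ((b, c), a)):
                ns = set(base)
                ns.add(tuple(sorted(pair)))
                ns.add((single,))
                out.add(frozenset(ns))
        else:
            a, b = e1
            c, d = e2
            for p1, p2 in (((a, c), (b, d)), ((a, d), (b, c))):
                ns = set(base)
                ns.add(tuple(sorted(p1)))
                ns.add(tuple(sorted(p2)))
                out.add(frozenset(ns))
    return out


def bfs_distance(sa: State, sb: State, limit: int = 12) -> int:
    """Shortest path in the single-DCJ move graph, bidirectional BFS."""
    if sa == sb:
        return 0
    fa = {sa: 0}
    fb = {sb: 0}
    qa, qb = deque([sa]), deque([sb])
    for _ in range(limit):
        if len(fa) <= len(fb):
            frontier, dist_map, other = qa, fa, fb
        else:
            frontier, dist_map, other = qb, fb, fa
        nxt: deque = deque()
        while frontier:
            s = frontier.popleft()
            for t in neighbors(s):
                if t in other:
                    return dist_map[s] + 1 + other[t]
                if t not in dist_map:
                    dist_map[t] = dist_map[s] + 1
                    nxt.append(t)
        if dist_map is fa:
            qa = nxt
        else:
            qb = nxt
        if not qa and not qb:
            break
    raise RuntimeError("states not connected within limit")


def all_states(n: int):
    """Every genome on markers 1..n: all matchings (with telomeres) of extremities."""
    exts = [Extremity(i, s) for i in range(1, n + 1) for s in ("h", "t")]

    def rec(rem: list) -> "itertools.Iterator[list]":
        if not rem:
            yield []
            return
        p = rem[0]
        for rest in rec(rem[1:]):
            yield [(p,)] + rest
        for k in range(1, len(rem)):
            q = rem[k]
            for rest in rec(rem[1:k] + rem[k + 1 :]):
                yield [tuple(sorted((p, q)))] + rest

    for els in rec(exts):
        yield frozenset(els)


def state_distance(sa: State, sb: State, n: int) -> int:
    """Independent cycle/path count: d = n - cycles - odd_paths/2.

    Re-derives the decomposition with its own traversal over element
    vertices, sharing no code with the library implementation.
    """
    def ext_map(state: State) -> dict:
        m: dict = {}
        for e in state:
            for x in e:
                m[x] = e
        return m

    ma, mb = ext_map(sa), ext_map(sb)
    seen: set = set()
    cycles = odd = 0
    # paths from telomere vertices
    for side, state in ((0, sa), (1, sb)):
        for e in state:
            if len(e) != 1 or (side, e) in seen:
                continue
            seen.add((side, e))
            edges = 0
            cur_side, cur, incoming = side, e, None
            while True:
                outs = [x for x in cur if x != incoming]
                if not outs:
                    break
                x = outs[0]
                cur_side = 1 - cur_side
                cur = (ma if cur_side == 0 else mb)[x]
                seen.add((cur_side, cur))
                incoming = x
                edges += 1
            if edges % 2 == 1:
                odd += 1
    for e in sa:
        if len(e) != 2 or (0, e) in seen:
            continue
        seen.add((0, e))
        edges = 0
        x = e[0]
        cur_side = 0
        while True:
            cur_side = 1 - cur_side
            cur = (ma if cur_side == 0 else mb)[x]
            edges += 1
            if (cur_side, cur) == (0, e):
                break
            seen.add((cur_side, cur))
            x = next(y for y in cur if y != x)
        cycles += 1
    return n - cycles - odd // 2
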