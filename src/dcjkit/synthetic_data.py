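"""Ground-truthed simulation of rearrangement histories and syntelog tables.

The generator emulates the study system: an ancestral genome of a few
dozen to a couple of hundred signed synteny blocks on 8-10 linear
chromosomes, three descendants produced by known counts of rearrangement
events (reversal, translocation, fusion, fission; transposition applied
as two DCJs), a gene-level orthologue ("syntelog") table obtained by
expanding each block into gene families and fractionating them at
per-genome retention rates (defaults 0.70 / 0.49 / 0.42, the retention
observed for the least- and most-fractionated subgenomes after the
*Brassica* whole-genome triplication), and log-normal Ks samples drawn
from explicit Gaussian mixtures on the ln(Ks) scale.

Every stage is reproducible from the config seed alone, and the returned
:class:`TruthSet` carries the full operation logs so inference can be
scored against the simulated truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import Chromosome, Genome, Marker
from .dcj_core import (
    DcjOperation,
    Element,
    apply_dcj,
    element_sort_key,
    genome_elements,
    make_operation,
)

__all__ = [
    "SimulationConfig",
    "OpEvent",
    "TruthSet",
    "simulate_ancestor",
    "evolve_genome",
    "simulate_triple",
    "simulate_syntelog_table",
    "sample_ks",
    "block_adjacency_recovery",
]

log = logging.getLogger(__name__)

DEFAULT_OP_WEIGHTS = {
    # intrachromosomal inversions dominate plant comparative maps
    "reversal": 0.6,
    "translocation": 0.2,
    "fusion": 0.05,
    "fission": 0.05,
    "transposition": 0.1,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated three-genome history."""

    n_blocks: int = 50
    n_chromosomes: int = 8
    branch_ops: tuple[int, int, int] = (5, 5, 15)
    op_weights: dict = field(default_factory=lambda: dict(DEFAULT_OP_WEIGHTS))
    retention: tuple[float, float, float] = (0.70, 0.49, 0.42)
    genes_per_block: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes > self.n_blocks:
            raise ValueError("n_chromosomes may not exceed n_blocks")
        if self.n_chromosomes < 1 or self.n_blocks < 1:
            raise ValueError("n_blocks and n_chromosomes must be positive")
        total = sum(self.op_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"op_weights must sum to 1, got {total}")
        unknown = set(self.op_weights) - set(DEFAULT_OP_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown operation kinds {sorted(unknown)}")
        for r in self.retention:
            if not 0 < r <= 1:
                raise ValueError(f"retention rates must lie in (0, 1], got {r}")
        if len(self.branch_ops) != 3:
            raise ValueError("branch_ops must give three branch lengths")


@dataclass(frozen=True)
class OpEvent:
    """One logged rearrangement event and the DCJ operations realizing it.

    A transposition is one event carrying two DCJs; everything else is
    one event, one DCJ.
    """

    kind: str
    ops: tuple[DcjOperation, ...]

    @property
    def n_dcj(self) -> int:
        return len(self.ops)


@dataclass
class TruthSet:
    """Simulated ancestor, leaves, operation logs and (optionally) genes."""

    ancestor: Genome
    leaves: tuple[Genome, Genome, Genome]
    op_logs: tuple[tuple[OpEvent, ...], ...]
    syntelog_table: pd.DataFrame | None = None
    family_block: dict[str, int] = field(default_factory=dict)
    true_block_count: int = 0
    dropped_blocks: list[int] = field(default_factory=list)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.leaves)


def simulate_ancestor(cfg: SimulationConfig) -> Genome:
    """Random signed ancestor: blocks 1..n over ``n_chromosomes`` linear chromosomes."""
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([1, -1], size=cfg.n_blocks)
    if cfg.n_chromosomes > 1:
        cuts = sorted(
            rng.choice(np.arange(1, cfg.n_blocks), size=cfg.n_chromosomes - 1, replace=False)
        )
    else:
        cuts = []
    bounds = [0] + list(cuts) + [cfg.n_blocks]
    g = Genome("ancestor")
    for i in range(cfg.n_chromosomes):
        markers = tuple(
            Marker(b + 1, int(signs[b])) for b in range(bounds[i], bounds[i + 1])
        )
        g.chromosomes.append(Chromosome(f"chr{i + 1}", markers))
    return g


# ---------------------------------------------------------------------------
# random events


def _marker_left(m: Marker):
    from .genome_model import _left

    return _left(m)


def _marker_right(m: Marker):
    from .genome_model import _right

    return _right(m)


def _boundary_elements(chrom: Chromosome, i: int, j: int):
    """Elements cut by excising markers[i..j] (inclusive, 0-based) of a linear chromosome."""
    ms = chrom.markers
    left_in = _marker_left(ms[i])
    right_in = _marker_right(ms[j])
    left_el = (
        frozenset({left_in})
        if i == 0
        else frozenset({_marker_right(ms[i - 1]), left_in})
    )
    right_el = (
        frozenset({right_in})
        if j == len(ms) - 1
        else frozenset({right_in, _marker_left(ms[j + 1])})
    )
    return left_el, right_el, left_in, right_in


def _pick_interval(
    chroms: list[Chromosome], rng: np.random.Generator
) -> tuple[Chromosome, int, int] | None:
    """Uniform draw over all proper intervals [i..j] of all chromosomes.

    Whole-chromosome spans are excluded (reversing or excising an entire
    chromosome is a structural no-op / undefined target).
    """
    weights = [len(c.markers) * (len(c.markers) + 1) // 2 - 1 for c in chroms]
    total = sum(weights)
    if total <= 0:
        return None
    r = int(rng.integers(total))
    for c, w in zip(chroms, weights):
        if r < w:
            break
        r -= w
    m = len(c.markers)
    for i in range(m):
        span = m - i if i > 0 else m - 1  # skip (0, m-1)
        if r < span:
            return c, i, i + r
        r -= span
    raise AssertionError("interval index out of range")


def _all_adjacency_sites(chroms: list[Chromosome]) -> list[tuple[Chromosome, int]]:
    return [(c, i) for c in chroms for i in range(len(c.markers) - 1)]


def _random_event(g: Genome, kind: str, rng: np.random.Generator) -> OpEvent | None:
    """Construct one applicable random event, or None if ``kind`` cannot apply.

    Sites are uniform over the genome: reversals over marker intervals,
    translocations and fissions over adjacencies, fusions over
    chromosome-end pairs, so long chromosomes receive proportionally
    more breaks.
    """
    chroms = [c for c in g.chromosomes if c.topology == "linear"]
    if kind == "reversal":
        picked = _pick_interval(chroms, rng)
        if picked is None:
            return None
        c, i, j = picked
        left_el, right_el, left_in, right_in = _boundary_elements(c, i, j)
        outer_left = left_el - {left_in}
        outer_right = right_el - {right_in}
        produced = [
            frozenset(outer_left | {right_in}),
            frozenset({left_in} | outer_right),
        ]
        return OpEvent("reversal", (make_operation([left_el, right_el], produced),))
    if kind == "translocation":
        sites = _all_adjacency_sites(chroms)
        if not sites:
            return None
        c1, i1 = sites[int(rng.integers(len(sites)))]
        other = [s for s in sites if s[0] is not c1]
        if not other:
            return None
        c2, i2 = other[int(rng.integers(len(other)))]
        a = _marker_right(c1.markers[i1])
        b = _marker_left(c1.markers[i1 + 1])
        c_ = _marker_right(c2.markers[i2])
        d = _marker_left(c2.markers[i2 + 1])
        if rng.random() < 0.5:
            produced = [frozenset({a, c_}), frozenset({b, d})]
        else:
            produced = [frozenset({a, d}), frozenset({b, c_})]
        return OpEvent(
            "translocation",
            (make_operation([frozenset({a, b}), frozenset({c_, d})], produced),),
        )
    if kind == "fusion":
        if len(chroms) < 2:
            return None
        idx = rng.choice(len(chroms), size=2, replace=False)
        c1, c2 = chroms[int(idx[0])], chroms[int(idx[1])]
        e1 = _marker_left(c1.markers[0]) if rng.random() < 0.5 else _marker_right(c1.markers[-1])
        e2 = _marker_left(c2.markers[0]) if rng.random() < 0.5 else _marker_right(c2.markers[-1])
        return OpEvent(
            "fusion",
            (make_operation([frozenset({e1}), frozenset({e2})], [frozenset({e1, e2})]),),
        )
    if kind == "fission":
        sites = _all_adjacency_sites(chroms)
        if not sites:
            return None
        c, i = sites[int(rng.integers(len(sites)))]
        a = _marker_right(c.markers[i])
        b = _marker_left(c.markers[i + 1])
        return OpEvent(
            "fission",
            (make_operation([frozenset({a, b})], [frozenset({a}), frozenset({b})]),),
        )
    if kind == "transposition":
        picked = _pick_interval(chroms, rng)
        if picked is None:
            return None
        c, i, j = picked
        left_el, right_el, left_in, right_in = _boundary_elements(c, i, j)
        circ = frozenset({left_in, right_in})
        outer = (left_el | right_el) - {left_in, right_in}
        produced1 = [circ]
        if outer:
            produced1.append(frozenset(outer))
        op1 = make_operation([left_el, right_el], produced1)
        mid = apply_dcj_set(genome_elements(g), op1)
        segment_ids = {mk.id for mk in c.markers[i : j + 1]}
        targets = [
            e
            for e in mid
            if e != circ and not any(x.marker_id in segment_ids for x in e)
        ]
        if not targets:
            return None
        targets.sort(key=element_sort_key)
        t = targets[int(rng.integers(len(targets)))]
        if len(t) == 2:
            u, v = sorted(t)
            if rng.random() < 0.5:
                produced2 = [frozenset({u, left_in}), frozenset({right_in, v})]
            else:
                produced2 = [frozenset({u, right_in}), frozenset({left_in, v})]
        else:
            (u,) = t
            if rng.random() < 0.5:
                produced2 = [frozenset({u, left_in}), frozenset({right_in})]
            else:
                produced2 = [frozenset({u, right_in}), frozenset({left_in})]
        op2 = make_operation([circ, t], produced2)
        return OpEvent("transposition", (op1, op2))
    raise ValueError(f"unknown operation kind {kind!r}")


def apply_dcj_set(elems: frozenset[Element], op: DcjOperation) -> frozenset[Element]:
    out = set(elems)
    for e in op.consumed:
        out.discard(e)
    out.update(op.produced)
    return frozenset(out)


def evolve_genome(
    g: Genome,
    n_ops: int,
    weights: dict | None = None,
    seed: int = 0,
) -> tuple[Genome, tuple[OpEvent, ...]]:
    """Apply ``n_ops`` random rearrangement events, returning genome and log.

    Inapplicable draws (e.g. a fission on a single-marker genome) are
    resampled; the resample count is logged at debug level.
    """
    if n_ops < 0:
        raise ValueError("n_ops must be non-negative")
    weights = dict(DEFAULT_OP_WEIGHTS) if weights is None else weights
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    cur = g
    events: list[OpEvent] = []
    resamples = 0
    while len(events) < n_ops:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        ev = _random_event(cur, kind, rng)
        if ev is None:
            resamples += 1
            if resamples > 1000 * (n_ops + 1):
                raise RuntimeError("no applicable rearrangement events found")
            continue
        for op in ev.ops:
            cur = apply_dcj(cur, op)
        cur = Genome(g.label, cur.chromosomes)
        events.append(ev)
    if resamples:
        log.debug("evolve_genome: resampled %d inapplicable events", resamples)
    return cur, tuple(events)


def simulate_triple(cfg: SimulationConfig) -> TruthSet:
    """Ancestor plus three leaves evolved independently along three branches.

    The default branch lengths (5, 5, 15) mimic two closely related
    lineages and one strongly rearranged outgroup-like lineage.
    """
    ancestor = simulate_ancestor(cfg)
    rng = np.random.default_rng(cfg.seed)
    branch_seeds = rng.integers(0, 2**31 - 1, size=3)
    leaves = []
    logs = []
    for i, (n_ops, bs) in enumerate(zip(cfg.branch_ops, branch_seeds), 1):
        leaf = Genome(f"g{i}", ancestor.chromosomes)
        leaf, events = evolve_genome(leaf, int(n_ops), cfg.op_weights, int(bs))
        leaves.append(leaf)
        logs.append(events)
    return TruthSet(
        ancestor=ancestor,
        leaves=tuple(leaves),
        op_logs=tuple(logs),
        true_block_count=cfg.n_blocks,
    )


def simulate_syntelog_table(ts: TruthSet, cfg: SimulationConfig) -> pd.DataFrame:
    """Expand blocks into gene families and fractionate per genome.

    Each block becomes ``genes_per_block`` families laid out in block
    order (reversed with flipped strands inside negatively oriented
    blocks).  Families are retained independently per genome at that
    genome's retention rate, but at least two survivors per block are
    forced so no block becomes unrecoverable; the number of forced
    retentions is logged.  Coordinates use a fixed 1 kb gene / 200 bp
    spacer layout.  The table is stored on the TruthSet and returned.
    """
    gpb = cfg.genes_per_block
    if gpb < 2:
        raise ValueError("genes_per_block must be at least 2")
    rng = np.random.default_rng((cfg.seed, 1))
    rows: list[dict] = []
    fam2block: dict[str, int] = {}
    forced = 0
    gene_len, spacer = 1000, 200
    for gi, leaf in enumerate(ts.leaves):
        rate = cfg.retention[gi]
        for chrom in leaf.chromosomes:
            cursor = 0
            order = 0
            for mk in chrom.markers:
                fams = [f"b{mk.id:04d}g{j:03d}" for j in range(gpb)]
                for f in fams:
                    fam2block[f] = mk.id
                strand = "+" if mk.sign > 0 else "-"
                if mk.sign < 0:
                    fams = fams[::-1]
                keep = rng.random(gpb) < rate
                if keep.sum() < 2:
                    keep[0] = keep[-1] = True
                    forced += 1
                for f, k in zip(fams, keep):
                    if not k:
                        continue
                    order += 1
                    rows.append(
                        {
                            "family_id": f,
                            "genome": leaf.label,
                            "chromosome": chrom.name,
                            "start_bp": cursor,
                            "end_bp": cursor + gene_len,
                            "strand": strand,
                            "order_index": order,
                        }
                    )
                    cursor += gene_len + spacer
    if forced:
        log.debug("simulate_syntelog_table: forced retention in %d blocks", forced)
    table = pd.DataFrame(rows)
    ts.syntelog_table = table
    ts.family_block = fam2block
    return table


# ---------------------------------------------------------------------------
# Ks sampling


@dataclass
class KsComponent:
    weight: float
    mean_lnks: float
    sd: float


def sample_ks(
    components: Sequence[tuple[float, float, float]] | Sequence[KsComponent],
    n: int,
    seed: int = 0,
    pair_label: str = "sim",
):
    """Draw Ks values from a Gaussian mixture on the ln(Ks) scale.

    ``components`` is a list of (weight, mean_lnks, sd); draws are
    exp(N(mean, sd^2)), hence strictly positive.
    """
    from .divergence import KsSample

    comps = [
        c if isinstance(c, KsComponent) else KsComponent(*c) for c in components
    ]
    wsum = sum(c.weight for c in comps)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {wsum}")
    for c in comps:
        if c.sd <= 0:
            raise ValueError("component sd must be positive")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(comps), size=n, p=[c.weight for c in comps])
    means = np.array([c.mean_lnks for c in comps])[which]
    sds = np.array([c.sd for c in comps])[which]
    lnks = rng.normal(means, sds)
    return KsSample(values=np.exp(lnks), pair_label=pair_label)


# ---------------------------------------------------------------------------
# truth scoring


def collapsed_ancestor(ts: TruthSet, blockset) -> Genome:
    """The true ancestor re-expressed on an inferred block universe.

    Inferred blocks merge true blocks that stayed contiguous in every
    leaf, so a direct DCJ comparison between an inferred median and the
    ancestor needs the ancestor collapsed to the same markers: each
    inferred block is located on the ancestor via its member families
    (ascending family order within a positively oriented true block),
    oriented by whether those families run forward or backward there.
    """
    pos: dict[str, tuple[str, int, int]] = {}  # family -> (chrom, index, dir)
    idx = 0
    for chrom in ts.ancestor.chromosomes:
        for mk in chrom.markers:
            fams = sorted(f for f, b in ts.family_block.items() if b == mk.id)
            if mk.sign < 0:
                fams = fams[::-1]
            for f in fams:
                pos[f] = (chrom.name, idx, mk.sign)
                idx += 1
    placed = []
    for blk in blockset.blocks:
        fams = next(iter(blk.placements.values())).families
        hits = [pos[f] for f in fams if f in pos]
        if not hits:
            continue
        chroms = {h[0] for h in hits}
        if len(chroms) != 1:
            raise RuntimeError(f"inferred block {blk.block_id} spans ancestor chromosomes")
        idxs = [h[1] for h in hits]
        orient = 1 if len(idxs) < 2 or idxs[-1] >= idxs[0] else -1
        placed.append((chroms.pop(), min(idxs), blk.block_id, orient))
    placed.sort()
    g = Genome("ancestor_collapsed")
    cur_chrom = None
    markers: list[Marker] = []
    for chrom, _, bid, orient in placed:
        if chrom != cur_chrom:
            if markers:
                g.chromosomes.append(Chromosome(cur_chrom, tuple(markers)))
            cur_chrom, markers = chrom, []
        markers.append(Marker(bid, orient))
    if markers:
        g.chromosomes.append(Chromosome(cur_chrom, tuple(markers)))
    return g


def block_adjacency_recovery(
    ts: TruthSet, blockset, recovered_genomes: Sequence[Genome]
) -> float:
    """Fraction of true block adjacencies preserved by an inferred block set.

    A true adjacency (two blocks consecutive on a leaf chromosome) counts
    as recovered when the two blocks map into the same inferred block or
    into inferred blocks that are themselves consecutive on the matching
    chromosome of the reconstructed genome.  Mapping is by majority vote
    over member gene families.
    """
    # true block -> inferred block, by majority of member families
    votes: dict[int, dict[int, int]] = {}
    for blk in blockset.blocks:
        for placement in blk.placements.values():
            for fam in placement.families:
                tb = ts.family_block.get(fam)
                if tb is None:
                    continue
                votes.setdefault(tb, {}).setdefault(blk.block_id, 0)
                votes[tb][blk.block_id] += 1
            break  # member families identical across genomes; one vote pass
    mapping = {
        tb: max(v.items(), key=lambda kv: (kv[1], -kv[0]))[0] for tb, v in votes.items()
    }
    rec_by_label = {g.label: g for g in recovered_genomes}
    total = 0
    hit = 0
    for leaf in ts.leaves:
        rg = rec_by_label.get(leaf.label)
        pos: dict[int, tuple[str, int]] = {}
        if rg is not None:
            for c in rg.chromosomes:
                for i, mk in enumerate(c.markers):
                    pos[mk.id] = (c.name, i)
        for chrom in leaf.chromosomes:
            for a, b in zip(chrom.markers, chrom.markers[1:]):
                total += 1
                ra, rb = mapping.get(a.id), mapping.get(b.id)
                if ra is None or rb is None:
                    continue
                if ra == rb:
                    hit += 1
                    continue
                pa, pb = pos.get(ra), pos.get(rb)
                if pa and pb and pa[0] == pb[0] and abs(pa[1] - pb[1]) == 1:
                    hit += 1
    return hit / total if total else 1.0
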