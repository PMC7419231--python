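"""Synteny-block construction: chaining, block building, genome emission, painting."""

import pandas as pd
import pytest

from dcjkit.block_builder import (
    ChainParams,
    blocks_to_genomes,
    build_blocks,
    chain_pairwise,
    paint_ancestral,
    prepare_table,
)
from dcjkit.dcj_core import dcj_distance
from dcjkit.genome_model import validate_genome_set

from conftest import make_genome


def toy_table(order_b=None, strand_b=None, genomes=("A", "B"), n=10, chrom="c1"):
    """Two-genome anchor table; genome B order/strand overridable."""
    rows = []
    order_b = order_b or list(range(n))
    strand_b = strand_b or ["+"] * n
    for i in range(n):
        rows.append(dict(family_id=f"f{i:02d}", genome=genomes[0], chromosome=chrom,
                         start_bp=i * 1000, end_bp=i * 1000 + 500, strand="+"))
    for rank, i in enumerate(order_b):
        rows.append(dict(family_id=f"f{i:02d}", genome=genomes[1], chromosome=chrom,
                         start_bp=rank * 1000, end_bp=rank * 1000 + 500,
                         strand=strand_b[rank]))
    return pd.DataFrame(rows)


def triple_table(orders, strands=None, chroms=None, labels=("A", "B", "C"), n=20):
    rows = []
    for gi, label in enumerate(labels):
        order = orders[gi]
        strand = (strands or [["+"] * len(order)] * 3)[gi]
        chrom = (chroms or [["c1"] * len(order)] * 3)[gi]
        for rank, fam in enumerate(order):
            rows.append(dict(family_id=f"f{fam:02d}", genome=label, chromosome=chrom[rank],
                             start_bp=rank * 1000, end_bp=rank * 1000 + 500,
                             strand=strand[rank]))
    return pd.DataFrame(rows)


class TestChaining:
    def test_perfectly_collinear(self):
        chains = chain_pairwise(toy_table(), "A", "B", ChainParams(min_anchors=2))
        assert len(chains) == 1
        assert chains[0].orientation == 1
        assert len(chains[0].families) == 10

    def test_reversed_with_flipped_strands(self):
        t = toy_table(order_b=list(range(9, -1, -1)), strand_b=["-"] * 10)
        chains = chain_pairwise(t, "A", "B", ChainParams(min_anchors=2))
        assert len(chains) == 1
        assert chains[0].orientation == -1
        assert len(chains[0].families) == 10

    def test_transposed_outlier_left_unchained(self):
        # family 4 moved to the end in B; the collinear run of 9 survives
        order = [0, 1, 2, 3, 5, 6, 7, 8, 9, 4]
        chains = chain_pairwise(
            toy_table(order_b=order), "A", "B", ChainParams(max_gap_genes=2, min_anchors=3)
        )
        assert len(chains) == 1
        assert len(chains[0].families) == 9
        assert "f04" not in chains[0].families

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError):
            chain_pairwise(toy_table(), "A", "Z", ChainParams())

    def test_translation_invariance(self):
        t = toy_table()
        shifted = t.copy()
        shifted["start_bp"] += 10_000_000
        shifted["end_bp"] += 10_000_000
        c1 = chain_pairwise(t, "A", "B", ChainParams(min_anchors=2))
        c2 = chain_pairwise(shifted, "A", "B", ChainParams(min_anchors=2))
        assert [c.families for c in c1] == [c.families for c in c2]


class TestBuildBlocks:
    def test_three_identical_genomes_single_block(self):
        t = triple_table([list(range(20))] * 3)
        bs = build_blocks(t, ChainParams(min_anchors=2))
        assert bs.universe_size == 1
        assert len(bs.blocks[0].placements["A"].families) == 20

    def test_internal_inversion_splits_into_three_blocks(self):
        # genome C carries an inversion of families 8..12
        inv = list(range(8)) + list(range(12, 7, -1)) + list(range(13, 20))
        strands_c = ["+"] * 8 + ["-"] * 5 + ["+"] * 7
        t = triple_table([list(range(20)), list(range(20)), inv],
                         strands=[["+"] * 20, ["+"] * 20, strands_c])
        bs = build_blocks(t, ChainParams(min_anchors=2))
        assert bs.universe_size == 3
        orients = sorted(b.placements["C"].orientation for b in bs.blocks)
        assert orients == [-1, 1, 1]

    def test_wrong_genome_count_rejected(self):
        with pytest.raises(ValueError):
            build_blocks(toy_table(), ChainParams())

    def test_nonuniversal_families_dropped(self):
        t = triple_table([list(range(20))] * 3)
        extra = pd.DataFrame([dict(family_id="f99", genome="A", chromosome="c1",
                                   start_bp=10**6, end_bp=10**6 + 10, strand="+")])
        bs = build_blocks(pd.concat([t, extra], ignore_index=True), ChainParams(min_anchors=2))
        assert all("f99" not in b.placements["A"].families for b in bs.blocks)


class TestBlocksToGenomes:
    def test_single_block_yields_one_marker_genomes(self):
        t = triple_table([list(range(20))] * 3)
        genomes = blocks_to_genomes(build_blocks(t, ChainParams(min_anchors=2)))
        assert all(g.n_markers() == 1 for g in genomes)
        assert validate_genome_set(genomes).ok

    def test_inversion_toy_gives_distance_one(self):
        inv = list(range(8)) + list(range(12, 7, -1)) + list(range(13, 20))
        strands_c = ["+"] * 8 + ["-"] * 5 + ["+"] * 7
        t = triple_table([list(range(20)), list(range(20)), inv],
                         strands=[["+"] * 20, ["+"] * 20, strands_c])
        ga, gb, gc = blocks_to_genomes(build_blocks(t, ChainParams(min_anchors=2)))
        assert dcj_distance(ga, gb) == 0
        assert dcj_distance(ga, gc) == 1


class TestPainting:
    def test_rows_and_ancestral_labels(self):
        inv = list(range(8)) + list(range(12, 7, -1)) + list(range(13, 20))
        strands_c = ["+"] * 8 + ["-"] * 5 + ["+"] * 7
        t = triple_table([list(range(20)), list(range(20)), inv],
                         strands=[["+"] * 20, ["+"] * 20, strands_c])
        bs = build_blocks(t, ChainParams(min_anchors=2))
        median = make_genome("median", [1, 2, 3])
        painting = paint_ancestral(bs, median)
        # one row per (block, genome) placement
        assert len(painting) == bs.universe_size * 3
        assert set(painting["ancestral_chromosome"]) == {"c1"}

    def test_universe_mismatch_rejected(self):
        t = triple_table([list(range(20))] * 3)
        bs = build_blocks(t, ChainParams(min_anchors=2))
        with pytest.raises(ValueError):
            paint_ancestral(bs, make_genome("median", [1, 2]))


def test_order_index_derived_from_coordinates():
    t = toy_table().drop(columns=[], errors="ignore")
    prepared = prepare_table(t)
    a = prepared[(prepared.genome == "A") & (prepared.chromosome == "c1")]
    assert list(a.sort_values("start_bp")["order_index"]) == sorted(a["order_index"])
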