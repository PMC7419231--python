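"""DCJ core: adjacency sets, graph decomposition, distance, operations, scenarios."""

import pytest

from dcjkit.dcj_core import (
    adjacencies,
    apply_dcj,
    build_adjacency_graph,
    dcj_distance,
    make_operation,
    sorting_scenario,
)
from dcjkit.genome_model import Extremity, GenomeFormatError

from conftest import make_genome, random_genome
from oracles import bfs_distance, to_state


class TestAdjacencies:
    def test_linear_three_markers(self):
        aset = adjacencies(make_genome("A", [1, 2, 3]))
        assert aset.adjacencies == frozenset(
            {
                frozenset({Extremity(1, "h"), Extremity(2, "t")}),
                frozenset({Extremity(2, "h"), Extremity(3, "t")}),
            }
        )
        assert aset.telomeres == frozenset({Extremity(1, "t"), Extremity(3, "h")})

    def test_singleton_chromosome(self):
        aset = adjacencies(make_genome("A", [1]))
        assert len(aset.adjacencies) == 0
        assert len(aset.telomeres) == 2

    def test_circular_has_no_telomeres(self):
        aset = adjacencies(make_genome("A", [1, 2], circular=True))
        assert len(aset.adjacencies) == 2
        assert len(aset.telomeres) == 0

    def test_counts_obey_linear_invariant(self, rng):
        for _ in range(10):
            g = random_genome(10, rng)
            aset = adjacencies(g)
            n_chrom = len(g.chromosomes)
            assert len(aset.adjacencies) == 10 - n_chrom
            assert len(aset.telomeres) == 2 * n_chrom


class TestAdjacencyGraph:
    def test_identical_genomes_reach_zero(self):
        g = make_genome("A", [1, 2, 3])
        graph = build_adjacency_graph(g, make_genome("B", [1, 2, 3]))
        assert graph.distance == 0
        assert graph.n_cycles + graph.n_odd_paths // 2 == graph.n_markers

    def test_unequal_universes_rejected(self):
        with pytest.raises(GenomeFormatError):
            build_adjacency_graph(make_genome("A", [1, 2]), make_genome("B", [1, 2, 3]))

    def test_odd_paths_always_even(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 12))
            graph = build_adjacency_graph(
                random_genome(n, rng, "a"), random_genome(n, rng, "b")
            )
            assert graph.n_odd_paths % 2 == 0


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (([1, 2, 3],), ([1, 2, 3],), 0),
            (([1, 2, 3],), ([1, -2, 3],), 1),  # single reversal
            (([1, 2, 3, 4],), ([1, 3, 2, 4],), 2),  # transposition = two DCJs
            (([1, 2, 3],), ([-3, -2, -1],), 0),  # whole-chromosome flip
            (([1, 2],), ([1], [2]), 1),  # fission
        ],
    )
    def test_textbook_cases(self, a, b, expected):
        assert dcj_distance(make_genome("a", *a), make_genome("b", *b)) == expected

    def test_symmetry_identity_triangle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 30))
            a, b, c = (random_genome(n, rng, l) for l in "abc")
            dab, dba = dcj_distance(a, b), dcj_distance(b, a)
            assert dab == dba
            assert dcj_distance(a, a) == 0
            assert dcj_distance(a, c) <= dab + dcj_distance(b, c)

    def test_matches_bfs_oracle_small(self, rng):
        """Spot-check against breadth-first search; the full 200-pair sweep
        lives in the acceptance suite."""
        for _ in range(25):
            n = int(rng.integers(2, 6))
            a, b = random_genome(n, rng, "a"), random_genome(n, rng, "b")
            assert dcj_distance(a, b) == bfs_distance(to_state(a), to_state(b))


class TestOperations:
    def test_reversal_op(self):
        g = make_genome("A", [1, 2, 3])
        op = make_operation(
            [
                frozenset({Extremity(1, "h"), Extremity(2, "t")}),
                frozenset({Extremity(2, "h"), Extremity(3, "t")}),
            ],
            [
                frozenset({Extremity(1, "h"), Extremity(2, "h")}),
                frozenset({Extremity(2, "t"), Extremity(3, "t")}),
            ],
        )
        assert apply_dcj(g, op) == make_genome("A", [1, -2, 3])

    def test_fission_op(self):
        g = make_genome("A", [1, 2])
        op = make_operation(
            [frozenset({Extremity(1, "h"), Extremity(2, "t")})],
            [frozenset({Extremity(1, "h")}), frozenset({Extremity(2, "t")})],
        )
        assert apply_dcj(g, op) == make_genome("A", [1], [2])

    def test_inapplicable_op_rejected(self):
        g = make_genome("A", [1, 2])
        op = make_operation(
            [frozenset({Extremity(1, "t"), Extremity(2, "t")})],
            [frozenset({Extremity(1, "t")}), frozenset({Extremity(2, "t")})],
        )
        with pytest.raises(ValueError, match="not applicable"):
            apply_dcj(g, op)

    def test_nonconserving_op_rejected(self):
        with pytest.raises(ValueError):
            make_operation(
                [frozenset({Extremity(1, "h"), Extremity(2, "t")})],
                [frozenset({Extremity(1, "h")}), frozenset({Extremity(3, "t")})],
            )

    def test_applied_op_moves_at_most_one(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            a = random_genome(n, rng, "a")
            b = random_genome(n, rng, "b")
            ops = sorting_scenario(a, b)
            if not ops:
                continue
            g2 = apply_dcj(a, ops[0])
            assert dcj_distance(a, g2) <= 1


class TestScenario:
    def test_identical_genomes_empty(self):
        g = make_genome("A", [1, 2, 3])
        assert sorting_scenario(g, make_genome("B", [1, 2, 3])) == []

    def test_single_reversal(self):
        ops = sorting_scenario(make_genome("A", [1, 2, 3]), make_genome("B", [1, -2, 3]))
        assert len(ops) == 1

    def test_replay_reaches_target_with_optimal_length(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 11))
            a, b = random_genome(n, rng, "a"), random_genome(n, rng, "b")
            ops = sorting_scenario(a, b)
            assert len(ops) == dcj_distance(a, b)
            g = a
            for op in ops:
                g = apply_dcj(g, op)
            assert g == b

    def test_deterministic(self, rng):
        a, b = random_genome(8, rng, "a"), random_genome(8, rng, "b")
        assert sorting_scenario(a, b) == sorting_scenario(a, b)
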