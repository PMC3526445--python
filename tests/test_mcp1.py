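import random

import pytest

from kmcp import (
    CIRCULAR_UNI,
    LINEAR_UNI,
    CompletionError,
    Genome,
    GenomeError,
    IllegalUpdateError,
    adj,
    breakpoint_graph,
    complete_circular,
    complete_linear,
    complete_unrestricted,
    dcj_distance,
    ext,
    free_extremities_graph,
    is_completable,
    make_genome,
    max_blue_updates,
    satisfies,
)
from kmcp.exhaustive import (
    all_matchings,
    best_completion_cycles,
    enumerate_completions,
    max_blue_updates_exhaustive,
)
from conftest import matchings_on, random_genome_on


def circular_genome_on(n: int, rng: random.Random) -> Genome:
    """A uniformly drawn circular genome (perfect matching) on n genes."""
    return Genome(n, rng.choice([m for m in matchings_on(n) if len(m) == n]))


def random_circular_uni_instance(rng: random.Random, n_max: int = 4):
    """A (partial genome, circular reference) pair where the partial genome is
    completable to circular uni-chromosomal and has free extremities."""
    while True:
        n = rng.randint(1, n_max)
        A = circular_genome_on(n, rng)
        G = random_genome_on(n, rng)
        if G.telomeres and is_completable(G, CIRCULAR_UNI):
            return G, A


THREE_GENE_G = [("1h", "2t")]
THREE_GENE_A = [("1h", "2t"), ("2h", "3t"), ("3h", "1t")]


def _genome(n, pairs):
    return make_genome(n, [adj(a, b) for a, b in pairs])


class TestFreeExtremitiesGraph:
    def test_single_gene_base_case(self):
        R = free_extremities_graph(make_genome(1, []), _genome(1, [("1h", "1t")]))
        assert sorted(R.vertices) == [ext("1t"), ext("1h")]
        assert R.blue_edges() == R.red_edges() == [adj("1t", "1h")]
        assert R.n_cycles == 1 and R.n_blue == 1

    def test_three_gene_worked_example(self):
        R = free_extremities_graph(_genome(3, THREE_GENE_G), _genome(3, THREE_GENE_A))
        assert sorted(R.vertices) == [ext("1t"), ext("2h"), ext("3t"), ext("3h")]
        assert R.blue_edges() == [adj("1t", "3h"), adj("2h", "3t")]
        assert R.red_edges() == [adj("1t", "2h"), adj("3t", "3h")]

    def test_rejects_non_circular_reference(self):
        with pytest.raises(GenomeError, match="circular"):
            free_extremities_graph(make_genome(2, []), _genome(2, [("1h", "2t")]))

    def test_rejects_complete_partial_genome(self):
        G = _genome(1, [("1h", "1t")])
        with pytest.raises(GenomeError, match="free"):
            free_extremities_graph(G, G)

    def test_matching_sizes_and_even_cycles(self):
        """|blue| = |red| = |free|/2 and every component is an even
        alternating cycle, for every random valid instance."""
        rng = random.Random(23)
        for _ in range(60):
            G, A = random_circular_uni_instance(rng)
            R = free_extremities_graph(G, A)
            assert len(R.blue_edges()) == len(R.red_edges()) == len(R.vertices) // 2
            for cycle in R.cycles():
                assert len(cycle) % 2 == 0
                # alternation: blue and red partners interleave along the walk
                for i, v in enumerate(cycle):
                    nxt = cycle[(i + 1) % len(cycle)]
                    partner = R.blue[v] if i % 2 == 0 else R.red[v]
                    assert partner == nxt or len(cycle) == 2


class TestUpdate:
    def test_base_case_empties_graph_and_gains_cycle(self):
        R = free_extremities_graph(make_genome(1, []), _genome(1, [("1h", "1t")]))
        R2 = R.update(ext("1t"), ext("1h"))
        assert not R2.vertices and R2.cycle_gain == 1

    def test_cross_cycle_update_merges_cycles(self):
        G = _genome(2, [])
        A = _genome(2, [("1h", "1t"), ("2h", "2t")])
        R = free_extremities_graph(G, A)
        assert R.n_cycles == 2
        R2 = R.update(ext("1t"), ext("2t"))
        assert R2.n_cycles == 1 and R2.cycle_gain == 0

    def test_premature_chromosome_closure_rejected(self):
        G = _genome(2, [])
        A = _genome(2, [("1h", "1t"), ("2h", "2t")])
        R = free_extremities_graph(G, A)
        with pytest.raises(IllegalUpdateError):
            R.update(ext("1t"), ext("1h"))  # closes gene 1's circle too early


class TestMaxBlueUpdates:
    def test_single_two_cycle(self):
        R = free_extremities_graph(make_genome(1, []), _genome(1, [("1h", "1t")]))
        assert max_blue_updates(R) == 1

    def test_formula_matches_exhaustive_update_search(self):
        rng = random.Random(31)
        for _ in range(25):
            G, A = random_circular_uni_instance(rng)
            R = free_extremities_graph(G, A)
            assert max_blue_updates(R) == max_blue_updates_exhaustive(R)


class TestCompleteUnrestricted:
    def test_complete_input_returned_unchanged(self, fig_genome):
        A = _genome(5, [("1t", "3t")] )
        full = fig_genome.with_adjacencies([adj("1t", "3t")])
        assert complete_unrestricted(full, A) == full

    def test_single_reference_path_closed(self):
        out = complete_unrestricted(make_genome(1, []), _genome(1, [("1h", "1t")]))
        assert out == _genome(1, [("1h", "1t")])

    def test_matches_exhaustive_extension_minimum(self):
        rng = random.Random(41)
        for _ in range(60):
            n = rng.randint(1, 3)
            G, A = random_genome_on(n, rng), random_genome_on(n, rng)
            out = complete_unrestricted(G, A)
            assert G.adjacencies <= out.adjacencies
            best = min(dcj_distance(Genome(n, G.adjacencies | extra), A)
                       for extra in all_matchings(sorted(G.telomeres)))
            assert dcj_distance(out, A) == best


class TestCompleteCircular:
    def test_single_gene(self):
        out = complete_circular(make_genome(1, []), _genome(1, [("1h", "1t")]))
        assert out == _genome(1, [("1h", "1t")])
        assert dcj_distance(out, _genome(1, [("1h", "1t")])) == 0

    def test_three_gene_worked_example_reaches_three_cycles(self):
        G, A = _genome(3, THREE_GENE_G), _genome(3, THREE_GENE_A)
        out = complete_circular(G, A)
        assert breakpoint_graph([out, A]).n_cycles == 3
        assert best_completion_cycles(G, A, CIRCULAR_UNI) == 3

    def test_uncompletable_input_rejected(self):
        G = _genome(2, [("1h", "1t")])
        A = _genome(2, [("1h", "2t"), ("2h", "1t")])
        with pytest.raises(CompletionError):
            complete_circular(G, A)

    def test_matches_exhaustive_completion_maximum(self):
        rng = random.Random(43)
        for _ in range(40):
            G, A = random_circular_uni_instance(rng)
            out = complete_circular(G, A)
            assert G.adjacencies <= out.adjacencies
            assert satisfies(out, CIRCULAR_UNI)
            assert (breakpoint_graph([out, A]).n_cycles
                    == best_completion_cycles(G, A, CIRCULAR_UNI))

    def test_any_optimal_first_adjacency_extends_to_optimum(self):
        """Greedy continuation after any cross-cycle or blue-edge first move
        still reaches the exhaustive optimum."""
        rng = random.Random(47)
        for _ in range(10):
            G, A = random_circular_uni_instance(rng, n_max=3)
            target = best_completion_cycles(G, A, CIRCULAR_UNI)
            R = free_extremities_graph(G, A)
            index = R.cycle_index()
            verts = sorted(R.vertices)
            for i, u in enumerate(verts):
                for v in verts[i + 1:]:
                    cross_cycle = index[u] != index[v]
                    blue_edge = R.blue[u] == v
                    if not (cross_cycle or blue_edge):
                        continue
                    if len(R.vertices) > 2 and R.red[u] == v:
                        continue
                    G1 = G.with_adjacencies([adj(u.token, v.token)])
                    if not is_completable(G1, CIRCULAR_UNI):
                        continue
                    out = (G1 if satisfies(G1, CIRCULAR_UNI)
                           else complete_circular(G1, A))
                    assert breakpoint_graph([out, A]).n_cycles == target


class TestThetaAndCompleteLinear:
    def test_theta_path_and_cycle_residents(self):
        from kmcp import theta
        G, A = _genome(3, THREE_GENE_G), _genome(3, THREE_GENE_A)
        assert theta(G, A, adj("2h", "3t")) == 1
        assert theta(G, A, adj("1h", "2t")) == 2

    def test_theta_requires_reference_adjacency(self):
        from kmcp import theta
        G, A = _genome(3, THREE_GENE_G), _genome(3, THREE_GENE_A)
        with pytest.raises(GenomeError):
            theta(G, A, adj("1t", "2h"))

    def test_theta_one_for_empty_partial_genome(self):
        from kmcp import theta
        A = _genome(3, THREE_GENE_A)
        for e in A.sorted_adjacencies():
            assert theta(make_genome(3, []), A, e) == 1

    @pytest.mark.parametrize("ref_pairs,expected_cycles", [
        ([("2h", "3t"), ("3h", "1t")], 1),  # removed edge on the doubled cycle
        ([("1h", "2t"), ("3h", "1t")], 2),  # removed edge on a path
    ])
    def test_three_gene_linear_examples(self, ref_pairs, expected_cycles):
        G = _genome(3, THREE_GENE_G)
        A_l = _genome(3, ref_pairs)
        out = complete_linear(G, A_l)
        assert G.adjacencies <= out.adjacencies
        assert satisfies(out, LINEAR_UNI)
        assert breakpoint_graph([out, A_l]).n_cycles == expected_cycles
        assert best_completion_cycles(G, A_l, LINEAR_UNI) == expected_cycles

    def test_complete_input_returned_unchanged(self):
        G = _genome(3, [("1h", "2t"), ("2h", "3t")])
        A_l = _genome(3, [("2h", "3t"), ("3h", "1t")])
        assert complete_linear(G, A_l) == G

    def test_circular_partial_genome_rejected(self):
        G = _genome(2, [("1h", "1t")])
        A_l = _genome(2, [("1h", "2t")])
        with pytest.raises(CompletionError):
            complete_linear(G, A_l)

    def test_theta_relates_circular_and_linear_optima(self):
        """c_hat_c(G, A_c) = c_hat_l(G, A_l) + theta(e), both sides by
        exhaustive enumeration, over random linear instances."""
        from kmcp import theta
        rng = random.Random(53)
        done = 0
        while done < 25:
            n = rng.randint(2, 4)
            A_c = circular_genome_on(n, rng)
            if not satisfies(A_c, CIRCULAR_UNI):
                continue
            e = rng.choice(A_c.sorted_adjacencies())
            A_l = A_c.without_adjacency(e)
            G = random_genome_on(n, rng)
            if not G.telomeres or not is_completable(G, LINEAR_UNI):
                continue
            c_c = best_completion_cycles(G, A_c, CIRCULAR_UNI)
            c_l = best_completion_cycles(G, A_l, LINEAR_UNI)
            assert c_c == c_l + theta(G, A_c, e)
            done += 1

    def test_matches_exhaustive_completion_maximum(self):
        rng = random.Random(59)
        done = 0
        while done < 30:
            n = rng.randint(2, 4)
            A_c = circular_genome_on(n, rng)
            if not satisfies(A_c, CIRCULAR_UNI):
                continue
            A_l = A_c.without_adjacency(rng.choice(A_c.sorted_adjacencies()))
            G = random_genome_on(n, rng)
            if not is_completable(G, LINEAR_UNI) or satisfies(G, LINEAR_UNI):
                continue
            out = complete_linear(G, A_l)
            assert (breakpoint_graph([out, A_l]).n_cycles
                    == best_completion_cycles(G, A_l, LINEAR_UNI))
            done += 1
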