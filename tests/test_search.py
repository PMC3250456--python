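"""Story search tests: successor generation, A* optimality, monotonicity."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from storyline.lattice import binarize, mine_concepts
from storyline.search import (
    SearchParams,
    astar_story,
    generate_successors,
    iter_successor_edges,
    min_candidate_count,
)
from storyline.vectors import TermVector, soergel_distance

from conftest import uniform_vector


def make_universe(term_sets: dict[str, set[str]], min_support=None):
    """Uniform-weight vectors plus their concept index."""
    vectors = {d: uniform_vector(d, ts) for d, ts in term_sets.items()}
    support = min_support if min_support is not None else 1 / len(term_sets)
    index = mine_concepts(binarize(vectors), support)
    return index, vectors


# A -- B -- C -- D line: adjacent pairs at 0.8, all others at 1.0
LINE = {
    "A": {"a1", "a2", "ab"},
    "B": {"ab", "b1", "bc"},
    "C": {"bc", "c1", "cd"},
    "D": {"cd", "d1", "d2"},
}


class TestMinCandidateCount:
    @pytest.mark.parametrize("k,b,expected", [
        (2, 1, 1),   # a single candidate forms the only 2-clique
        (3, 10, 5),  # C(5,2) = 10
        (3, 3, 3),   # C(3,2) = 3
        (2, 5, 5),
        (4, 20, 6),  # C(6,3) = 20
    ])
    def test_smallest_m_with_enough_subsets(self, k, b, expected):
        assert min_candidate_count(k, b) == expected

    def test_never_fewer_than_b_cliques(self):
        from math import comb
        for k in range(2, 6):
            for b in range(1, 40):
                m = min_candidate_count(k, b)
                assert comb(m, k - 1) >= b
                assert m == k - 1 or comb(m - 1, k - 1) < b


class TestGenerateSuccessors:
    def test_three_mutually_close_candidates_give_three_cliques(self):
        # hub + 3 candidates all pairwise within theta
        term_sets = {
            "H": {"s", "h"},
            "X": {"s", "x"},
            "Y": {"s", "y"},
            "Z": {"s", "z"},
        }
        index, vectors = make_universe(term_sets)
        params = SearchParams(theta=0.7, k=3, b=3)
        cliques = generate_successors("H", params, index, vectors)
        assert len(cliques) == 3
        assert all(len(c.members) == 3 and "H" in c.members for c in cliques)
        avg = [c.avg_distance for c in cliques]
        assert avg == sorted(avg)

    def test_candidates_close_to_junction_but_not_each_other(self):
        # X and Y within theta of H but disjoint from each other
        term_sets = {"H": {"hx", "hy"}, "X": {"hx", "x1"}, "Y": {"hy", "y1"}}
        index, vectors = make_universe(term_sets)
        params = SearchParams(theta=0.75, k=3, b=3)
        assert generate_successors("H", params, index, vectors) == []

    def test_k2_every_candidate_within_theta_is_a_clique(self):
        index, vectors = make_universe(LINE)
        params = SearchParams(theta=0.85, k=2, b=5)
        cliques = generate_successors("B", params, index, vectors)
        partners = {next(iter(c.members - {"B"})) for c in cliques}
        assert partners == {"A", "C"}


class TestAStar:
    def test_line_corpus_recovers_full_chain(self):
        index, vectors = make_universe(LINE)
        params = SearchParams(theta=0.85, k=2, b=3)
        chain = astar_story("A", "D", params, index, vectors)
        assert chain is not None
        assert chain.junctions == ["A", "B", "C", "D"]
        assert chain.total_cost == pytest.approx(2.4)
        assert chain.link_distances == pytest.approx([0.8, 0.8, 0.8])

    def test_theta_below_every_distance_gives_no_story(self):
        index, vectors = make_universe(LINE)
        params = SearchParams(theta=0.5, k=2, b=3)
        assert astar_story("A", "D", params, index, vectors) is None

    def test_end_within_theta_gives_single_link_chain(self):
        index, vectors = make_universe(LINE)
        params = SearchParams(theta=0.85, k=2, b=3)
        chain = astar_story("A", "B", params, index, vectors)
        assert chain.junctions == ["A", "B"]
        assert len(chain.cliques) == 1

    def test_start_equals_end_is_error(self):
        index, vectors = make_universe(LINE)
        with pytest.raises(ValueError):
            astar_story("A", "A", SearchParams(), index, vectors)

    def test_empty_vector_is_error(self):
        index, vectors = make_universe(LINE)
        vectors["E"] = TermVector("E", {})
        with pytest.raises(ValueError):
            astar_story("E", "A", SearchParams(), index, vectors)


def check_chain_invariants(chain, theta, k, vectors, start, end):
    """Re-check every CliqueChain invariant from the vectors alone."""
    assert chain.junctions[0] == start and chain.junctions[-1] == end
    assert len(set(chain.junctions)) == len(chain.junctions)  # simple path
    assert len(chain.cliques) == len(chain.junctions) - 1
    total = 0.0
    for i, (a, b) in enumerate(zip(chain.junctions, chain.junctions[1:])):
        d = soergel_distance(vectors[a], vectors[b])
        assert d <= theta + 1e-12
        assert chain.link_distances[i] == pytest.approx(d)
        total += d
        clique = chain.cliques[i]
        assert len(clique.members) == k
        assert a in clique.members and b in clique.members
        for x, y in itertools.combinations(sorted(clique.members), 2):
            assert soergel_distance(vectors[x], vectors[y]) <= theta + 1e-12
    assert chain.total_cost == pytest.approx(total)


def dijkstra_optimal_cost(start, end, params, index, vectors):
    """Independent optimum: materialize the successor edge relation and run
    scipy's Dijkstra over it (no heuristic, no shared search code)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    ids = sorted(vectors)
    pos = {d: i for i, d in enumerate(ids)}
    rows, cols, vals = [], [], []
    for doc in ids:
        if not vectors[doc]:
            continue
        for member, dist, _ in iter_successor_edges(
            doc, end, params, index, vectors
        ):
            rows.append(pos[doc])
            cols.append(pos[member])
            vals.append(dist)
    graph = csr_matrix((vals, (rows, cols)), shape=(len(ids), len(ids)))
    costs = dijkstra(graph, directed=True, indices=pos[start])
    c = costs[pos[end]]
    return None if np.isinf(c) else float(c)


class TestOptimality:
    def test_astar_cost_equals_exhaustive_optimum_on_random_corpora(self):
        """On 50 random corpora (<=30 docs), across theta in {0.95, 0.9, 0.85}
        and k in {2, 3}, the A* chain cost equals the constrained optimum."""
        rng = np.random.default_rng(11)
        n_with_story = 0
        for trial in range(50):
            n_docs = int(rng.integers(8, 31))
            pool = 24
            term_sets = {}
            for i in range(n_docs):
                size = int(rng.integers(3, 7))
                terms = rng.choice(pool, size=size, replace=False)
                term_sets[f"d{i:02d}"] = {f"t{t}" for t in terms}
            index, vectors = make_universe(term_sets, min_support=2 / n_docs)
            ids = sorted(term_sets)
            start, end = ids[0], ids[-1]
            for theta in (0.95, 0.90, 0.85):
                for k in (2, 3):
                    params = SearchParams(theta=theta, k=k, b=5)
                    chain = astar_story(start, end, params, index, vectors)
                    optimal = dijkstra_optimal_cost(
                        start, end, params, index, vectors
                    )
                    if chain is None:
                        assert optimal is None
                    else:
                        n_with_story += 1
                        assert chain.total_cost == pytest.approx(optimal)
                        check_chain_invariants(
                            chain, theta, k, vectors, start, end
                        )
        assert n_with_story > 20  # the suite actually exercised stories


# line of 5 documents with a weak direct start-end shortcut
SHORTCUT = {
    "A": {"a1", "a2", "ab1", "ab2", "ae"},
    "B": {"ab1", "ab2", "b1", "bc1", "bc2"},
    "C": {"bc1", "bc2", "c1", "cd1", "cd2"},
    "D": {"cd1", "cd2", "d1", "de1", "de2"},
    "E": {"de1", "de2", "e1", "e2", "ae"},
}


class TestMonotonicity:
    def test_story_count_non_increasing_and_length_non_decreasing(self):
        """Stricter thresholds keep or remove stories (never add) and the
        surviving story gets no shorter."""
        index, vectors = make_universe(SHORTCUT)
        # adjacent pairs at 0.75, the A-E shortcut at ~0.889
        assert soergel_distance(vectors["A"], vectors["E"]) == pytest.approx(8 / 9)
        counts, lengths = [], []
        for theta in (0.90, 0.80, 0.70):
            chain = astar_story(
                "A", "E", SearchParams(theta=theta, k=2, b=5), index, vectors
            )
            counts.append(0 if chain is None else 1)
            if chain is not None:
                lengths.append(len(chain))
        assert counts == sorted(counts, reverse=True)
        assert lengths == sorted(lengths)  # loose: direct link; strict: chain
        assert lengths == [2, 5]

    def test_counts_non_increasing_in_theta_and_k_on_synthetic_corpus(
        self, synthetic_default
    ):
        _, corpus, gt, vectors = synthetic_default
        from storyline.lattice import default_min_support

        index = mine_concepts(binarize(vectors), default_min_support(len(corpus)))
        pairs = [
            ("B00", "B04"), ("B00", "B02"), ("C0d05", "C0d09"),
            ("C1d04", "C1d09"), ("C0d05", "C1d05"), ("B02", "C0d07"),
        ]
        thetas = (0.95, 0.90, 0.85, 0.75, 0.55)
        counts = {}
        for k in (2, 3):
            for theta in thetas:
                params = SearchParams(theta=theta, k=k, b=5)
                n = sum(
                    1
                    for s, e in pairs
                    if astar_story(s, e, params, index, vectors) is not None
                )
                counts[(k, theta)] = n
        for k in (2, 3):
            series = [counts[(k, t)] for t in thetas]
            assert series == sorted(series, reverse=True), series
        for theta in thetas:
            assert counts[(3, theta)] <= counts[(2, theta)]
        assert counts[(2, thetas[0])] > 0
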