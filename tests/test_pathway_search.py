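"""k-shortest loop-less search, pathway scoring and benchmark modes."""

import math
from collections import deque

import pytest

from carpath.graph_model import threshold_subgraph
from carpath.pathway_search import (
    SearchQuery,
    multi_source_search,
    score_pathway,
    two_sided_unweighted_search,
    yen_k_shortest,
)
from conftest import graph_from_edges
from oracle_utils import enumerate_simple_paths, graph_adjacency, sort_paths


class TestScorePathway:
    @pytest.mark.parametrize(
        "cars, transform, score, avg",
        [
            ([1.0, 1.0], "default", 2.0, 1.0),
            ([0.5, 0.8], "default", 3.25, 0.65),
            ([0.5, 0.8], "exp", math.exp(1.0) + math.exp(0.25), 0.65),
            ([0.5, 0.8], "sqrt", math.sqrt(2) + math.sqrt(1.25), 0.65),
        ],
    )
    def test_hand_values(self, cars, transform, score, avg):
        got_score, got_avg = score_pathway(cars, transform)
        assert got_score == pytest.approx(score, abs=1e-9)
        assert got_avg == pytest.approx(avg, abs=1e-12)

    def test_perfect_conservation_score_equals_length_under_all_transforms(self):
        for t in ("default", "sqrt", "exp"):
            score, avg = score_pathway([1.0] * 7, t)
            assert score == pytest.approx(7.0, abs=1e-12)
            assert avg == 1.0

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            score_pathway([], "default")


class TestYenKShortest:
    def test_diamond_ranks_conserving_route_first(self, diamond_graph):
        paths = yen_k_shortest(
            diamond_graph, SearchQuery(source="A", target="D", k=2)
        )
        assert [p.node_sequence for p in paths] == [
            ("A", "B", "D"), ("A", "C", "D"),
        ]
        assert paths[0].score == pytest.approx(2.0)
        assert paths[1].score == pytest.approx(4.0)
        assert [p.rank for p in paths] == [1, 2]

    def test_k_beyond_path_count_returns_all(self):
        # exactly 3 simple A->D routes; k=10 must return all of them
        g = graph_from_edges([
            ("R1", "A", "B", 1.0), ("R2", "B", "D", 1.0),
            ("R3", "A", "C", 0.5), ("R4", "C", "D", 0.5),
            ("R5", "A", "D", 0.25),
        ])
        paths = yen_k_shortest(g, SearchQuery(source="A", target="D", k=10))
        assert len(paths) == 3
        # score tie at 4.0 broken by length: the direct edge outranks A-C-D
        assert [p.node_sequence for p in paths] == [
            ("A", "B", "D"), ("A", "D"), ("A", "C", "D"),
        ]

    def test_paths_are_loop_less(self, random_graph_factory):
        g = random_graph_factory(n_nodes=10, edge_prob=0.5, seed=3)
        paths = yen_k_shortest(
            g, SearchQuery(source="C00001", target="C00010", k=50)
        )
        assert paths
        for p in paths:
            assert len(set(p.node_sequence)) == len(p.node_sequence)

    def test_scores_non_decreasing_with_rank_under_every_transform(
        self, random_graph_factory
    ):
        for transform in ("default", "sqrt", "exp"):
            g = random_graph_factory(n_nodes=11, edge_prob=0.4, seed=5)
            g.set_transform(transform)
            paths = yen_k_shortest(
                g,
                SearchQuery(source="C00001", target="C00011", k=30,
                            transform=transform),
            )
            scores = [p.score for p in paths]
            assert scores == sorted(scores)

    def test_max_length_discards_without_counting_toward_k(self, hub_fixture):
        from carpath.graph_model import build_graph

        g = build_graph(hub_fixture.pairs, hub_fixture.compounds, exclusions=())
        paths = yen_k_shortest(
            g, SearchQuery(source="C00001", target="C00007", k=2, max_length=2)
        )
        assert len(paths) == 1  # only the 2-step hub route fits the limit
        assert paths[0].node_sequence == ("C00001", "C00002", "C00007")

    def test_unknown_endpoint_raises_naming_the_id(self, diamond_graph):
        with pytest.raises(KeyError, match="C99999"):
            yen_k_shortest(
                diamond_graph, SearchQuery(source="C99999", target="D", k=1)
            )

    def test_source_equals_target_rejected(self):
        with pytest.raises(ValueError):
            SearchQuery(source="A", target="A", k=1)

    def test_disconnected_endpoints_give_empty_result(self, two_triangles_graph):
        paths = yen_k_shortest(
            two_triangles_graph, SearchQuery(source="A", target="X", k=5)
        )
        assert paths == []

    def test_pathway_records_are_fully_populated(self, diamond_graph):
        (best, *_rest) = yen_k_shortest(
            diamond_graph, SearchQuery(source="A", target="D", k=1)
        )
        assert best.length == 2 == len(best.reaction_sequence)
        assert best.average_car == pytest.approx(1.0)
        assert best.representative_reactions() == ("R1", "R2")
        assert best.score == pytest.approx(sum(best.step_distances))


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration_on_random_graphs(
        self, random_graph_factory
    ):
        """k=inf output must equal all simple paths sorted by
        (score, length, lexicographic node sequence)."""
        n_compared = 0
        for seed in range(30):
            g = random_graph_factory(n_nodes=10, edge_prob=0.35, seed=seed)
            source, target = "C00001", "C00010"
            if source not in g.graph or target not in g.graph:
                continue
            adj = graph_adjacency(g)
            expected = sort_paths(list(enumerate_simple_paths(adj, source, target)))
            got = yen_k_shortest(
                g, SearchQuery(source=source, target=target, k=10**9)
            )
            assert [p.node_sequence for p in got] == [nodes for nodes, _ in expected]
            for p, (_, score) in zip(got, expected):
                assert p.score == pytest.approx(score, abs=1e-9)
            n_compared += 1
        assert n_compared >= 20


class TestHubAvoidance:
    def test_transform_choice_flips_the_winning_route(self, hub_fixture):
        from carpath.graph_model import build_graph

        for transform in ("default", "sqrt", "exp"):
            g = build_graph(hub_fixture.pairs, hub_fixture.compounds,
                            transform=transform, exclusions=())
            paths = yen_k_shortest(
                g,
                SearchQuery(source=hub_fixture.source, target=hub_fixture.target,
                            k=2, transform=transform),
            )
            gt = hub_fixture.ground_truth[transform]
            winner = gt[gt["rank1"]]
            assert list(paths[0].node_sequence) == winner["nodes"]
            assert paths[0].score == pytest.approx(winner["score"], abs=1e-9)

    def test_exponential_transform_prefers_long_conserving_chain(self, hub_fixture):
        gt = hub_fixture.ground_truth
        assert gt["exp"]["rank1"] == "chain_route"
        assert gt["sqrt"]["rank1"] == "hub_route"


def _single_sided_bfs_shortest_paths(adj, source, target):
    """Oracle: all minimum-hop simple paths via plain BFS layering."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    if target not in dist:
        return []
    paths = []

    def extend(path):
        node = path[-1]
        if node == target:
            paths.append(tuple(path))
            return
        for nbr in sorted(adj[node]):
            if dist.get(nbr) == dist[node] + 1:
                extend(path + [nbr])

    extend([source])
    return sorted(paths)


class TestTwoSidedUnweightedSearch:
    def test_path_graph_single_route(self):
        g = graph_from_edges(
            [("R1", "A", "B", 0.9), ("R2", "B", "C", 0.9), ("R3", "C", "D", 0.9)]
        )
        view = threshold_subgraph(g, 0.34)
        paths = two_sided_unweighted_search(
            view, SearchQuery(source="A", target="D", k=5)
        )
        assert len(paths) == 1
        assert paths[0].node_sequence == ("A", "B", "C", "D")
        assert paths[0].score == pytest.approx(3.0)  # hop count

    def test_hop_counts_non_decreasing(self, random_graph_factory):
        g = random_graph_factory(n_nodes=12, edge_prob=0.35, seed=11)
        view = threshold_subgraph(g, 0.0)
        paths = two_sided_unweighted_search(
            view, SearchQuery(source="C00001", target="C00012", k=40)
        )
        lengths = [p.length for p in paths]
        assert lengths == sorted(lengths)

    def test_minimum_hop_paths_match_bfs_oracle(self, random_graph_factory):
        for seed in range(10):
            g = random_graph_factory(n_nodes=11, edge_prob=0.3, seed=seed)
            view = threshold_subgraph(g, 0.0)
            source, target = "C00001", "C00011"
            if source not in view.graph or target not in view.graph:
                continue
            adj = graph_adjacency(view, weight="distance")
            expected = _single_sided_bfs_shortest_paths(adj, source, target)
            got = two_sided_unweighted_search(
                view, SearchQuery(source=source, target=target, k=10**9)
            )
            if not expected:
                assert got == []
                continue
            min_hops = len(expected[0]) - 1
            got_min = sorted(
                p.node_sequence for p in got if p.length == min_hops
            )
            assert got_min == expected


class TestMultiSourceSearch:
    def test_matches_independent_single_queries(self, random_graph_factory):
        g = random_graph_factory(n_nodes=12, edge_prob=0.4, seed=2)
        sources = ["C00001", "C00002", "C00003"]
        target = "C00012"
        combined = multi_source_search(g, sources, target, k=5)
        assert list(combined) == sources
        for source in sources:
            single = yen_k_shortest(
                g, SearchQuery(source=source, target=target, k=5)
            )
            assert [p.node_sequence for p in combined[source]] == [
                p.node_sequence for p in single
            ]

    def test_empty_source_list(self, diamond_graph):
        assert multi_source_search(diamond_graph, [], "D") == {}

    def test_failing_source_does_not_affect_others(self, diamond_graph):
        result = multi_source_search(diamond_graph, ["A", "C99999"], "D", k=2)
        assert len(result["A"]) == 2
        assert result["C99999"] == []
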