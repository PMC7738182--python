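"""Trajectory enumeration, accessibility, greedy paths and network export."""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from fitscape.landscape import Substitution
from fitscape.synthetic import LandscapeSpec, simulate_fitness_landscape
from fitscape.trajectories import (
    StepRule,
    build_network,
    classify_step,
    count_accessible,
    enumerate_trajectories,
    export_network,
    greedy_plausible_path,
    read_edge_csv,
)

from conftest import brute_force_accessible, make_landscape, multiplicative_landscape


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 1), (4, 24), (7, 5040)])
    def test_counts(self, n, count):
        assert sum(1 for _ in enumerate_trajectories(n)) == count

    def test_lexicographic_and_distinct(self):
        perms = list(enumerate_trajectories(3))
        assert perms == sorted(set(perms))

    @pytest.mark.parametrize("n", [0, 13])
    def test_guard_rails(self, n):
        with pytest.raises(ValueError, match="factorial"):
            enumerate_trajectories(n)


class TestStepRule:
    def test_twenty_percent_gain_improves(self):
        assert classify_step(1.0, 1.20, StepRule(0.16))

    def test_boundary_is_strict(self):
        assert not classify_step(1.0, 1.16, StepRule(0.16))

    def test_threshold_is_relative(self):
        assert classify_step(2.0, 2.40, StepRule(0.16))
        assert not classify_step(2.0, 2.32, StepRule(0.16))

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(ValueError):
            classify_step(0.0, 1.0)


class TestAccessibility:
    def test_multiplicative_landscape_fully_accessible(self):
        land = multiplicative_landscape({"A1V": 1.5, "C2W": 1.5, "D3Y": 1.5, "E4F": 1.5})
        report = count_accessible(land)
        assert report.accessible_count == report.total == math.factorial(4)

    def test_toy_matches_brute_force(self, toy3):
        report = count_accessible(toy3, list_accessible=True)
        assert report.accessible_count == brute_force_accessible(toy3)
        assert len(report.accessible_paths) == report.accessible_count
        assert report.accessible_fraction == report.accessible_count / 6

    @pytest.mark.parametrize("n,seed", [(3, 0), (4, 1), (5, 2)])
    def test_random_landscapes_match_brute_force(self, n, seed):
        spec = LandscapeSpec(
            substitutions=tuple(f"A{i + 1}V" for i in range(n)),
            log_effects=tuple(0.3 * math.sin(i * 2.7 + seed) for i in range(n)),
            replicates=3,
            cv=0.2,
            seed=seed,
        )
        land, _ = simulate_fitness_landscape(spec)
        assert count_accessible(land).accessible_count == brute_force_accessible(land)

    def test_incomplete_landscape_rejected_by_default(self):
        land = make_landscape({"A1V": 0, "C2W": 0}, {"A1V": 2.0, "C2W": 2.0})
        with pytest.raises(ValueError, match="incomplete"):
            count_accessible(land)
        with pytest.warns(UserWarning, match="incomplete"):
            report = count_accessible(land, allow_incomplete=True)
        assert report.skipped == 2  # both orderings hit the missing double

    def test_gated_landscape_paths_start_with_gate(self):
        spec = LandscapeSpec(
            substitutions=tuple(f"A{i + 1}V" for i in range(5)),
            log_effects=(0.3, 0.3, 0.3, 0.3, 0.5),
            gate="A5V",
            masking=0.0,
            replicates=1,
            cv=0.0,
            seed=0,
        )
        land, _ = simulate_fitness_landscape(spec)
        report = count_accessible(land, list_accessible=True)
        assert report.accessible_count == math.factorial(4)  # gate first, rest free
        assert all(str(path[0]) == "A5V" for path in report.accessible_paths)


class TestGreedyPath:
    def test_multiplicative_orders_by_effect_size(self):
        land = multiplicative_landscape({"A1V": 1.2, "C2W": 2.0, "D3Y": 1.5})
        path = greedy_plausible_path(land)
        assert [str(s) for s in path] == ["C2W", "D3Y", "A1V"]

    def test_least_deleterious_first_step_when_nothing_improves(self):
        folds = {
            "WT": 1.0, "A1V": 0.7, "C2W": 0.9, "A1V+C2W": 3.0,
        }
        land = make_landscape({"A1V": 0, "C2W": 0}, folds)
        path = greedy_plausible_path(land)
        assert [str(s) for s in path] == ["C2W", "A1V"]

    def test_ties_break_to_lowest_position(self):
        land = multiplicative_landscape({"A1V": 1.5, "C2W": 1.5})
        assert [str(s) for s in greedy_plausible_path(land)] == ["A1V", "C2W"]

    def test_row_order_invariance(self, toy3):
        # rebuild the same landscape with shuffled insertion order
        shuffled = make_landscape(
            {"D3Y": 0, "A1V": 0, "C2W": 0},
            {
                "A1V+C2W+D3Y": 4.0, "WT": 1.0, "C2W+D3Y": 0.9, "A1V": 1.5,
                "D3Y": 1.1, "A1V+D3Y": 1.9, "C2W": 0.8, "A1V+C2W": 2.5,
            },
        )
        assert greedy_plausible_path(shuffled) == greedy_plausible_path(toy3)


class TestNetwork:
    @pytest.fixture
    def net3(self, toy3):
        greedy = greedy_plausible_path(toy3)
        return build_network(toy3, greedy=greedy)

    def test_node_and_edge_counts(self, net3, toy3):
        n = toy3.n
        assert net3.number_of_nodes() == 2**n
        assert net3.number_of_edges() == n * 2 ** (n - 1)

    def test_greedy_edges_number_n(self, net3, toy3):
        greedy_edges = [e for e in net3.edges(data=True) if e[2]["on_greedy_path"]]
        assert len(greedy_edges) == toy3.n

    def test_edge_attributes_match_step_rule(self, net3, toy3):
        for u, v, attrs in net3.edges(data=True):
            assert attrs["improving"] == classify_step(toy3.mean(u), toy3.mean(v))
            assert attrs["delta"] == pytest.approx(toy3.mean(v) - toy3.mean(u))

    def test_node_attributes_carry_fold_and_layer(self, net3, toy3):
        assert net3.nodes["WT"]["layer"] == 0
        assert net3.nodes["A1V+C2W+D3Y"]["fold"] == 4.0

    def test_foreign_greedy_path_rejected(self, toy3):
        with pytest.raises(ValueError, match="permutation"):
            build_network(toy3, greedy=(Substitution.parse("S41Y"),))

    def test_seven_substitution_network_size(self):
        land = multiplicative_landscape({f"A{i + 1}V": 1.5 for i in range(7)})
        net = build_network(land)
        assert net.number_of_nodes() == 128
        assert net.number_of_edges() == 448


class TestExport:
    def test_graphml_parses_and_preserves_counts(self, toy3, tmp_path):
        net = build_network(toy3, greedy=greedy_plausible_path(toy3))
        p = tmp_path / "net.graphml"
        export_network(net, "graphml", p)
        ET.parse(p)  # well-formed XML
        back = nx.read_graphml(p)
        assert back.number_of_nodes() == net.number_of_nodes()
        assert back.number_of_edges() == net.number_of_edges()
        assert back.nodes["WT"]["layer"] == 0

    def test_edge_csv_round_trip_preserves_attributes(self, toy3, tmp_path):
        net = build_network(toy3, greedy=greedy_plausible_path(toy3))
        p = tmp_path / "net.csv"
        export_network(net, "edge-csv", p)
        back = read_edge_csv(p)
        assert set(back.edges) == set(net.edges)
        for u, v in net.edges:
            assert back[u][v]["improving"] == net[u][v]["improving"]
            assert back[u][v]["on_greedy_path"] == net[u][v]["on_greedy_path"]
            assert back[u][v]["delta"] == pytest.approx(net[u][v]["delta"])

    def test_dot_has_one_statement_per_node(self, toy3, tmp_path):
        net = build_network(toy3, greedy=greedy_plausible_path(toy3))
        p = tmp_path / "net.dot"
        export_network(net, "dot", p)
        lines = p.read_text().splitlines()
        node_lines = [l for l in lines if "[layer=" in l]
        assert len(node_lines) == net.number_of_nodes()

    def test_unknown_format_rejected(self, toy3, tmp_path):
        net = build_network(toy3)
        with pytest.raises(ValueError, match="format"):
            export_network(net, "gexf", tmp_path / "x")
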