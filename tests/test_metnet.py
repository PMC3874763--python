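"""SBML loading, currency removal, connectivity, shortest paths, sub-networks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from metcorrnet.corrstats import DifferentialCorrelation
from metcorrnet.metnet import (
    MetabolicNetwork,
    Reaction,
    Species,
    assemble_subnetwork,
    compare_networks,
    connectivity_graph,
    decompose,
    default_currency,
    export_network,
    import_network,
    load_sbml,
    map_pairs,
    metabolite_graph,
    paths_table,
    remove_currency,
    shortest_path,
    write_sbml,
)
from metcorrnet.profiles import MetaboliteAnnotation
from metcorrnet.synthetic import simulate_network


def diff_record(a, b):
    return DifferentialCorrelation(
        pair=(a, b), r_a=0.9, r_b=0.0, n_a=30, n_b=30,
        passes_magnitude=True, passes_difference=True, significant=True,
    )


def brute_force_edges(net):
    """Reaction-by-reaction enumeration of conversion edges (oracle).

    Loops over every reaction and every (consumed, produced) pair of
    participants — no matrix algebra shared with the implementation.
    """
    edges = set()
    for rxn in net.reactions:
        for (a, _), (b, _) in itertools.product(rxn.consumed, rxn.produced):
            if a != b:
                edges.add(frozenset((a, b)))
    return edges


class TestSBML:
    def test_round_trip(self, two_step_network, tmp_path):
        path = tmp_path / "net.xml"
        write_sbml(two_step_network, path)
        back = load_sbml(path)
        assert [s.id for s in back.species] == ["A", "B", "C", "D"]
        assert back.reactions[0].consumed == (("A", 1.0), ("B", 1.0))
        assert back.reactions[1].produced == (("D", 2.0),)

    def test_stoichiometric_coefficients_preserved(self, tmp_path):
        net = MetabolicNetwork(
            species=[Species("A"), Species("B")],
            reactions=[Reaction("r", consumed=(("A", 2.0),), produced=(("B", 1.0),))],
        )
        write_sbml(net, tmp_path / "n.xml")
        back = load_sbml(tmp_path / "n.xml")
        assert back.reactions[0].consumed == (("A", 2.0),)

    def test_malformed_xml_reports_position(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><model><unclosed></model></sbml>")
        with pytest.raises(ValueError, match="line"):
            load_sbml(path)

    def test_unknown_species_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            MetabolicNetwork(
                species=[Species("A")],
                reactions=[Reaction("r", consumed=(("A", 1.0),), produced=(("Z", 1.0),))],
            )

    def test_single_compartment_suffix_stripped(self, tmp_path):
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
  <model id="m">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies>
      <species id="A_c" name="metA" compartment="c"/>
      <species id="B_c" name="metB" compartment="c"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="true">
        <listOfReactants><speciesReference species="A_c"/></listOfReactants>
        <listOfProducts><speciesReference species="B_c"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""
        path = tmp_path / "l2.xml"
        path.write_text(text)
        net = load_sbml(path)
        assert net.species_ids == ["A", "B"]
        net_raw = load_sbml(path, strip_compartment=False)
        assert net_raw.species_ids == ["A_c", "B_c"]


class TestCurrencyRemoval:
    def test_network_without_currency_unchanged(self, two_step_network):
        out = remove_currency(two_step_network)
        assert out.species == two_step_network.species
        assert out.reactions == two_step_network.reactions

    def test_cofactors_stripped_from_reaction(self):
        net = MetabolicNetwork(
            species=[Species("A"), Species("B"), Species("ATP"), Species("ADP")],
            reactions=[
                Reaction("r", consumed=(("A", 1.0), ("ATP", 1.0)), produced=(("B", 1.0), ("ADP", 1.0)))
            ],
        )
        out = remove_currency(net, ["ATP", "ADP"])
        assert out.species_ids == ["A", "B"]
        assert out.reactions[0].consumed == (("A", 1.0),)
        assert out.reactions[0].produced == (("B", 1.0),)

    def test_pure_currency_reaction_dropped(self):
        net = MetabolicNetwork(
            species=[Species("ATP"), Species("ADP")],
            reactions=[Reaction("r", consumed=(("ATP", 1.0),), produced=(("ADP", 1.0),))],
        )
        out = remove_currency(net, ["ATP", "ADP"])
        assert out.reactions == []

    def test_matching_by_name_and_kegg(self):
        net = MetabolicNetwork(
            species=[
                Species("x1", name="Water"),
                Species("x2", kegg="C00002"),  # ATP by KEGG annotation
                Species("x3", name="glucose"),
            ],
            reactions=[],
        )
        out = remove_currency(net)  # shipped default table
        assert out.species_ids == ["x3"]

    def test_default_table_covers_published_cofactors(self):
        names = {row["name"] for row in default_currency()}
        assert {"ATP", "NADPH", "H2O", "CO2", "orthophosphate", "hydrogen"} <= names
        assert len(names) == 18

    def test_purging_never_creates_adjacency(self):
        """Edges among non-currency species survive purging unchanged except
        those that existed only through a currency intermediate."""
        rng = np.random.default_rng(5)
        for seed in range(20):
            net, _ = simulate_network(8, 14, seed=seed)
            doomed = [net.species[int(rng.integers(8))].id]
            purged = remove_currency(net, doomed)
            kept_edges = brute_force_edges(purged)
            full_edges = {
                e for e in brute_force_edges(net) if not (set(e) & set(doomed))
            }
            assert kept_edges <= full_edges


class TestDecompose:
    def test_single_reaction(self, two_step_network):
        d = decompose(two_step_network)
        assert d.consumed.shape == (4, 2)
        # A+B -> C ; C -> 2D
        nz_consumed = {(d.species_ids[i], d.reaction_ids[j]): d.consumed[i, j]
                       for i, j in zip(*np.nonzero(d.consumed))}
        nz_produced = {(d.species_ids[i], d.reaction_ids[j]): d.produced[i, j]
                       for i, j in zip(*np.nonzero(d.produced))}
        assert nz_consumed == {("A", "r1"): 1.0, ("B", "r1"): 1.0, ("C", "r2"): 1.0}
        assert nz_produced == {("C", "r1"): 1.0, ("D", "r2"): 2.0}

    def test_empty_network(self):
        d = decompose(MetabolicNetwork(species=[], reactions=[]))
        assert d.consumed.size == 0 and d.produced.size == 0


class TestConnectivity:
    def test_single_conversion_edge(self):
        net = MetabolicNetwork(
            species=[Species("A"), Species("B")],
            reactions=[Reaction("r", consumed=(("A", 1.0),), produced=(("B", 1.0),))],
        )
        g = connectivity_graph(decompose(net))
        assert set(map(frozenset, g.edges)) == {frozenset(("A", "B"))}
        assert g.edges["A", "B"]["reactions"] == {"r"}

    def test_two_step_toy(self, two_step_network):
        g = connectivity_graph(decompose(two_step_network))
        expected = {frozenset(p) for p in (("A", "C"), ("B", "C"), ("C", "D"))}
        assert set(map(frozenset, g.edges)) == expected
        assert not g.has_edge("A", "B")  # co-substrates are not converted

    def test_degenerate_self_conversion_cleared(self):
        net = MetabolicNetwork(
            species=[Species("A")],
            reactions=[Reaction("r", consumed=(("A", 1.0),), produced=(("A", 1.0),))],
        )
        g = connectivity_graph(decompose(net))
        assert g.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        """Matrix construction equals direct reaction-pair enumeration on
        random toy networks (<= 15 species)."""
        rng = np.random.default_rng(seed)
        n_sp = int(rng.integers(4, 16))
        net, _ = simulate_network(n_sp, n_sp + int(rng.integers(1, 10)),
                                  max_participants=3, seed=seed)
        g = connectivity_graph(decompose(net))
        assert set(map(frozenset, g.edges)) == brute_force_edges(net)


class TestShortestPath:
    def graph(self, net):
        return connectivity_graph(decompose(net))

    def test_adjacent_nodes(self, two_step_network):
        res = shortest_path(self.graph(two_step_network), "A", "C")
        assert res.status == "found" and res.length == 1

    def test_two_step_path_with_reactions(self, two_step_network):
        res = shortest_path(self.graph(two_step_network), "A", "D")
        assert res.nodes == ("A", "C", "D")
        assert res.length == 2
        assert res.step_reactions == (frozenset({"r1"}), frozenset({"r2"}))

    def test_absent_endpoints(self, two_step_network):
        g = self.graph(two_step_network)
        assert shortest_path(g, "Z", "D").status == "source_absent"
        assert shortest_path(g, "A", "Z").status == "target_absent"

    def test_disconnected(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        assert shortest_path(g, "A", "B").status == "disconnected"

    def test_deterministic_tie_breaking(self):
        # two length-2 routes A-B-D and A-C-D: lexicographic expansion picks B
        g = nx.Graph()
        for e in (("A", "C"), ("A", "B"), ("C", "D"), ("B", "D")):
            g.add_edge(*e, reactions=set())
        assert shortest_path(g, "A", "D").nodes == ("A", "B", "D")

    @pytest.mark.parametrize("seed", range(25))
    def test_length_matches_exhaustive_search(self, seed):
        """BFS path lengths equal an exhaustive simple-path search on random
        graphs of <= 12 nodes."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        nx.set_edge_attributes(g, set(), "reactions")
        nodes = sorted(g)
        for a, b in itertools.combinations(nodes, 2):
            res = shortest_path(g, a, b)
            # oracle: brute-force enumeration of all simple paths
            simple = [len(p) - 1 for p in nx.all_simple_paths(g, a, b)]
            if not simple:
                assert res.status == "disconnected"
            else:
                assert res.status == "found"
                assert res.length == min(simple)


class TestMapPairs:
    @pytest.fixture
    def setting(self):
        net, _ = simulate_network(6, 9, seed=11)
        g = metabolite_graph(net, currency=False)
        ann = {
            "peak1": MetaboliteAnnotation("peak1", "one", ("C90001",)),
            "peak2": MetaboliteAnnotation("peak2", "two", ("C90002",)),
            "multi": MetaboliteAnnotation("multi", "iso", ("C90005", "C90006")),
            "orphan": MetaboliteAnnotation("orphan", "none", ()),
        }
        return g, ann

    def test_single_candidate_pair_found(self, setting):
        g, ann = setting
        (res,) = map_pairs(g, [diff_record("peak1", "peak2")], ann)
        assert res.status == "found"
        assert res.source_id == "S01" and res.target_id == "S02"

    def test_multi_identity_keeps_shortest(self, setting):
        g, ann = setting
        (res,) = map_pairs(g, [diff_record("peak1", "multi")], ann)
        assert res.status == "found"
        lengths = {
            cand: shortest_path(g, "S01", cand).length for cand in ("S05", "S06")
        }
        assert res.length == min(lengths.values())
        assert res.target_id in {c for c, l in lengths.items() if l == res.length}

    def test_unannotated_endpoint_reported(self, setting):
        g, ann = setting
        (res,) = map_pairs(g, [diff_record("orphan", "peak2")], ann)
        assert res.status == "source_absent"
        (res2,) = map_pairs(g, [diff_record("peak1", "orphan")], ann)
        assert res2.status == "target_absent"

    def test_first_listed_policy(self, setting):
        g, ann = setting
        (res,) = map_pairs(g, [diff_record("peak1", "multi")], ann, policy="first")
        assert res.status == "found"
        assert res.target_id == "S05"

    def test_no_pair_dropped_silently(self, setting):
        g, ann = setting
        diffs = [diff_record("peak1", "peak2"), diff_record("orphan", "peak2")]
        assert len(map_pairs(g, diffs, ann)) == len(diffs)

    def test_paths_table_columns(self, setting):
        g, ann = setting
        table = paths_table(map_pairs(g, [diff_record("peak1", "peak2")], ann))
        assert list(table.columns) == [
            "metabolite_a", "metabolite_b", "status", "length", "nodes", "reactions",
        ]


class TestSubnetworks:
    def path(self, nodes, rxns=None):
        from metcorrnet.metnet import PathResult

        steps = tuple(frozenset(r) for r in (rxns or [set()] * (len(nodes) - 1)))
        return PathResult(pair=(nodes[0], nodes[-1]), status="found",
                          nodes=tuple(nodes), step_reactions=steps)

    def test_single_path(self):
        g = assemble_subnetwork([self.path(["A", "C", "D"])])
        assert set(g) == {"A", "C", "D"} and g.number_of_edges() == 2

    def test_shared_node_counted_once(self):
        g = assemble_subnetwork([self.path(["A", "C"]), self.path(["B", "C"])])
        assert set(g) == {"A", "B", "C"} and g.number_of_edges() == 2

    def test_overlapping_edges_merge_annotations(self):
        g = assemble_subnetwork(
            [self.path(["A", "C"], [{"r1"}]), self.path(["A", "C"], [{"r2"}])]
        )
        assert g.edges["A", "C"]["reactions"] == {"r1", "r2"}

    def test_order_independent_and_idempotent(self):
        paths = [self.path(["A", "C", "D"]), self.path(["B", "C"]), self.path(["D", "E"])]
        g1 = assemble_subnetwork(paths)
        g2 = assemble_subnetwork(list(reversed(paths)))
        g3 = assemble_subnetwork(paths + paths)
        for g in (g2, g3):
            assert set(g) == set(g1)
            assert set(map(frozenset, g.edges)) == set(map(frozenset, g1.edges))


class TestCompareNetworks:
    def graph(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            g.add_edge(*e, reactions=set())
        return g

    def test_disjoint(self):
        comp = compare_networks(self.graph([("A", "B")]), self.graph([("X", "Y")]))
        assert comp.node_counts() == {"A_only": 2, "B_only": 2, "shared": 0}

    def test_identical(self):
        g = self.graph([("A", "B"), ("B", "C")])
        comp = compare_networks(g, g.copy())
        assert comp.node_counts() == {"A_only": 0, "B_only": 0, "shared": 3}

    def test_partial_overlap_partition(self):
        comp = compare_networks(
            self.graph([("M", "P"), ("P", "G")]), self.graph([("P", "G"), ("G", "F")])
        )
        assert comp.nodes_with_origin("shared") == {"P", "G"}
        assert comp.nodes_with_origin("A_only") == {"M"}
        assert comp.nodes_with_origin("B_only") == {"F"}
        assert comp.graph.edges["P", "G"]["origin"] == "shared"
        assert comp.graph.edges["M", "P"]["origin"] == "A_only"

    def test_origins_partition_union_exactly(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ga = nx.gnp_random_graph(8, 0.3, seed=seed)
            gb = nx.gnp_random_graph(8, 0.3, seed=seed + 100)
            gb = nx.relabel_nodes(gb, {i: i + 4 for i in range(8)})
            comp = compare_networks(ga, gb)
            counts = comp.node_counts()
            assert sum(counts.values()) == len(set(ga) | set(gb))
            assert comp.nodes_with_origin("shared") == set(ga) & set(gb)


class TestExport:
    def test_graphml_round_trip(self):
        g = assemble_subnetwork([])
        g.add_edge("A", "C", reactions={"r1", "r2"})
        g.add_edge("C", "D", reactions={"r2"})
        comp = compare_networks(g, g.copy())
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as td:
            path = pathlib.Path(td) / "net.graphml"
            export_network(comp, path, "graphml")
            back = import_network(path)
        assert set(back) == set(comp.graph)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, comp.graph.edges))
        assert back.edges["A", "C"]["reactions"] == {"r1", "r2"}
        assert back.nodes["A"]["origin"] == "shared"

    def test_sif_lines(self, tmp_path):
        g = nx.Graph([("A", "C"), ("C", "D")])
        export_network(g, tmp_path / "net.sif", "sif")
        lines = (tmp_path / "net.sif").read_text().splitlines()
        assert lines == ["A\tcc\tC", "C\tcc\tD"]
        back = import_network(tmp_path / "net.sif", "sif")
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(nx.Graph(), tmp_path / "x", "dot")
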