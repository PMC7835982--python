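"""BioGRID parsing, network construction, node classification, hub selection."""

import io

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from secretonet.interactome import (
    apply_id_mapping,
    build_cm_network,
    candidates_frame,
    classify_nodes,
    expand_to_panel,
    export_network,
    map_identifiers,
    parse_biogrid_tab,
    select_mediators,
    write_biogrid_tab,
)


def tab2_line(n, a, b, org_a="9606", org_b="9606", system_type="physical"):
    row = ["-"] * 24
    row[0] = str(n)
    row[7], row[8] = a, b
    row[11] = "Two-hybrid"
    row[12] = system_type
    row[14] = str(30000000 + n)
    row[15], row[16] = org_a, org_b
    row[23] = "TEST"
    return "\t".join(row)


HEADER = "#BioGRID Interaction ID" + "\tcol" * 23


@pytest.fixture()
def triangle_text():
    return "\n".join(
        [HEADER, tab2_line(1, "A", "B"), tab2_line(2, "B", "C"), tab2_line(3, "C", "A")]
    )


class TestParser:
    def test_three_wellformed_lines_give_three_records(self, triangle_text):
        records = parse_biogrid_tab(triangle_text)
        assert len(records) == 3

    def test_self_interaction_dropped(self):
        text = "\n".join([HEADER, tab2_line(1, "A", "A"), tab2_line(2, "A", "B")])
        records = parse_biogrid_tab(text)
        assert len(records) == 1

    def test_malformed_line_skipped(self):
        text = "\n".join([HEADER, "garbage\tline", tab2_line(1, "A", "B")])
        assert len(parse_biogrid_tab(text)) == 1

    def test_taxon_filter(self):
        text = "\n".join(
            [HEADER, tab2_line(1, "A", "B"),
             tab2_line(2, "C", "D", org_a="10090", org_b="10090")]
        )
        records = parse_biogrid_tab(text, taxon_filter=9606)
        assert len(records) == 1
        assert records.loc[0, "interactor_a"] == "A"

    def test_system_type_filter(self):
        text = "\n".join(
            [HEADER, tab2_line(1, "A", "B"),
             tab2_line(2, "C", "D", system_type="genetic")]
        )
        assert len(parse_biogrid_tab(text, system_type="physical")) == 1

    def test_zero_parseable_lines_is_format_error(self):
        with pytest.raises(ValueError, match="parseable"):
            parse_biogrid_tab(HEADER + "\nnot\ta\trecord")

    def test_round_trip(self, triangle_text, tmp_path):
        records = parse_biogrid_tab(triangle_text)
        path = tmp_path / "out.tab2.txt"
        write_biogrid_tab(records, path)
        pd.testing.assert_frame_equal(parse_biogrid_tab(path), records)

    def test_reads_file_like_stream(self, triangle_text):
        assert len(parse_biogrid_tab(io.StringIO(triangle_text))) == 3


class TestMapping:
    def test_empty_mapping_is_identity(self, triangle_text):
        records = parse_biogrid_tab(triangle_text)
        mapping = pd.DataFrame(columns=["accession", "symbol"])
        out, unmapped = map_identifiers(records, mapping)
        pd.testing.assert_frame_equal(out, records)
        assert set(unmapped) == {"A", "B", "C"}

    def test_known_pair_remapped(self, triangle_text):
        records = parse_biogrid_tab(triangle_text)
        mapping = pd.DataFrame({"accession": ["A"], "symbol": ["ALPHA"]})
        out, _ = map_identifiers(records, mapping)
        assert set(out["interactor_a"]) | set(out["interactor_b"]) >= {"ALPHA"}
        assert "A" not in set(out["interactor_a"]) | set(out["interactor_b"])

    def test_ambiguous_mapping_resolved_lexicographically(self):
        mapping = pd.DataFrame(
            {"accession": ["A", "A"], "symbol": ["ZZZ", "BBB"]}
        )
        out1, _ = apply_id_mapping(["A"], mapping)
        out2, _ = apply_id_mapping(["A"], mapping)
        assert out1 == out2 == ["BBB"]


class TestNetworkConstruction:
    def test_triangle_of_catalog_proteins(self, triangle_text):
        records = parse_biogrid_tab(triangle_text)
        g = build_cm_network(records, {"A", "B", "C"})
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 3
        assert all(d == 2 for _, d in g.degree)

    def test_edge_needs_both_endpoints_in_catalog(self, triangle_text):
        records = parse_biogrid_tab(triangle_text)
        g = build_cm_network(records, {"A", "B"})
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_duplicate_and_reversed_lines_collapse(self):
        text = "\n".join(
            [HEADER, tab2_line(1, "A", "B"), tab2_line(2, "B", "A"),
             tab2_line(3, "A", "B")]
        )
        g = build_cm_network(parse_biogrid_tab(text), {"A", "B"})
        assert g.number_of_edges() == 1

    def test_empty_catalog_gives_empty_graph(self, triangle_text):
        g = build_cm_network(parse_biogrid_tab(triangle_text), set())
        assert g.number_of_nodes() == 0


class TestPanelExpansion:
    @pytest.fixture()
    def base(self, triangle_text):
        extra = "\n".join(
            [triangle_text,
             tab2_line(4, "A", "IL6"), tab2_line(5, "A", "CCL2"),
             tab2_line(6, "B", "IL6"), tab2_line(7, "IL6", "CCL2")]
        )
        records = parse_biogrid_tab(extra)
        graph = build_cm_network(records, {"A", "B", "C"})
        return graph, records

    def test_empty_differential_set_changes_nothing(self, base):
        graph, records = base
        out = expand_to_panel(graph, records, set(), {})
        assert set(out.nodes) == set(graph.nodes)
        assert all(out.nodes[n]["measured_degree"] == 0 for n in out.nodes)

    def test_measured_degree_counts_distinct_differential_factors(self, base):
        graph, records = base
        out = expand_to_panel(
            graph, records, {"IL6", "CCL2"},
            {"IL6": {"cytokine"}, "CCL2": {"cytokine"}},
        )
        assert out.nodes["A"]["measured_degree"] == 2
        assert out.nodes["B"]["measured_degree"] == 1
        assert out.nodes["C"]["measured_degree"] == 0

    def test_panel_panel_edges_excluded_by_default(self, base):
        graph, records = base
        out = expand_to_panel(
            graph, records, {"IL6", "CCL2"},
            {"IL6": {"cytokine"}, "CCL2": {"cytokine"}},
        )
        assert not out.has_edge("IL6", "CCL2")
        opt = expand_to_panel(
            graph, records, {"IL6", "CCL2"},
            {"IL6": {"cytokine"}, "CCL2": {"cytokine"}},
            include_panel_panel_edges=True,
        )
        assert opt.has_edge("IL6", "CCL2")

    def test_idempotence(self, base):
        graph, records = base
        diff = {"IL6", "CCL2"}
        panel = {"IL6": {"cytokine"}, "CCL2": {"cytokine"}}
        once = expand_to_panel(graph, records, diff, panel)
        twice = expand_to_panel(once, records, diff, panel)
        assert nx.utils.graphs_equal(once, twice)

    def test_enlarging_differential_set_is_monotone(self, base):
        graph, records = base
        small = expand_to_panel(graph, records, {"IL6"}, {"IL6": {"cytokine"}})
        large = expand_to_panel(
            graph, records, {"IL6", "CCL2"},
            {"IL6": {"cytokine"}, "CCL2": {"cytokine"}},
        )
        for node in small.nodes:
            assert (
                large.nodes[node]["measured_degree"]
                >= small.nodes[node]["measured_degree"]
            )


class TestClassification:
    def test_classes_partition_the_nodes(self, triangle_text):
        records = parse_biogrid_tab(
            "\n".join([triangle_text, tab2_line(4, "A", "IL6")])
        )
        graph = build_cm_network(records, {"A", "B", "C"})
        graph = expand_to_panel(graph, records, {"IL6"}, {"IL6": {"cytokine"}})
        presence = {"A": "unique_cm", "B": "shared", "C": "unique_cm"}
        graph = classify_nodes(graph, presence, {"IL6": {"cytokine"}})
        classes = [graph.nodes[n]["presence_class"] for n in graph.nodes]
        assert sorted(classes) == ["panel_only", "shared", "unique_cm", "unique_cm"]
        datasets = [graph.nodes[n]["dataset_class"] for n in graph.nodes]
        assert sorted(datasets) == ["cytokine", "neither", "neither", "neither"]

    def test_factor_in_both_panels_is_purple(self, triangle_text):
        records = parse_biogrid_tab(
            "\n".join([triangle_text, tab2_line(4, "A", "MRC1")])
        )
        graph = build_cm_network(records, {"A", "B", "C"})
        graph = expand_to_panel(
            graph, records, {"MRC1"}, {"MRC1": {"pcr", "cytokine"}}
        )
        graph = classify_nodes(
            graph, {"A": "unique_cm", "B": "shared", "C": "shared"},
            {"MRC1": {"pcr", "cytokine"}},
        )
        assert graph.nodes["MRC1"]["dataset_class"] == "both"
        assert graph.nodes["MRC1"]["border_color"] == "purple"
        assert graph.nodes["MRC1"]["shape"] == "circle"

    def test_contradictory_node_raises(self, triangle_text):
        graph = build_cm_network(parse_biogrid_tab(triangle_text), {"A", "B", "C"})
        graph = expand_to_panel(graph, parse_biogrid_tab(triangle_text), set(), {})
        with pytest.raises(ValueError, match="C"):
            classify_nodes(graph, {"A": "unique_cm", "B": "shared"}, {})


def brute_force_selection(graph, panel_membership, differential, min_degree):
    """Per-node recount of differential neighbours against the rule."""
    selected = set()
    for node in graph.nodes:
        eligible = (
            graph.nodes[node].get("presence_class") == "unique_cm"
            or node in panel_membership
        )
        count = sum(1 for nbr in graph.neighbors(node) if nbr in differential)
        if eligible and count >= min_degree:
            selected.add(node)
    return selected


class TestSelection:
    def build_classified(self, n_proteins, n_factors, rng):
        proteins = [f"P{i}" for i in range(n_proteins)]
        factors = [f"F{i}" for i in range(n_factors)]
        graph = nx.Graph()
        graph.add_nodes_from(proteins)
        for _ in range(rng.integers(0, 3 * n_proteins + 1)):
            a, b = rng.choice(proteins, 2, replace=False)
            graph.add_edge(str(a), str(b))
        for p in proteins:
            for f in factors:
                if rng.random() < 0.25:
                    graph.add_edge(p, f)
        differential = set(factors)
        panel = {f: {"cytokine"} for f in factors}
        presence = {
            p: ("unique_cm" if rng.random() < 0.5 else "shared") for p in proteins
        }
        records = pd.DataFrame(
            [(a, b, "9606", "9606", "physical", "T", "1") for a, b in graph.edges],
            columns=["interactor_a", "interactor_b", "organism_a", "organism_b",
                     "system_type", "source", "pubmed"],
        )
        graph = expand_to_panel(graph, records, differential, panel)
        graph = classify_nodes(graph, presence, panel)
        return graph, panel, differential

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            graph, panel, differential = self.build_classified(
                int(rng.integers(2, 30)), int(rng.integers(1, 12)), rng
            )
            for min_degree in (1, 3, 6):
                got = {
                    c.protein_id
                    for c in select_mediators(graph, panel, min_degree)
                    if c.selected
                }
                assert got == brute_force_selection(
                    graph, panel, differential, min_degree
                )

    def test_more_than_five_is_strict(self):
        graph = nx.Graph()
        factors = [f"F{i}" for i in range(6)]
        panel = {f: {"pcr"} for f in factors}
        for f in factors[:5]:
            graph.add_edge("P5", f)
        for f in factors:
            graph.add_edge("P6", f)
        records = pd.DataFrame(
            [(a, b, "9606", "9606", "physical", "T", "1") for a, b in graph.edges],
            columns=["interactor_a", "interactor_b", "organism_a", "organism_b",
                     "system_type", "source", "pubmed"],
        )
        graph = expand_to_panel(graph, records, set(factors), panel)
        graph = classify_nodes(
            graph, {"P5": "unique_cm", "P6": "unique_cm"}, panel
        )
        by_id = {c.protein_id: c for c in select_mediators(graph, panel, 6)}
        assert not by_id["P5"].selected   # exactly five is not "more than five"
        assert by_id["P6"].selected
        assert len(by_id["P6"].interacting_factors) == by_id["P6"].measured_degree

    def test_empty_graph_gives_empty_table(self):
        assert select_mediators(nx.Graph(), {}, 6) == []

    def test_ranking_degree_desc_then_lexicographic(self):
        graph = nx.Graph()
        panel = {f"F{i}": {"pcr"} for i in range(3)}
        for p in ("PB", "PA"):
            for f in panel:
                graph.add_edge(p, f)
        records = pd.DataFrame(
            [(a, b, "9606", "9606", "physical", "T", "1") for a, b in graph.edges],
            columns=["interactor_a", "interactor_b", "organism_a", "organism_b",
                     "system_type", "source", "pubmed"],
        )
        graph = expand_to_panel(graph, records, set(panel), panel)
        graph = classify_nodes(
            graph, {"PA": "unique_cm", "PB": "unique_cm"}, panel
        )
        ids = [c.protein_id for c in select_mediators(graph, panel, 6)]
        assert ids[:2] == ["PA", "PB"]


class TestExport:
    def test_graphml_round_trip_preserves_structure(self, triangle_text, tmp_path):
        records = parse_biogrid_tab(
            "\n".join([triangle_text, tab2_line(4, "A", "IL6")])
        )
        graph = build_cm_network(records, {"A", "B", "C"})
        graph = expand_to_panel(graph, records, {"IL6"}, {"IL6": {"cytokine"}})
        graph = classify_nodes(
            graph, {"A": "unique_cm", "B": "shared", "C": "shared"},
            {"IL6": {"cytokine"}},
        )
        candidates = select_mediators(graph, {"IL6": {"cytokine"}}, 6)
        paths = export_network(graph, candidates, tmp_path)
        back = nx.read_graphml(paths["graphml"])
        assert set(back.nodes) == set(graph.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in graph.edges
        }
        for node in graph.nodes:
            for attr in ("presence_class", "dataset_class", "measured_degree"):
                assert back.nodes[node][attr] == graph.nodes[node][attr]
        sif_lines = [
            l for l in paths["sif"].read_text().splitlines() if "interacts" in l
        ]
        assert len(sif_lines) == graph.number_of_edges()
        nodes_tsv = pd.read_csv(paths["nodes"], sep="\t")
        assert len(nodes_tsv) == graph.number_of_nodes()

    def test_empty_graph_exports_valid_documents(self, tmp_path):
        paths = export_network(nx.Graph(), [], tmp_path)
        assert nx.read_graphml(paths["graphml"]).number_of_nodes() == 0
        assert paths["sif"].read_text() == ""
        assert candidates_frame([]).empty
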