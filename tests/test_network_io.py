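import io

import networkx as nx
import pytest

import comorbnet as cn
from comorbnet.network_io import read_comorbid_list


def _tsv(*rows, header="protein_a\tprotein_b\tconfidence"):
    return io.StringIO("\n".join([header, *rows]) + "\n")


class TestReadInteractions:
    def test_row_count_equals_record_count(self):
        records = cn.read_interactions(
            _tsv("P1\tP2\t0.9", "P2\tP3\t0.5", "P1\tP3\t0.73"))
        assert len(records) == 3
        assert records[2].confidence == 0.73

    def test_self_loops_pass_through_the_reader(self):
        records = cn.read_interactions(_tsv("P1\tP1\t0.99"))
        assert records == [cn.ScoredInteraction("P1", "P1", 0.99)]

    def test_comma_dialect_auto_detected(self):
        records = cn.read_interactions(io.StringIO(
            "protein_a,protein_b,confidence\nP1,P2,0.8\n"))
        assert records == [cn.ScoredInteraction("P1", "P2", 0.8)]

    def test_missing_column_error_names_it(self):
        with pytest.raises(cn.FormatError, match="confidence"):
            cn.read_interactions(io.StringIO("protein_a\tprotein_b\nP1\tP2\n"))

    def test_malformed_rows_reported_not_silent(self):
        stream = _tsv("P1\tP2\thigh", "P1\tP3\t1.7", "P4\tP5\t0.8")
        with pytest.warns(UserWarning, match="2 malformed"):
            records = cn.read_interactions(stream)
        assert records == [cn.ScoredInteraction("P4", "P5", 0.8)]

    def test_empty_file_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="empty"):
            assert cn.read_interactions(io.StringIO("")) == []

    def test_custom_column_mapping(self):
        stream = io.StringIO("ida\tidb\tscore\nP1\tP2\t0.9\n")
        records = cn.read_interactions(stream, columns={
            "protein_a": "ida", "protein_b": "idb", "confidence": "score"})
        assert records == [cn.ScoredInteraction("P1", "P2", 0.9)]


class TestBuildNetwork:
    def test_threshold_drops_weak_edges_and_isolated_nodes(self):
        records = [cn.ScoredInteraction("A", "B", 0.9),
                   cn.ScoredInteraction("B", "C", 0.5)]
        graph, report = cn.build_network(records, 0.73)
        assert set(graph.nodes) == {"A", "B"}
        assert graph.number_of_edges() == 1
        assert report.excluded_proteins == {"C"}

    def test_threshold_is_inclusive(self):
        graph, _ = cn.build_network(
            [cn.ScoredInteraction("A", "B", 0.73)], 0.73)
        assert graph.has_edge("A", "B")

    def test_duplicates_collapse_to_max_confidence(self):
        records = [cn.ScoredInteraction("A", "B", 0.8),
                   cn.ScoredInteraction("B", "A", 0.95)]
        graph, _ = cn.build_network(records, 0.73)
        assert graph.number_of_edges() == 1
        assert graph["A"]["B"]["confidence"] == 0.95

    def test_self_loops_removed(self):
        records = [cn.ScoredInteraction("A", "A", 0.99),
                   cn.ScoredInteraction("A", "B", 0.9)]
        graph, _ = cn.build_network(records, 0.73)
        assert not list(nx.selfloop_edges(graph))
        assert set(graph.nodes) == {"A", "B"}

    def test_empty_network_is_an_error(self):
        with pytest.raises(cn.EmptyNetworkError):
            cn.build_network([cn.ScoredInteraction("A", "B", 0.5)], 0.73)

    def test_idempotent_on_its_own_output(self, default_dataset):
        graph, _ = cn.build_network(default_dataset.interactions)
        reserialized = [
            cn.ScoredInteraction(a, b, graph[a][b]["confidence"])
            for a, b in graph.edges]
        graph2, report2 = cn.build_network(reserialized)
        assert set(graph.nodes) == set(graph2.nodes)
        assert set(map(frozenset, graph.edges)) == set(
            map(frozenset, graph2.edges))
        assert report2.excluded_proteins == frozenset()

    def test_counts_match_generator_manifest(self):
        spec = cn.SyntheticSpec(n_background=200, rng_seed=7)
        dataset = cn.generate(spec)
        graph, report = cn.build_network(dataset.interactions)
        assert report.n_retained_proteins == dataset.manifest.expected_nodes
        assert report.n_retained_edges == dataset.manifest.expected_edges
        assert report.n_retained_edges <= report.n_input_records


class TestRoundTrips:
    """Generator-written files re-read losslessly through every reader."""

    def test_interactions(self, tmp_path, default_dataset):
        paths = default_dataset.write(tmp_path)
        records = cn.read_interactions(paths["interactions"])
        assert tuple(records) == default_dataset.interactions

    def test_annotations(self, tmp_path, default_dataset):
        paths = default_dataset.write(tmp_path)
        annotation = cn.read_disease_annotations(paths["annotations"])
        assert sorted(annotation.items()) == sorted(default_dataset.annotations)

    def test_gene_sets(self, tmp_path, default_dataset):
        paths = default_dataset.write(tmp_path)
        pathways = cn.read_gene_sets(paths["pathways"])
        assert {name: set(members) for name, members in pathways.items()} \
            == {k: set(v) for k, v in default_dataset.pathway_sets.items()}

    def test_comorbid_list(self, tmp_path, default_dataset):
        paths = default_dataset.write(tmp_path)
        assert tuple(read_comorbid_list(paths["comorbid"])) \
            == default_dataset.comorbid


class TestReadDiseaseAnnotations:
    def test_forward_and_reverse_maps(self):
        stream = io.StringIO("protein\tdisease\nP1\tmigraine\n"
                             "P2\tmigraine\nP1\tobesity\n")
        annotation = cn.read_disease_annotations(stream)
        assert annotation.proteins_for("migraine") == {"P1", "P2"}
        assert annotation.diseases_for("P1") == {"migraine", "obesity"}

    def test_duplicate_rows_collapse(self):
        stream = io.StringIO("protein\tdisease\n" + "P1\tmigraine\n" * 3)
        annotation = cn.read_disease_annotations(stream)
        assert len(annotation) == 1

    def test_missing_column_error(self):
        with pytest.raises(cn.FormatError, match="disease"):
            cn.read_disease_annotations(io.StringIO("protein\nP1\n"))


class TestReadGeneSets:
    def test_members_deduplicated(self):
        pathways = cn.read_gene_sets(io.StringIO("pw1\tdesc\tA\tB\tA\n"))
        assert pathways.members("pw1") == {"A", "B"}
        assert pathways.description("pw1") == "desc"

    def test_empty_line_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty line"):
            pathways = cn.read_gene_sets(
                io.StringIO("pw1\tdesc\tA\tB\n\npw2\tdesc\tC\tD\n"))
        assert len(pathways) == 2

    def test_short_line_error_carries_line_number(self):
        with pytest.raises(cn.FormatError, match="line 2"):
            cn.read_gene_sets(io.StringIO("pw1\tdesc\tA\npw2\tdesc\n"))


class TestWriteResults:
    def test_all_artifacts_written_and_graphml_annotated(
            self, tmp_path, default_network, default_clusters,
            default_annotation, default_dataset):
        results = cn.enrich_clusters(
            default_clusters, default_annotation, default_network)
        filtered = cn.comorbidity_filter(results, default_dataset.comorbid)
        flagged = {(r.cluster_id, r.disease) for r in filtered}
        import dataclasses
        disease_out = [dataclasses.replace(
            r, comorbid=(r.cluster_id, r.disease) in flagged)
            for r in results]
        files = cn.write_results(tmp_path, default_network, default_clusters,
                                 disease_out, [])
        for path in files.values():
            assert path.exists() and path.stat().st_size > 0
        exported = nx.read_graphml(files["network"])
        assert set(exported.nodes) == set(default_network.nodes)
        shared = {n for n, d in exported.nodes(data=True)
                  if d["shared_protein"]}
        expected = set()
        for r in disease_out:
            if r.significant and r.comorbid:
                expected |= r.shared_proteins
        assert shared == expected
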