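"""Protein inference: graph compilation, projection solve, synthetic graphs."""

import numpy as np
import pytest

from conicopt.generators import oracle_projection
from conicopt.proteomics import (
    GraphValidationError,
    PeptideProteinGraph,
    build_qp,
    gen_synthetic_graph,
    infer_proteins,
    initial_feasible_point,
    read_graph,
    write_graph,
    write_scores,
)


@pytest.fixture
def two_protein_graph() -> PeptideProteinGraph:
    """R1 and R2 share peptide e2; evidence weights w = (1.7, 1.3)."""
    return PeptideProteinGraph(
        ["R1", "R2"], ["e1", "e2", "e3"],
        {("R1", "e1"), ("R1", "e2"), ("R2", "e2"), ("R2", "e3")},
        {"e1": 0.9, "e2": 0.8, "e3": 0.5})


class TestGraphValidation:
    def test_isolated_peptide_rejected(self):
        with pytest.raises(GraphValidationError, match="no protein"):
            PeptideProteinGraph(["R1"], ["e1", "e2"], {("R1", "e1")},
                                {"e1": 0.5, "e2": 0.5})

    def test_score_out_of_range_rejected(self):
        with pytest.raises(GraphValidationError, match="outside"):
            PeptideProteinGraph(["R1"], ["e1"], {("R1", "e1")}, {"e1": 1.5})


class TestBuildQp:
    def test_worked_example_weights_and_constraints(self, two_protein_graph):
        qp = build_qp(two_protein_graph, gamma_fraction=0.9)
        assert np.allclose(qp.w, [1.7, 1.3])
        assert qp.gamma == pytest.approx(1.98)
        assert qp.problem.k == len(qp.proteins) + 1  # evidence + nonnegativity
        A = qp.problem.A.toarray()
        assert np.allclose(A[0], [-1.7, -1.3])
        assert qp.problem.b[0] == pytest.approx(-1.98)
        assert np.allclose(A[1:], -np.eye(2))
        assert np.allclose(qp.problem.z, 0.0)

    def test_zero_evidence_graph(self):
        G = PeptideProteinGraph(["R1"], ["e1"], {("R1", "e1")}, {"e1": 0.0})
        qp = build_qp(G, 0.9)
        table, res = infer_proteins(G, 0.9)
        assert qp.gamma == 0.0
        assert res.status == "optimal"
        assert table["score"].iloc[0] == pytest.approx(0.0)

    def test_single_protein_single_peptide(self):
        G = PeptideProteinGraph(["R"], ["e"], {("R", "e")}, {"e": 1.0})
        table, res = infer_proteins(G, 0.5)
        assert table["score"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_gamma_fraction_bounds(self, two_protein_graph):
        with pytest.raises(GraphValidationError):
            build_qp(two_protein_graph, gamma_fraction=1.0)


class TestInitialPoint:
    def test_all_ones_feasible_on_example(self, two_protein_graph):
        qp = build_qp(two_protein_graph, 0.9)
        x0 = initial_feasible_point(qp)
        assert float(qp.w @ x0) >= qp.gamma

    def test_scaling_branch_engages_for_thin_margin(self):
        # every peptide unique to one protein (degree 1) and a fraction near
        # 1 make the all-ones evidence barely sufficient, forcing the rescale
        G = PeptideProteinGraph(
            ["R1", "R2"], ["e1", "e2"],
            {("R1", "e1"), ("R2", "e2")}, {"e1": 0.9, "e2": 0.8})
        qp = build_qp(G, gamma_fraction=0.999)
        x0 = initial_feasible_point(qp)
        assert np.all(x0 > 1.0)
        assert float(qp.w @ x0) >= 2.0 * qp.gamma - 1e-12


class TestInferProteins:
    def test_worked_example_matches_kkt_closed_form(self, two_protein_graph):
        table, res = infer_proteins(two_protein_graph, 0.9, seed=0)
        w = np.array([1.7, 1.3])
        expected = (1.98 / float(w @ w)) * w
        by_id = table.set_index("protein_id")["score"]
        assert by_id["R1"] == pytest.approx(expected[0], abs=1e-9)
        assert by_id["R2"] == pytest.approx(expected[1], abs=1e-9)
        assert list(table["protein_id"]) == ["R1", "R2"]
        assert res.certificate is not None
        # cross-check against the enumeration oracle
        qp = build_qp(two_protein_graph, 0.9)
        assert res.objective == pytest.approx(
            oracle_projection(qp.problem), abs=1e-9)

    def test_uncovered_protein_scores_zero(self):
        G = PeptideProteinGraph(
            ["Rcov", "Rnone"], ["e1", "e2"],
            {("Rcov", "e1"), ("Rcov", "e2")}, {"e1": 0.9, "e2": 0.7})
        table, _ = infer_proteins(G, 0.9, seed=1)
        by_id = table.set_index("protein_id")["score"]
        assert by_id["Rnone"] == 0.0
        assert by_id["Rcov"] > 0.0

    def test_twin_proteins_share_score(self):
        G = PeptideProteinGraph(
            ["Ra", "Rb"], ["e1", "e2"],
            {("Ra", "e1"), ("Rb", "e1"), ("Ra", "e2"), ("Rb", "e2")},
            {"e1": 0.8, "e2": 0.6})
        table, _ = infer_proteins(G, 0.9, seed=2)
        scores = table["score"].to_numpy()
        assert scores[0] == pytest.approx(scores[1], abs=1e-9)

    def test_norm_monotone_in_gamma_fraction(self, two_protein_graph):
        norms = []
        for frac in (0.3, 0.6, 0.9):
            _, res = infer_proteins(two_protein_graph, frac, seed=0)
            norms.append(res.objective)
        assert norms[0] <= norms[1] + 1e-12 <= norms[2] + 1e-12

    def test_small_synthetic_matches_oracle(self):
        for seed in range(3):
            G = gen_synthetic_graph(8, 25, mean_degree=2.0, seed=seed)
            qp = build_qp(G, 0.9)
            table, res = infer_proteins(G, 0.9, seed=seed)
            assert res.status == "optimal"
            assert res.objective == pytest.approx(
                oracle_projection(qp.problem), abs=1e-6)


class TestSyntheticGraphs:
    def test_construction_guarantees(self):
        G = gen_synthetic_graph(100, 300, mean_degree=2.0, seed=7)
        degree = {e: 0 for e in G.peptides}
        for _, e in G.edges:
            degree[e] += 1
        assert min(degree.values()) >= 1
        assert all(0.0 <= q <= 1.0 for q in G.scores.values())

    def test_mean_degree_one_gives_unique_peptides(self):
        G = gen_synthetic_graph(50, 120, mean_degree=1.0, seed=3)
        degree = {e: 0 for e in G.peptides}
        for _, e in G.edges:
            degree[e] += 1
        assert set(degree.values()) == {1}

    def test_seed_determinism(self):
        a = gen_synthetic_graph(20, 60, 2.0, seed=11)
        b = gen_synthetic_graph(20, 60, 2.0, seed=11)
        assert a.edges == b.edges and a.scores == b.scores

    def test_invalid_sizes_rejected(self):
        with pytest.raises(GraphValidationError):
            gen_synthetic_graph(0, 10)
        with pytest.raises(GraphValidationError):
            gen_synthetic_graph(10, 10, mean_degree=0.5)


class TestTsvIO:
    def test_graph_round_trip(self, two_protein_graph, tmp_path):
        edges = tmp_path / "g.edges.tsv"
        scores = tmp_path / "g.scores.tsv"
        write_graph(two_protein_graph, edges, scores)
        back = read_graph(edges, scores)
        assert back.edges == two_protein_graph.edges
        assert back.scores == pytest.approx(two_protein_graph.scores)

    def test_score_table_written(self, two_protein_graph, tmp_path):
        table, _ = infer_proteins(two_protein_graph, 0.9)
        out = tmp_path / "proteins.tsv"
        write_scores(table, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["protein_id", "score", "rank"]
        assert len(lines) == 3
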