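import io
import json

import numpy as np
import pytest

from comorbnet.downstream import two_group_de
from comorbnet.genesets import GeneSet
from comorbnet.interactome import write_interactome
from comorbnet.proximity import closest_distance
from comorbnet.synthetic import (
    generate_annotations,
    generate_drug_table,
    generate_expression,
    generate_interactome,
    plant_dense_module,
    plant_gene_set_pair,
)

from conftest import geneset


def serialize(g):
    buf = io.StringIO()
    write_interactome(g, buf)
    return buf.getvalue()


class TestGenerateInteractome:
    def test_edge_count_from_growth_rule(self):
        g = generate_interactome(100, 2, seed=0)
        assert g.n_nodes == 100
        assert g.n_edges == 3 + 2 * 97  # clique on 3, then 2 edges per new node

    def test_clique_when_no_growth(self):
        g = generate_interactome(4, 3, seed=0)
        assert g.n_edges == 6 and g.n_nodes == 4

    def test_connected(self):
        import networkx as nx
        g = generate_interactome(500, 3, seed=1)
        assert nx.is_connected(g.graph)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_interactome(3, 3, seed=0)

    def test_deterministic_given_seed(self):
        assert serialize(generate_interactome(200, 3, seed=5)) == \
            serialize(generate_interactome(200, 3, seed=5))
        assert serialize(generate_interactome(200, 3, seed=5)) != \
            serialize(generate_interactome(200, 3, seed=6))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_heavy_tailed_degrees(self, seed):
        g = generate_interactome(5000, 3, seed=seed)
        degrees = np.array(sorted(g.degrees().values()))
        top1pct_max = degrees[-50:].max()
        assert top1pct_max >= 10 * np.median(degrees)


class TestPlantGeneSetPair:
    def test_infeasible_ball_error(self, net2000):
        with pytest.raises(ValueError):
            plant_gene_set_pair(net2000, 1, 1, proximal=True,
                                locality_radius=0, mixing=1.0, seed=0)

    def test_non_proximal_truth_flag(self, net2000):
        a, b, truth = plant_gene_set_pair(net2000, 10, 10, proximal=False, seed=1)
        assert truth.planted_proximal is False
        assert not a.ids & b.ids
        assert a.ids | b.ids <= net2000.nodes

    def test_proximal_truth_and_disjointness(self, net2000):
        a, b, truth = plant_gene_set_pair(net2000, 30, 30, proximal=True,
                                          locality_radius=2, mixing=0.8, seed=2)
        assert truth.planted_proximal and truth.center in net2000.nodes
        assert len(a) == len(b) == 30 and not a.ids & b.ids

    def test_planted_pairs_are_closer_than_random(self, net2000):
        prox_d, rand_d = [], []
        for rep in range(6):
            a, b, _ = plant_gene_set_pair(net2000, 30, 30, proximal=True,
                                          locality_radius=2, mixing=0.8, seed=100 + rep)
            prox_d.append(closest_distance(net2000, a, b))
            a, b, _ = plant_gene_set_pair(net2000, 30, 30, proximal=False, seed=200 + rep)
            rand_d.append(closest_distance(net2000, a, b))
        assert np.mean(prox_d) < np.mean(rand_d)


class TestPlantDenseModule:
    def test_zero_fraction_leaves_graph_unchanged(self):
        g = generate_interactome(300, 3, seed=3)
        before = serialize(g)
        seeds, truth = plant_dense_module(g, 20, 0.0, 5, seed=4)
        assert serialize(g) == before
        assert len(seeds) == 5 and set(seeds.ids) <= set(truth.planted_module_members)

    def test_edge_additions_are_simple_and_internal(self):
        g = generate_interactome(300, 3, seed=5)
        before = {frozenset(e) for e in g.edges()}
        seeds, truth = plant_dense_module(g, 25, 1.5, 5, seed=6)
        after = {frozenset(e) for e in g.edges()}
        new = after - before
        members = set(truth.planted_module_members)
        assert all(len(e) == 2 and set(e) <= members for e in new)
        assert truth.achieved_extra_edge_fraction == pytest.approx(1.5, abs=0.1)

    def test_saturation_records_achieved_fraction(self):
        g = generate_interactome(30, 3, seed=7)
        _, truth = plant_dense_module(g, 5, 50.0, 2, seed=8)
        assert truth.achieved_extra_edge_fraction < 50.0

    def test_parameter_validation(self, net2000):
        with pytest.raises(ValueError):
            plant_dense_module(net2000, 10, 1.0, 0, seed=0)


class TestGenerateAnnotations:
    def test_terms_within_background(self):
        ann, truth = generate_annotations(range(1, 501), 50, (5, 20), seed=9)
        assert all(t.members <= ann.background for t in ann.terms)
        assert len(ann.terms) == 50 and truth.planted_enriched_terms == ()

    def test_planted_terms_share_members_with_query(self):
        query = geneset(*range(1, 31), name="q")
        ann, truth = generate_annotations(
            range(1, 1001), 20, (20, 20), planted_query=query,
            n_planted_terms=5, overlap_fraction=0.8, seed=10)
        assert len(truth.planted_enriched_terms) == 5
        for tid in truth.planted_enriched_terms:
            term = next(t for t in ann.terms if t.id == tid)
            assert len(term.members & query.ids) == 16  # ceil(0.8 * 20)

    def test_zero_overlap_planted_terms_are_null(self):
        query = geneset(*range(1, 31), name="q")
        ann, truth = generate_annotations(
            range(1, 1001), 10, (20, 20), planted_query=query,
            n_planted_terms=3, overlap_fraction=0.0, seed=11)
        for tid in truth.planted_enriched_terms:
            term = next(t for t in ann.terms if t.id == tid)
            assert not term.members & query.ids

    def test_disjoint_mode_partitions(self):
        ann, _ = generate_annotations(range(1, 1001), 10, (100, 100),
                                      seed=12, disjoint=True)
        members = [g for t in ann.terms for g in t.members]
        assert len(members) == len(set(members)) == 1000

    def test_infeasible_overlap_error(self):
        query = geneset(1, 2, name="q")
        with pytest.raises(ValueError):
            generate_annotations(range(1, 101), 5, (20, 20), planted_query=query,
                                 n_planted_terms=1, overlap_fraction=1.0, seed=13)


class TestGenerateExpression:
    def test_matrix_shape_and_labels(self):
        planted = geneset(1, 2, name="p")
        expr, labels, truth = generate_expression(range(1, 21), 10, planted, 1.0, 0.5, seed=14)
        assert expr.shape == (20, 20)
        assert labels.count("control") == labels.count("case") == 10
        assert truth.planted_deg_genes == (1, 2)

    def test_planted_logfc_mean_matches_effect(self):
        planted = geneset(1, name="p")
        fcs = []
        for rep in range(100):
            expr, labels, _ = generate_expression(range(1, 21), 10, planted,
                                                  1.0, 0.5, seed=1000 + rep)
            table = two_group_de(expr, labels, test_group="case")
            fcs.append(float(table.loc[table["gene"] == 1, "log2fc"].iloc[0]))
        assert np.mean(fcs) == pytest.approx(1.0, abs=0.05)

    def test_null_scenario_has_no_shift(self):
        planted = geneset(1, name="p")
        expr, labels, _ = generate_expression(range(1, 51), 10, planted, 0.0, 0.5, seed=15)
        table = two_group_de(expr, labels, test_group="case")
        assert table["log2fc"].abs().max() < 1.5  # pure noise at sigma 0.5

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_expression(range(1, 11), 1, geneset(1, name="p"), 1.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            generate_expression(range(1, 11), 5, geneset(99, name="p"), 1.0, 0.5, seed=0)


class TestGenerateDrugTable:
    def test_empty_at_zero_edge_probability(self):
        table, _ = generate_drug_table(range(1, 11), 5, 0.0, 0.5, seed=16)
        assert table.empty

    def test_complete_and_all_approved(self):
        table, _ = generate_drug_table(range(1, 11), 5, 1.0, 1.0, seed=17)
        assert len(table) == 50 and table["approved"].all()

    def test_approved_edge_count_near_expectation(self):
        n_drugs, n_genes, p_edge, p_approved = 10, 20, 0.3, 0.5
        counts = []
        for rep in range(50):
            table, _ = generate_drug_table(range(1, n_genes + 1), n_drugs,
                                           p_edge, p_approved, seed=2000 + rep)
            counts.append(int(table["approved"].sum()) if len(table) else 0)
        expected = n_drugs * n_genes * p_edge * p_approved
        se = np.sqrt(n_drugs * n_genes * p_edge * p_approved *
                     (1 - p_edge * p_approved) / 50)
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_truth_serializes(self, tmp_path):
        _, truth = generate_drug_table(range(1, 6), 2, 0.5, 0.5, seed=18)
        truth.to_json(tmp_path / "truth.json")
        loaded = json.loads((tmp_path / "truth.json").read_text())
        assert loaded["seed"] == 18
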