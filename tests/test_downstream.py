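import io

import numpy as np
import pandas as pd
import pytest

from comorbnet.downstream import (
    build_drug_gene_network,
    deg_filter,
    read_de_table,
    read_drug_gene_table,
    two_group_de,
)

from conftest import geneset


def drug_df(rows):
    return pd.DataFrame(rows, columns=["drug", "gene", "interaction_type", "approved", "source"])


class TestDrugTableIO:
    def test_parse_and_duplicate_drop(self):
        text = ("drug\tgene\tinteraction_type\tapproved\tsource\n"
                "aspirin\t10\tinhibitor\ttrue\tdb\n"
                "aspirin\t10\tinhibitor\ttrue\tdb\n"
                "statin\t20\tmodulator\t0\tdb\n")
        df = read_drug_gene_table(io.StringIO(text))
        assert len(df) == 2
        assert df["approved"].tolist() == [True, False]

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_drug_gene_table(io.StringIO("drug\tgene\na\t1\n"))

    def test_bad_approval_flag(self):
        text = "drug\tgene\tinteraction_type\tapproved\tsource\na\t1\ti\tmaybe\tdb\n"
        with pytest.raises(ValueError, match="approval"):
            read_drug_gene_table(io.StringIO(text))


class TestBuildDrugGeneNetwork:
    def test_approved_only_filter(self):
        table = drug_df([
            ("a", "1", "inhibitor", True, "db"),
            ("b", "2", "agonist", True, "db"),
            ("c", "3", "inhibitor", False, "db"),
        ])
        net = build_drug_gene_network(table, geneset(1, 2, 3), approved_only=True)
        assert net.graph.number_of_edges() == 2
        assert net.n_druggable_genes == 2

    def test_genes_disjoint_from_table(self):
        table = drug_df([("a", "1", "inhibitor", True, "db")])
        net = build_drug_gene_network(table, geneset(99), approved_only=False)
        assert net.graph.number_of_nodes() == 0 and net.n_druggable_genes == 0

    def test_case_insensitive_symbol_match(self):
        table = drug_df([("a", "Aldh1a1", "inhibitor", True, "db")])
        net = build_drug_gene_network(table, {"ALDH1A1"}, approved_only=True)
        assert net.n_druggable_genes == 1

    def test_node_sets_equal_surviving_endpoints(self):
        rng = np.random.default_rng(19817)
        rows = [(f"d{rng.integers(10)}", str(rng.integers(1, 30)), "t",
                 bool(rng.random() < 0.5), "db") for _ in range(100)]
        table = drug_df(rows).drop_duplicates()
        genes = geneset(*range(1, 16))
        net = build_drug_gene_network(table, genes, approved_only=True)
        surviving = [(d, g) for d, g, _, ap, _ in table.itertuples(index=False)
                     if ap and int(g) in genes.ids]
        assert set(net.drugs) == {d for d, _ in surviving}
        assert set(net.genes) == {g for _, g in surviving}
        assert net.n_druggable_genes == len({g for _, g in surviving})

    def test_exports(self, tmp_path):
        table = drug_df([("a", "1", "inhibitor", True, "db")])
        net = build_drug_gene_network(table, geneset(1), approved_only=True)
        net.to_edge_tsv(tmp_path / "edges.tsv")
        net.to_graphml(tmp_path / "net.graphml")
        lines = (tmp_path / "edges.tsv").read_text().splitlines()
        assert lines == ["drug\tgene\tinteraction_type", "a\t1\tinhibitor"]
        assert (tmp_path / "net.graphml").stat().st_size > 0


class TestTwoGroupDe:
    def test_identical_groups_null(self):
        expr = pd.DataFrame([[1, 2, 3, 1, 2, 3]], index=[10],
                            columns=list("abcdef"))
        out = two_group_de(expr, ["g1"] * 3 + ["g2"] * 3)
        assert out.loc[0, "log2fc"] == 0
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_linear_scale_ratio(self):
        expr = pd.DataFrame([[7.0, 8.0, 9.0, 3.0, 4.0, 5.0]], index=[10],
                            columns=list("abcdef"))
        out = two_group_de(expr, ["hi"] * 3 + ["lo"] * 3, data_scale="linear")
        assert out.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_log2_scale_mean_difference(self):
        expr = pd.DataFrame([[9.0, 9.0, 8.0, 8.0]], index=[10], columns=list("abcd"))
        out = two_group_de(expr, ["case", "case", "ctrl", "ctrl"], test_group="case")
        assert out.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_test_group_selects_numerator(self):
        expr = pd.DataFrame([[9.0, 9.0, 8.0, 8.0]], index=[10], columns=list("abcd"))
        fwd = two_group_de(expr, ["case", "case", "ctrl", "ctrl"], test_group="case")
        rev = two_group_de(expr, ["case", "case", "ctrl", "ctrl"], test_group="ctrl")
        assert fwd.loc[0, "log2fc"] == -rev.loc[0, "log2fc"]

    def test_sample_order_invariance_within_groups(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(8, 1, size=(20, 10)),
                            index=range(1, 21), columns=[f"s{i}" for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        shuffled = expr.iloc[:, [3, 0, 4, 1, 2, 8, 6, 5, 9, 7]]
        out1 = two_group_de(expr, labels, test_group="a")
        out2 = two_group_de(shuffled, labels, test_group="a")
        assert np.allclose(out1["p_raw"], out2["p_raw"])
        assert np.allclose(out1["log2fc"], out2["log2fc"])

    def test_group_too_small_error(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=[1], columns=list("abc"))
        with pytest.raises(ValueError, match="2 samples"):
            two_group_de(expr, ["x", "y", "y"])

    def test_nonpositive_linear_mean_names_gene(self):
        expr = pd.DataFrame([[1.0, 1.0, -2.0, -2.0]], index=[42], columns=list("abcd"))
        with pytest.raises(ValueError, match="42"):
            two_group_de(expr, ["a", "a", "b", "b"], data_scale="linear")


class TestDeTableAndFilter:
    def test_geo2r_dialect(self):
        text = ("ID\tGene.symbol\tlogFC\tP.Value\tadj.P.Val\n"
                "10\tALDH1A1\t0.5\t0.001\t0.01\n")
        df = read_de_table(io.StringIO(text))
        assert list(df.columns) == ["gene", "log2fc", "p_raw", "p_adj"]
        assert df.loc[0, "log2fc"] == 0.5

    def test_plain_dialect_and_validation(self):
        df = read_de_table(io.StringIO("gene\tlog2fc\tp_raw\tp_adj\n1\t0.4\t0.01\t0.02\n"))
        assert len(df) == 1
        with pytest.raises(ValueError):
            read_de_table(io.StringIO("gene\tlog2fc\tp_raw\tp_adj\n1\t0.4\t2.0\t0.02\n"))

    def test_threshold_logic(self):
        table = pd.DataFrame({
            "gene": [1, 2, 3, 4],
            "log2fc": [0.5, 0.2, 0.5, -0.4],
            "p_raw": [0.001] * 4,
            "p_adj": [0.01, 0.01, 0.06, 0.04],
        })
        assert deg_filter(table).ids == {1, 4}

    def test_empty_table(self):
        assert deg_filter(pd.DataFrame(columns=["gene", "log2fc", "p_raw", "p_adj"])).ids == frozenset()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "gene": range(1, 101),
            "log2fc": rng.normal(0, 0.5, 100),
            "p_raw": rng.uniform(0, 1, 100),
            "p_adj": rng.uniform(0, 1, 100),
        })
        strict = deg_filter(table, 0.3, 0.05).ids
        assert strict <= deg_filter(table, 0.2, 0.05).ids
        assert strict <= deg_filter(table, 0.3, 0.10).ids

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "gene": range(1, 51),
            "log2fc": rng.normal(0, 0.5, 50),
            "p_raw": rng.uniform(0, 1, 50),
            "p_adj": rng.uniform(0, 1, 50),
        })
        expected = {int(r.gene) for r in table.itertuples()
                    if abs(r.log2fc) > 0.3 and r.p_adj < 0.05}
        assert deg_filter(table).ids == expected
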