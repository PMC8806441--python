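"""Drug-gene bipartite networks and differential-expression validation.

Two downstream stages of the comorbidity analysis:

* building a drug-gene interaction network from an interaction table
  (DGIdb-style TSV with an approval flag), restricted to a gene set of
  interest (e.g. the core genes) and optionally to approved drugs only; and
* a two-group differential-expression screen (Welch t-test per gene, BH
  adjustment) with the threshold filter |log2FC| > 0.3 and adjusted
  p < 0.05.  The Welch test stands in for the moderated statistics of
  microarray pipelines; externally produced GEO2R-style tables can be fed
  straight into :func:`deg_filter` via :func:`read_de_table`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .genesets import GeneSet

logger = logging.getLogger(__name__)

DRUG_COLUMNS = ["drug", "gene", "interaction_type", "approved", "source"]
_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


# ---------------------------------------------------------------------------
# drug-gene network


def read_drug_gene_table(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Read a DGIdb-style TSV (drug, gene, interaction_type, approved, source).

    The ``approved`` column accepts true/false, yes/no or 0/1.  Fully
    duplicated rows are dropped with a logged count.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drug-gene table is missing columns {missing}")
    df = df[DRUG_COLUMNS].copy()

    def to_bool(v: str) -> bool:
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise ValueError(f"cannot parse approval flag {v!r}")

    df["approved"] = df["approved"].map(to_bool)
    n0 = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n0:
        logger.info("read_drug_gene_table: dropped %d duplicate rows", n0 - len(df))
    return df


def _norm_gene(value) -> str:
    return str(value).strip().upper()


@dataclass(frozen=True)
class BipartiteNetwork:
    """Drug-gene bipartite graph; every node has at least one edge."""

    graph: nx.Graph
    drugs: tuple[str, ...]
    genes: tuple[str, ...]

    @property
    def n_druggable_genes(self) -> int:
        return len(self.genes)

    def edge_rows(self) -> list[tuple[str, str, str]]:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            drug, gene = (u, v) if self.graph.nodes[u]["kind"] == "drug" else (v, u)
            rows.append((drug[5:], gene[5:], data.get("interaction_type", "")))
        return sorted(rows)

    def to_edge_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        close = isinstance(path, (str, os.PathLike))
        handle = open(path, "w", encoding="utf-8") if close else path
        try:
            handle.write("drug\tgene\tinteraction_type\n")
            for drug, gene, itype in self.edge_rows():
                handle.write(f"{drug}\t{gene}\t{itype}\n")
        finally:
            if close:
                handle.close()

    def to_graphml(self, path: str | os.PathLike) -> None:
        nx.write_graphml(self.graph, path)


def build_drug_gene_network(
    table: pd.DataFrame,
    genes: GeneSet | Iterable,
    approved_only: bool = True,
) -> BipartiteNetwork:
    """Bipartite network of drug-gene interactions touching ``genes``.

    Rows survive when their gene is in ``genes`` (exact identifier or
    case-insensitive symbol match, no aliasing) and, if ``approved_only``,
    the approval flag is set.  An empty result is valid and logged.  Node
    names are prefixed ``drug:`` / ``gene:`` so the two partitions can never
    collide in exports.
    """
    if table.empty:
        raise ValueError("drug-gene table is empty")
    gene_ids = genes.ids if isinstance(genes, GeneSet) else genes
    wanted = {_norm_gene(g) for g in gene_ids}
    mask = table["gene"].map(_norm_gene).isin(wanted)
    if approved_only:
        mask &= table["approved"]
    surviving = table[mask]
    if surviving.empty:
        logger.info("build_drug_gene_network: no interactions survive the filters")
    graph = nx.Graph()
    for row in surviving.itertuples(index=False):
        d, g = f"drug:{row.drug}", f"gene:{row.gene}"
        graph.add_node(d, kind="drug", bipartite=0)
        graph.add_node(g, kind="gene", bipartite=1)
        graph.add_edge(d, g, interaction_type=str(row.interaction_type))
    drugs = tuple(sorted(n[5:] for n, d in graph.nodes(data=True) if d["kind"] == "drug"))
    gene_nodes = tuple(sorted(n[5:] for n, d in graph.nodes(data=True) if d["kind"] == "gene"))
    return BipartiteNetwork(graph=graph, drugs=drugs, genes=gene_nodes)


# ---------------------------------------------------------------------------
# differential expression

DE_COLUMNS = ["gene", "log2fc", "p_raw", "p_adj"]
_GEO2R_MAP = {"ID": "gene", "logFC": "log2fc", "P.Value": "p_raw", "adj.P.Val": "p_adj"}


def two_group_de(
    expr: pd.DataFrame,
    groups: Sequence[str],
    data_scale: str = "log2",
    test_group: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-group comparison: Welch t-test plus log2 fold change.

    ``expr`` is genes x samples; ``groups`` labels each column with one of
    exactly two levels.  ``test_group`` names the numerator of the fold
    change (e.g. the hypertensive group; defaults to the first label in
    column order).  With ``data_scale='log2'`` the fold change is the mean
    difference; with ``'linear'`` it is log2 of the ratio of means, which
    must both be positive.  Returns a DeTable DataFrame with columns
    gene, log2fc, p_raw, p_adj (BH).
    """
    groups = list(groups)
    if len(groups) != expr.shape[1]:
        raise ValueError("one group label per expression column is required")
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels are required, got {levels}")
    if data_scale not in ("log2", "linear"):
        raise ValueError("data_scale must be 'log2' or 'linear'")
    if test_group is None:
        test_group = levels[0]
    if test_group not in levels:
        raise ValueError(f"test_group {test_group!r} is not a group label")
    ref_group = levels[1] if test_group == levels[0] else levels[0]
    garr = np.asarray(groups)
    a = expr.loc[:, garr == test_group].to_numpy(dtype=float)
    b = expr.loc[:, garr == ref_group].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    if data_scale == "linear":
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        bad = np.flatnonzero((ma <= 0) | (mb <= 0))
        if bad.size:
            raise ValueError(
                f"nonpositive group mean on linear scale for gene {expr.index[bad[0]]!r}"
            )
        log2fc = np.log2(ma / mb)
    else:
        log2fc = a.mean(axis=1) - b.mean(axis=1)

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate rows (zero variance in both groups): t-test is undefined;
    # identical means are a perfect null (p=1), different means a sure call.
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        diff = a.mean(axis=1) - b.mean(axis=1)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    out = pd.DataFrame({
        "gene": expr.index,
        "log2fc": log2fc,
        "p_raw": p,
        "p_adj": bh_adjust(p),
    }).reset_index(drop=True)
    return out


def read_de_table(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Read a DE table in GEO2R dialect or the plain 4-column dialect.

    GEO2R headers (``ID``, ``logFC``, ``P.Value``, ``adj.P.Val``; extra
    columns such as ``Gene.symbol`` ignored) are renamed to the canonical
    gene/log2fc/p_raw/p_adj columns.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    if set(_GEO2R_MAP) <= set(df.columns):
        df = df.rename(columns=_GEO2R_MAP)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table is missing columns {missing}")
    df = df[DE_COLUMNS].copy()
    for c in ("log2fc", "p_raw", "p_adj"):
        df[c] = pd.to_numeric(df[c])
    if ((df["p_raw"] < 0) | (df["p_raw"] > 1) | (df["p_adj"] < 0) | (df["p_adj"] > 1)).any():
        raise ValueError("DE table p-values must lie in [0, 1]")
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError("DE table fold changes must be finite")
    return df


def deg_filter(
    table: pd.DataFrame,
    min_abs_log2fc: float = 0.3,
    max_p_adj: float = 0.05,
) -> GeneSet:
    """Differentially expressed genes: |log2FC| > threshold AND adj. p < threshold.

    Both inequalities are strict, matching the conventional cutoff notation.
    """
    if table.empty:
        return GeneSet(name="degs", ids=frozenset())
    mask = (table["log2fc"].abs() > min_abs_log2fc) & (table["p_adj"] < max_p_adj)
    ids = frozenset(int(g) for g in table.loc[mask, "gene"])
    return GeneSet(name="degs", ids=ids)
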