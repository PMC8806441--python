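"""End-to-end run configuration and orchestration.

``full_run`` chains the whole analysis on a synthetic scenario: generate
inputs -> gene-set overlaps -> proximity z-score -> DIAMOnD modules for
both diseases -> core genes -> enrichment of the core genes -> drug-gene
network -> differential-expression validation, and writes every stage
output plus a single structured report.  The run is deterministic given the
global seed: per-stage seeds are derived by hashing the stage name into the
global seed, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass

import numpy as np

from . import diamond, downstream, enrichment, genesets, proximity, synthetic
from .interactome import Interactome, largest_connected_component, write_interactome

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run.

    The significance thresholds default to the conventional cutoffs used
    throughout the package: GO filter p < 0.01 / count >= 3 / factor > 1.5,
    KEGG p < 0.05, DE |log2FC| > 0.3 / adj. p < 0.05, proximity z <= -1.645.
    """

    seed: int = 0
    log_level: str = "INFO"
    # synthetic scenario
    n_nodes: int = 2000
    attachment_edges: int = 3
    set_size_a: int = 30
    set_size_b: int = 30
    proximal: bool = True
    locality_radius: int = 2
    mixing: float = 0.8
    n_terms: int = 200
    term_size_lo: int = 10
    term_size_hi: int = 40
    n_planted_terms: int = 5
    overlap_fraction: float = 0.8
    n_per_group: int = 10
    n_expr_genes: int = 500
    n_planted_degs: int = 50
    delta_log2: float = 1.0
    sigma: float = 0.5
    n_drugs: int = 50
    p_edge: float = 0.02
    p_approved: float = 0.5
    # analysis parameters
    n_random: int = 1000
    min_bin_size: int | None = None
    target_size_a: int = 120
    target_size_b: int = 120
    omega: int = 1
    measure: str = "closest"
    # thresholds
    go_max_p: float = 0.01
    go_min_count: int = 3
    go_min_factor: float = 1.5
    kegg_max_p: float = 0.05
    de_min_abs_log2fc: float = 0.3
    de_max_p_adj: float = 0.05
    z_alpha: float = 0.05

    def validate(self) -> None:
        if self.target_size_a < self.set_size_a or self.target_size_b < self.set_size_b:
            raise ValueError("target module sizes must be at least the seed-set sizes")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if not 0 <= self.mixing <= 1:
            raise ValueError("mixing must lie in [0, 1]")
        if self.n_planted_degs > self.n_expr_genes:
            raise ValueError("more planted DEGs than expression genes")

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file; keyword overrides win."""
        values: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, "r", encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"config line {lineno}: expected 'key = value'")
                key, _, val = (p.strip() for p in line.partition("="))
                if key not in fields:
                    raise ValueError(f"config line {lineno}: unknown key {key!r}")
                values[key] = _coerce(val, fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(value: str, annotation: str):
    annotation = str(annotation)
    if value.lower() in ("none", ""):
        return None
    if "bool" in annotation:
        return value.lower() in ("true", "1", "yes")
    if "int" in annotation:
        return int(value)
    if "float" in annotation:
        return float(value)
    return value


def full_run(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute every stage on the configured synthetic scenario.

    Writes stage outputs (edge list, gene lists, GMT, TSVs, GraphML,
    truth.json) under ``outdir`` and returns the report dict, also written
    as ``report.json`` with sorted keys so equal configs give byte-identical
    files.  A stage failure propagates with the stage name; outputs of
    completed stages are retained.
    """
    config.validate()
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "config": config.to_dict()}
    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------------
        g = synthetic.generate_interactome(
            config.n_nodes, config.attachment_edges, seed=stage_seed(config.seed, "interactome"))
        g = largest_connected_component(g)
        set_a, set_b, pair_truth = synthetic.plant_gene_set_pair(
            g, config.set_size_a, config.set_size_b, proximal=config.proximal,
            locality_radius=config.locality_radius, mixing=config.mixing,
            seed=stage_seed(config.seed, "gene_sets"))
        set_a = genesets.GeneSet(name="disease_a", ids=set_a.ids)
        set_b = genesets.GeneSet(name="disease_b", ids=set_b.ids)
        expr_genes = sorted(g.nodes)[: config.n_expr_genes]
        rng_ids = np.random.default_rng(stage_seed(config.seed, "planted_degs"))
        planted_degs = genesets.GeneSet(
            name="planted_degs",
            ids=frozenset(int(x) for x in rng_ids.choice(expr_genes, size=config.n_planted_degs,
                                                         replace=False)))
        ann, ann_truth = synthetic.generate_annotations(
            sorted(g.nodes), config.n_terms, (config.term_size_lo, config.term_size_hi),
            planted_query=set_a, n_planted_terms=config.n_planted_terms,
            overlap_fraction=config.overlap_fraction,
            seed=stage_seed(config.seed, "annotations"))
        expr, labels, expr_truth = synthetic.generate_expression(
            expr_genes, config.n_per_group, planted_degs, config.delta_log2,
            config.sigma, seed=stage_seed(config.seed, "expression"))
        drug_table, drug_truth = synthetic.generate_drug_table(
            sorted(g.nodes), config.n_drugs, config.p_edge, config.p_approved,
            seed=stage_seed(config.seed, "drugs"))

        write_interactome(g, os.path.join(outdir, "edges.tsv"))
        genesets.write_gene_set(set_a, os.path.join(outdir, "set_a.txt"))
        genesets.write_gene_set(set_b, os.path.join(outdir, "set_b.txt"))
        enrichment.write_annotations(ann, os.path.join(outdir, "annotations.gmt"))
        expr.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
        with open(os.path.join(outdir, "labels.tsv"), "w", encoding="utf-8") as fh:
            fh.write("sample\tgroup\n")
            for col, lab in zip(expr.columns, labels):
                fh.write(f"{col}\t{lab}\n")
        drug_table.to_csv(os.path.join(outdir, "drugs.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
            json.dump({"pair": pair_truth.__dict__, "annotations": ann_truth.__dict__,
                       "expression": expr_truth.__dict__, "drugs": drug_truth.__dict__},
                      fh, indent=1, sort_keys=True, default=list)

        # --- overlap -------------------------------------------------------
        stage = "overlap"
        ov = genesets.overlap_percentages(set_a, set_b)
        venn = genesets.multiway_overlap([set_a, set_b])
        venn.to_tsv(os.path.join(outdir, "overlap.tsv"))
        report["overlap"] = {
            "count": ov.count, "pct_of_a": ov.pct_of_a, "pct_of_b": ov.pct_of_b,
        }

        # --- proximity -----------------------------------------------------
        stage = "proximity"
        prox = proximity.proximity_zscore(
            g, set_a, set_b, n_random=config.n_random,
            min_bin_size=config.min_bin_size, seed=stage_seed(config.seed, "proximity"),
            measure=config.measure)
        report["proximity"] = prox.to_dict()

        # --- diamond modules -----------------------------------------------
        stage = "diamond"
        mod_a = diamond.build_disease_module("disease_a", g, set_a,
                                             target_size=config.target_size_a, omega=config.omega)
        mod_b = diamond.build_disease_module("disease_b", g, set_b,
                                             target_size=config.target_size_b, omega=config.omega)
        mod_a.provenance.to_tsv(os.path.join(outdir, "module_a_steps.tsv"))
        mod_b.provenance.to_tsv(os.path.join(outdir, "module_b_steps.tsv"))
        genesets.write_gene_set(mod_a.members, os.path.join(outdir, "module_a.txt"))
        genesets.write_gene_set(mod_b.members, os.path.join(outdir, "module_b.txt"))
        report["modules"] = {"size_a": mod_a.size, "size_b": mod_b.size}

        # --- core genes ----------------------------------------------------
        stage = "core"
        core = diamond.module_core_genes(mod_a, mod_b)
        genesets.write_gene_set(core, os.path.join(outdir, "core_genes.txt"))
        report["core"] = {"count": len(core), "genes": sorted(core.ids)}

        # --- enrichment ----------------------------------------------------
        stage = "enrich"
        rows = enrichment.enrich(core if len(core) else set_a, ann, profile="go")
        enrichment.write_enrichment_tsv(rows, os.path.join(outdir, "enrichment.tsv"))
        report["enrichment"] = {
            "n_terms_tested": len(ann.terms),
            "n_reported": len(rows),
            "n_pass_go": sum(r.passes_go_filter for r in rows),
            "n_pass_kegg": sum(r.passes_kegg_filter for r in rows),
        }

        # --- drug-gene network ---------------------------------------------
        stage = "drugnet"
        net = downstream.build_drug_gene_network(drug_table, core if len(core) else set_a,
                                                 approved_only=True)
        net.to_edge_tsv(os.path.join(outdir, "drug_gene_edges.tsv"))
        net.to_graphml(os.path.join(outdir, "drug_gene_network.graphml"))
        report["drugs"] = {
            "n_druggable_genes": net.n_druggable_genes,
            "n_drugs": len(net.drugs),
            "n_interactions": net.graph.number_of_edges(),
        }

        # --- differential expression ---------------------------------------
        stage = "de"
        de_table = downstream.two_group_de(expr, labels, data_scale="log2", test_group="case")
        de_table.to_csv(os.path.join(outdir, "de_table.tsv"), sep="\t", index=False)
        degs = downstream.deg_filter(de_table, config.de_min_abs_log2fc, config.de_max_p_adj)
        genesets.write_gene_set(degs, os.path.join(outdir, "degs.txt"))
        report["de"] = {
            "n_deg": len(degs),
            "n_deg_in_core": len(degs.ids & core.ids),
            "n_planted_recovered": len(degs.ids & planted_degs.ids),
            "n_planted": len(planted_degs),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
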