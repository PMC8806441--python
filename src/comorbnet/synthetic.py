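"""Synthetic inputs with known ground truth for the whole pipeline.

Real inputs to a network-medicine comorbidity analysis — a curated human
interactome, database gene-set extracts, GO/KEGG annotations, DGIdb drug
tables and GEO expression series — are not redistributable.  This module
generates desk-scale stand-ins for all of them with the planted signal
recorded in a :class:`ScenarioTruth`, so every downstream claim (proximity
detection, module recovery, enrichment power, DE power/FDR) can be tested
against ground truth.

Every generator is a pure function of its seed: identical arguments give
byte-identical artifacts after serialization.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationCollection, Term
from .genesets import GeneSet
from .interactome import Interactome, bfs_distances

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("inhibitor", "agonist", "antagonist", "modulator", "binder")


@dataclass
class ScenarioTruth:
    """Ground truth of a generated scenario, JSON-serializable.

    ``params`` echoes every generator argument; the planted_* fields record
    what signal, if any, was placed in the artifacts.
    """

    seed: int
    params: dict = field(default_factory=dict)
    planted_proximal: bool | None = None
    locality_radius: int | None = None
    center: int | None = None
    planted_module_members: tuple[int, ...] = ()
    achieved_extra_edge_fraction: float | None = None
    planted_enriched_terms: tuple[str, ...] = ()
    planted_deg_genes: tuple[int, ...] = ()

    def to_json(self, path) -> None:
        import os
        close = isinstance(path, (str, os.PathLike))
        handle = open(path, "w", encoding="utf-8") if close else path
        try:
            json.dump(self.__dict__, handle, indent=1, sort_keys=True, default=list)
        finally:
            if close:
                handle.close()


def generate_interactome(n_nodes: int, attachment_edges: int, seed: int,
                         name: str = "synthetic_ppi") -> Interactome:
    """Preferential-attachment network with a heavy-tailed degree distribution.

    Growth starts from a clique on m+1 nodes (m = ``attachment_edges``);
    each subsequent node attaches m distinct edges to existing nodes with
    probability proportional to current degree.  The result is connected
    with exactly C(m+1, 2) + m (n - m - 1) edges, emulating the sparse,
    hub-dominated shape of a curated protein-protein interactome at
    configurable scale.  Nodes are labelled 1..n.
    """
    m = attachment_edges
    if not (n_nodes > m >= 1):
        raise ValueError(f"need n_nodes > attachment_edges >= 1; got {n_nodes}, {m}")
    rng = np.random.default_rng(seed)
    g = Interactome(name=name)
    # degree-proportional sampling via the repeated-endpoints list
    repeated: list[int] = []
    for a in range(1, m + 2):
        for b in range(a + 1, m + 2):
            g.graph.add_edge(a, b)
            repeated.extend((a, b))
    for new in range(m + 2, n_nodes + 1):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in sorted(targets):
            g.graph.add_edge(new, t)
            repeated.extend((new, t))
    g._invalidate()
    return g


def _ball(g: Interactome, center: int, radius: int) -> list[int]:
    d = bfs_distances(g, {center})
    return sorted(n for n, dist in d.items() if dist <= radius)


def plant_gene_set_pair(
    g: Interactome,
    size_a: int,
    size_b: int,
    proximal: bool,
    locality_radius: int = 2,
    mixing: float = 0.8,
    seed: int = 0,
) -> tuple[GeneSet, GeneSet, ScenarioTruth]:
    """Two disjoint gene sets, optionally planted close together.

    Proximal pairs are a BFS-ball sample around a shared center: the
    innermost ``size_a + size_b`` nodes of the radius-``locality_radius``
    ball (whole BFS layers from the center, the boundary layer completed by
    a uniform draw), shuffled and split into the two sets, so the pair
    genuinely occupies one local neighborhood.  Each member is then
    independently replaced by a uniform random network node with
    probability 1 - ``mixing`` (``mixing`` = 0.8 keeps 80% of the local
    signal).  Non-proximal pairs are uniform draws.  The center is drawn
    uniformly among nodes whose ball can host both sets; if none exists,
    ValueError.
    """
    if not 0 <= mixing <= 1:
        raise ValueError("mixing must lie in [0, 1]")
    nodes = sorted(g.nodes)
    if size_a + size_b > len(nodes):
        raise ValueError("requested sets exceed the network size")
    rng = np.random.default_rng(seed)
    truth = ScenarioTruth(
        seed=seed,
        params={"size_a": size_a, "size_b": size_b, "proximal": proximal,
                "locality_radius": locality_radius, "mixing": mixing},
        planted_proximal=proximal,
        locality_radius=locality_radius if proximal else None,
    )
    if proximal:
        need = size_a + size_b
        order = rng.permutation(nodes)
        center = ball = None
        for cand in order:
            b = _ball(g, int(cand), locality_radius)
            if len(b) >= need:
                center, ball = int(cand), b
                break
        if center is None:
            raise ValueError(
                f"no radius-{locality_radius} ball can host {size_a}+{size_b} genes"
            )
        truth.center = center
        dist = bfs_distances(g, {center})
        by_layer: dict[int, list[int]] = {}
        for node in ball:
            by_layer.setdefault(dist[node], []).append(node)
        local: list[int] = []
        for layer in sorted(by_layer):
            layer_nodes = sorted(by_layer[layer])
            if len(local) + len(layer_nodes) <= need:
                local.extend(layer_nodes)
            else:
                local.extend(int(x) for x in
                             rng.choice(layer_nodes, size=need - len(local), replace=False))
                break
        local = [int(x) for x in rng.permutation(local)]
        a = set(local[:size_a])
        b_set = set(local[size_a:])
        # mixing: swap each member for a uniform outsider with prob 1 - mixing
        for s in (a, b_set):
            for gene in sorted(s):
                if rng.random() > mixing:
                    s.discard(gene)
                    while True:
                        repl = int(nodes[int(rng.integers(len(nodes)))])
                        if repl not in a and repl not in b_set:
                            s.add(repl)
                            break
    else:
        draw = rng.choice(nodes, size=size_a + size_b, replace=False)
        a = set(int(x) for x in draw[:size_a])
        b_set = set(int(x) for x in draw[size_a:])
    return (
        GeneSet(name="set_a", ids=frozenset(a)),
        GeneSet(name="set_b", ids=frozenset(b_set)),
        truth,
    )


def plant_dense_module(
    g: Interactome,
    module_size: int,
    extra_edge_fraction: float,
    n_seeds: int,
    seed: int = 0,
) -> tuple[GeneSet, ScenarioTruth]:
    """Densify a BFS-ball sample of nodes into a planted module (mutates ``g``).

    The ``module_size`` nodes nearest a random center (BFS order, ties by
    id) become the module; random non-adjacent member pairs gain edges until
    the internal edge count has grown by ``extra_edge_fraction`` (e.g. 1.5
    means +150%).  If the members saturate into a clique first, the achieved
    fraction is recorded in the truth and a warning logged.  ``n_seeds``
    members are returned as the seed set for module-recovery experiments.
    """
    if not 0 < n_seeds <= module_size <= g.n_nodes:
        raise ValueError("need 0 < n_seeds <= module_size <= |nodes|")
    if extra_edge_fraction < 0:
        raise ValueError("extra_edge_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    center = int(nodes[int(rng.integers(len(nodes)))])
    dist = bfs_distances(g, {center})
    reachable = sorted(dist, key=lambda n: (dist[n], n))
    if len(reachable) < module_size:
        raise ValueError("center's component is smaller than the requested module")
    members = sorted(reachable[:module_size])
    internal0 = g.graph.subgraph(members).number_of_edges()
    target_new = math.ceil(internal0 * extra_edge_fraction)
    possible = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]
                if not g.graph.has_edge(a, b)]
    n_new = min(target_new, len(possible))
    if n_new < target_new:
        logger.warning(
            "plant_dense_module: clique saturation at +%d of %d requested edges",
            n_new, target_new,
        )
    if n_new:
        chosen = rng.choice(len(possible), size=n_new, replace=False)
        for i in sorted(int(c) for c in chosen):
            g.add_edge(*possible[i])
    seeds = sorted(int(x) for x in rng.choice(members, size=n_seeds, replace=False))
    achieved = n_new / internal0 if internal0 else 0.0
    truth = ScenarioTruth(
        seed=seed,
        params={"module_size": module_size, "extra_edge_fraction": extra_edge_fraction,
                "n_seeds": n_seeds, "center": center},
        planted_module_members=tuple(members),
        achieved_extra_edge_fraction=achieved,
    )
    return GeneSet(name="module_seeds", ids=frozenset(seeds)), truth


def generate_annotations(
    universe: Sequence[int],
    n_terms: int,
    size_range: tuple[int, int],
    planted_query: GeneSet | None = None,
    n_planted_terms: int = 0,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    disjoint: bool = False,
) -> tuple[AnnotationCollection, ScenarioTruth]:
    """Annotation collection over ``universe`` with optionally planted terms.

    Unplanted terms are uniform draws of a size sampled from ``size_range``
    (inclusive); each planted term shares ceil(overlap_fraction * size)
    members with ``planted_query`` and fills the rest from outside it.
    Planted term sizes are drawn from the feasible part of ``size_range``
    (a term cannot share more members with the query than the query has);
    an empty feasible range is an error.  With
    ``disjoint=True`` the unplanted terms partition the universe without
    overlap (useful for independence in type-I calibration), which requires
    n_terms * max_size <= |universe|.
    """
    universe = sorted(int(u) for u in set(universe))
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("size_range infeasible for the universe")
    if n_planted_terms > n_terms:
        raise ValueError("more planted terms than terms")
    if n_planted_terms and planted_query is None:
        raise ValueError("planted terms need a planted_query")
    rng = np.random.default_rng(seed)
    terms: list[Term] = []
    planted_ids: list[str] = []
    query = sorted(planted_query.ids) if planted_query is not None else []
    non_query = [u for u in universe if u not in set(query)]
    pool = list(universe)  # consumed only in disjoint mode
    planted_hi = hi
    if n_planted_terms and overlap_fraction > 0:
        planted_hi = min(hi, math.floor(len(query) / overlap_fraction))
    for i in range(n_terms):
        tid = f"T{i + 1:04d}"
        if i < n_planted_terms:
            if planted_hi < lo:
                raise ValueError("planted overlap infeasible for query/universe sizes")
            size = int(rng.integers(lo, planted_hi + 1))
            n_shared = math.ceil(overlap_fraction * size)
            if n_shared > len(query) or size - n_shared > len(non_query):
                raise ValueError("planted overlap infeasible for query/universe sizes")
            shared = rng.choice(query, size=n_shared, replace=False)
            rest = rng.choice(non_query, size=size - n_shared, replace=False)
            members = frozenset(int(x) for x in shared) | frozenset(int(x) for x in rest)
            planted_ids.append(tid)
            terms.append(Term(id=tid, name=f"synthetic term {i + 1}", members=members))
            continue
        size = int(rng.integers(lo, hi + 1))
        if disjoint:
            if size > len(pool):
                raise ValueError("disjoint terms exhausted the universe")
            draw = rng.choice(pool, size=size, replace=False)
            members = frozenset(int(x) for x in draw)
            pool = [u for u in pool if u not in members]
        else:
            draw = rng.choice(universe, size=size, replace=False)
            members = frozenset(int(x) for x in draw)
        terms.append(Term(id=tid, name=f"synthetic term {i + 1}", members=members))
    truth = ScenarioTruth(
        seed=seed,
        params={"n_terms": n_terms, "size_range": list(size_range),
                "n_planted_terms": n_planted_terms,
                "overlap_fraction": overlap_fraction, "disjoint": disjoint},
        planted_enriched_terms=tuple(planted_ids),
    )
    return AnnotationCollection(terms=tuple(terms), background=frozenset(universe)), truth


def generate_expression(
    genes: Sequence[int],
    n_per_group: int,
    planted: GeneSet,
    delta_log2: float,
    sigma: float,
    seed: int = 0,
    group_labels: tuple[str, str] = ("control", "case"),
) -> tuple[pd.DataFrame, list[str], ScenarioTruth]:
    """Two-group log2-scale expression matrix with planted DEGs.

    Per-gene baseline ~ Normal(8, 1); i.i.d. Normal(0, sigma) noise; the
    planted genes are shifted by ``delta_log2`` in the second (case) group,
    so their expected log2 fold change (case vs control) is ``delta_log2``.
    Returns (genes x samples DataFrame, per-column group labels, truth).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    genes = sorted(int(x) for x in set(genes))
    stray = set(planted.ids) - set(genes)
    if stray:
        raise ValueError(f"planted genes absent from the gene list: {sorted(stray)[:5]}")
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, 2 * n_per_group))
    planted_mask = np.array([g in planted.ids for g in genes])
    values[planted_mask, n_per_group:] += delta_log2
    ctrl, case = group_labels
    columns = [f"{ctrl}_{i + 1}" for i in range(n_per_group)] + \
              [f"{case}_{i + 1}" for i in range(n_per_group)]
    labels = [ctrl] * n_per_group + [case] * n_per_group
    expr = pd.DataFrame(values, index=genes, columns=columns)
    truth = ScenarioTruth(
        seed=seed,
        params={"n_per_group": n_per_group, "delta_log2": delta_log2, "sigma": sigma,
                "group_labels": list(group_labels)},
        planted_deg_genes=tuple(sorted(planted.ids)),
    )
    return expr, labels, truth


def generate_drug_table(
    genes: Sequence[int],
    n_drugs: int,
    p_edge: float,
    p_approved: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Random DGIdb-style interaction table over ``genes``.

    Each (drug, gene) pair is an interaction independently with probability
    ``p_edge``; its approval flag is Bernoulli(``p_approved``).
    """
    if not (0 <= p_edge <= 1 and 0 <= p_approved <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    genes = sorted(int(x) for x in set(genes))
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(1, n_drugs + 1):
        drug = f"DRUG{d:04d}"
        for gene in genes:
            if rng.random() < p_edge:
                rows.append({
                    "drug": drug,
                    "gene": gene,
                    "interaction_type": INTERACTION_TYPES[int(rng.integers(len(INTERACTION_TYPES)))],
                    "approved": bool(rng.random() < p_approved),
                    "source": "synthetic",
                })
    table = pd.DataFrame(rows, columns=["drug", "gene", "interaction_type", "approved", "source"])
    truth = ScenarioTruth(
        seed=seed,
        params={"n_drugs": n_drugs, "p_edge": p_edge, "p_approved": p_approved,
                "n_genes": len(genes)},
    )
    return table, truth
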