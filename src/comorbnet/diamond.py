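"""DIAMOnD disease-module expansion and core-gene intersection.

DIAMOnD (DIseAse MOdule Detection) grows a disease module from curated seed
genes by repeatedly adding the gene whose links into the current module are
most statistically unexpected.  For a candidate of degree k with ks links
into a module of size s0 inside an N-node network, the connectivity
significance is the hypergeometric upper tail

    p(k, ks) = sum_{i = ks..k} C(s0, i) C(N - s0, k - i) / C(N, k),

i.e. the chance that a random degree-k gene would hit the module at least
ks times.  At every iteration the candidate with the smallest p is added
(ties: larger ks, then smaller k, then smaller gene id — fixed so runs are
deterministic) and the module grows by one.

A seed weight omega >= 1 counts each link to a seed gene omega times, as in
the original algorithm; omega = 1 (the default) is the pure hypergeometric.

The *core genes* of two diseases are the intersection of their modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

from scipy.stats import hypergeom

from .genesets import GeneSet
from .interactome import Interactome

logger = logging.getLogger(__name__)


def connectivity_pvalue(
    k: int,
    ks: int,
    s0: int,
    N: int,
    omega: int = 1,
    ks_seed: int | None = None,
    s_seed: int | None = None,
) -> float:
    """Hypergeometric upper-tail connectivity significance.

    Parameters mirror the statistic above: ``k`` candidate degree, ``ks``
    links into the module, ``s0`` module size, ``N`` network size.  With
    ``omega > 1``, ``ks_seed`` of the module links and ``s_seed`` of the
    module members are seeds and each seed link/member is counted ``omega``
    times (both default to all of them).  ``ks = 0`` gives p = 1.
    """
    if not (isinstance(omega, int) and omega >= 1):
        raise ValueError("omega must be an integer >= 1")
    if not (0 <= ks <= min(k, s0)):
        raise ValueError(f"need 0 <= ks <= min(k, s0); got k={k}, ks={ks}, s0={s0}")
    if not (0 < s0 < N):
        raise ValueError(f"need 0 < s0 < N; got s0={s0}, N={N}")
    if not (0 <= k <= N - 1):
        raise ValueError(f"need 0 <= k <= N-1; got k={k}, N={N}")
    if omega > 1:
        ks_seed = ks if ks_seed is None else ks_seed
        s_seed = s0 if s_seed is None else s_seed
        if not (0 <= ks_seed <= ks and 0 <= s_seed <= s0):
            raise ValueError("need 0 <= ks_seed <= ks and 0 <= s_seed <= s0")
        k = k + (omega - 1) * ks_seed
        ks = omega * ks_seed + (ks - ks_seed)
        s0 = omega * s_seed + (s0 - s_seed)
        N = N + (omega - 1) * s_seed
    # upper tail P(X >= ks) for X ~ Hypergeom(N, s0, k)
    return float(hypergeom.sf(ks - 1, N, s0, k))


class DiamondStep(NamedTuple):
    """One module-growth step: iteration index (1-based), gene, its degree,
    its links into the module at addition time, and the connectivity p."""

    iteration: int
    gene: int
    degree: int
    ks: int
    p_connectivity: float


@dataclass(frozen=True)
class DiamondRun:
    """Ordered log of a DIAMOnD expansion."""

    seeds_in_network: GeneSet
    steps: tuple[DiamondStep, ...]
    n_iterations_requested: int
    omega: int
    network_size: int

    @property
    def added_genes(self) -> tuple[int, ...]:
        return tuple(s.gene for s in self.steps)

    @property
    def completed(self) -> bool:
        return len(self.steps) == self.n_iterations_requested

    def to_tsv(self, path) -> None:
        import os
        close = isinstance(path, (str, os.PathLike))
        handle = open(path, "w", encoding="utf-8") if close else path
        try:
            handle.write("iteration\tgene\tdegree\tks\tp_connectivity\n")
            for s in self.steps:
                handle.write(f"{s.iteration}\t{s.gene}\t{s.degree}\t{s.ks}\t{s.p_connectivity:.6g}\n")
        finally:
            if close:
                handle.close()


@dataclass(frozen=True)
class DiseaseModule:
    """A disease module: seeds plus DIAMOnD-added genes, with provenance."""

    name: str
    members: GeneSet
    provenance: DiamondRun

    def __post_init__(self):
        expected = set(self.provenance.seeds_in_network.ids) | set(self.provenance.added_genes)
        if set(self.members.ids) != expected:
            raise ValueError("module members must equal seeds plus stepped genes")

    @property
    def size(self) -> int:
        return len(self.members)


def diamond_iterate(
    g: Interactome,
    seeds: GeneSet,
    n_iterations: int,
    omega: int = 1,
) -> DiamondRun:
    """Run the iterative DIAMOnD expansion for ``n_iterations`` steps.

    Candidates are all non-module genes with at least one link into the
    module; per-candidate link counts are maintained incrementally as the
    module grows, and p-values are memoised within an iteration by
    (degree, links) since module size is fixed there.  If the candidate pool
    empties first the run stops short with a warning.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    seeds_in = set(seeds.ids) & g.nodes
    if not seeds_in:
        raise ValueError(f"no seed of {seeds.name!r} is present in network {g.name!r}")
    if len(seeds_in) < len(seeds.ids):
        logger.warning(
            "diamond_iterate(%s): %d of %d seeds absent from the network",
            seeds.name, len(seeds.ids) - len(seeds_in), len(seeds.ids),
        )
    N = g.n_nodes
    adj = g.graph
    module = set(seeds_in)
    # per-candidate links into the module, split by seed / non-seed endpoints
    ks_seed: dict[int, int] = {}
    ks_added: dict[int, int] = {}
    for s in module:
        for nb in adj.neighbors(s):
            if nb not in module:
                ks_seed[nb] = ks_seed.get(nb, 0) + 1

    steps: list[DiamondStep] = []
    n_seeds = len(seeds_in)
    for it in range(1, n_iterations + 1):
        if not ks_seed and not ks_added:
            logger.warning(
                "diamond_iterate(%s): candidate pool exhausted after %d of %d iterations",
                seeds.name, it - 1, n_iterations,
            )
            break
        s0 = len(module)
        cache: dict[tuple[int, int, int], float] = {}
        best = None
        candidates = set(ks_seed) | set(ks_added)
        for node in candidates:
            kseed = ks_seed.get(node, 0)
            ks = kseed + ks_added.get(node, 0)
            k = adj.degree[node]
            key = (k, ks, kseed if omega > 1 else 0)
            p = cache.get(key)
            if p is None:
                p = connectivity_pvalue(k, ks, s0, N, omega=omega,
                                        ks_seed=kseed, s_seed=n_seeds)
                cache[key] = p
            cand = (p, -ks, k, node)
            if best is None or cand < best:
                best = cand
        p, neg_ks, k, gene = best
        steps.append(DiamondStep(iteration=it, gene=gene, degree=k, ks=-neg_ks, p_connectivity=p))
        module.add(gene)
        ks_seed.pop(gene, None)
        ks_added.pop(gene, None)
        for nb in adj.neighbors(gene):
            if nb not in module:
                ks_added[nb] = ks_added.get(nb, 0) + 1

    return DiamondRun(
        seeds_in_network=GeneSet(name=f"{seeds.name}_in_network", ids=frozenset(seeds_in)),
        steps=tuple(steps),
        n_iterations_requested=n_iterations,
        omega=omega,
        network_size=N,
    )


def build_disease_module(
    name: str,
    g: Interactome,
    seeds: GeneSet,
    target_size: int,
    omega: int = 1,
) -> DiseaseModule:
    """Grow a module to ``target_size`` total members (seeds included).

    The number of DIAMOnD iterations is target_size minus the seeds present
    in the network; if the candidate pool empties first the module is
    returned at the achieved size with a warning.
    """
    n_seeds_in = len(set(seeds.ids) & g.nodes)
    if target_size < n_seeds_in:
        raise ValueError(
            f"target_size {target_size} is below the {n_seeds_in} seeds present in the network"
        )
    run = diamond_iterate(g, seeds, n_iterations=target_size - n_seeds_in, omega=omega)
    members = frozenset(run.seeds_in_network.ids) | frozenset(run.added_genes)
    return DiseaseModule(name=name, members=GeneSet(name=name, ids=members), provenance=run)


def module_core_genes(a: DiseaseModule, b: DiseaseModule) -> GeneSet:
    """Core genes shared by two disease modules (deterministic intersection)."""
    return GeneSet(name=f"core_{a.name}_{b.name}", ids=a.members.ids & b.members.ids)
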