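"""Hypergeometric over-representation analysis with the study filter profiles.

A query gene set is tested against each term of an annotation collection
(GO-style or KEGG-style, read from GMT).  For a query of n genes inside an
N-gene background and a term of K genes, an observed overlap of k genes has
upper-tail probability P(X >= k) under Hypergeom(N, K, n), and enrichment
factor (k/n) / (K/N) — observed over expected overlap.

Two filter profiles are applied to flag significant terms:

* ``go``:   raw p < 0.01, overlap count >= 3 and enrichment factor > 1.5;
* ``kegg``: raw p < 0.05.

Benjamini-Hochberg adjusted p-values are always reported alongside the raw
ones; terms with zero overlap are omitted from the output but still count
toward the number of tests in the adjustment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, _parse_gmt_line
from .interactome import ParseError

logger = logging.getLogger(__name__)

PROFILES = ("go", "kegg")
GO_MAX_P = 0.01
GO_MIN_COUNT = 3
GO_MIN_FACTOR = 1.5
KEGG_MAX_P = 0.05


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    members: frozenset[int]


@dataclass(frozen=True)
class AnnotationCollection:
    """A list of annotation terms over a common background universe."""

    terms: tuple[Term, ...]
    background: frozenset[int]

    def __post_init__(self):
        ids = [t.id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("annotation term ids must be unique")
        stray = set().union(*(t.members for t in self.terms)) - self.background if self.terms else set()
        if stray:
            raise ValueError(f"{len(stray)} term members outside the background universe")


def load_annotations(
    source: str | os.PathLike | IO[str],
    background: Sequence[int] | None = None,
) -> AnnotationCollection:
    """Read a GMT file (``term<TAB>description<TAB>id...`` per line).

    The background defaults to the union of all term members; pass an
    explicit universe (e.g. the network nodes) to override.
    """
    close = isinstance(source, (str, os.PathLike))
    handle = open(source, "r", encoding="utf-8") if close else source
    try:
        terms: list[Term] = []
        for raw in handle:
            if not raw.strip() or raw.startswith("#"):
                continue
            tid, desc, ids = _parse_gmt_line(raw)
            terms.append(Term(id=tid, name=desc, members=frozenset(ids)))
    finally:
        if close:
            handle.close()
    if not terms:
        raise ParseError("GMT source contains no terms")
    universe = frozenset(background) if background is not None \
        else frozenset().union(*(t.members for t in terms))
    return AnnotationCollection(terms=tuple(terms), background=universe)


def write_annotations(ann: AnnotationCollection, path: str | os.PathLike | IO[str]) -> None:
    close = isinstance(path, (str, os.PathLike))
    handle = open(path, "w", encoding="utf-8") if close else path
    try:
        for t in ann.terms:
            members = "\t".join(str(g) for g in sorted(t.members))
            handle.write(f"{t.id}\t{t.name}\t{members}\n")
    finally:
        if close:
            handle.close()


def hypergeom_overrep_p(k: int, n_query: int, K_term: int, N: int) -> float:
    """Upper-tail P(X >= k) for overlap of an n-gene query with a K-gene term."""
    if not (0 <= k <= min(n_query, K_term) <= N):
        raise ValueError(
            f"need 0 <= k <= min(n_query, K_term) <= N; got k={k}, "
            f"n_query={n_query}, K_term={K_term}, N={N}"
        )
    if max(n_query, K_term) > N:
        raise ValueError("query and term must fit inside the background")
    return float(hypergeom.sf(k - 1, N, K_term, n_query))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    n_query: int
    K_term: int
    N: int
    p_raw: float
    p_adj: float
    enrichment_factor: float
    passes_go_filter: bool
    passes_kegg_filter: bool
    overlap_genes: tuple[int, ...]


def enrich(
    query: GeneSet,
    ann: AnnotationCollection,
    profile: str = "go",
) -> list[EnrichmentRow]:
    """Over-representation analysis of a query set against every term.

    The query is restricted to the background before counting.  One row is
    returned per term with k >= 1, sorted by raw p then term id; BH
    adjustment is computed over *all* terms (zero-overlap terms score p = 1).
    The ``profile`` argument only logs which filter a caller cares about;
    both pass/fail flags are always populated.
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}, got {profile!r}")
    q = set(query.ids) & set(ann.background)
    if not q:
        raise ValueError(f"query {query.name!r} does not overlap the annotation background")
    n_query, N = len(q), len(ann.background)
    ks = [len(q & t.members) for t in ann.terms]
    p_raw = [hypergeom_overrep_p(k, n_query, len(t.members), N)
             for k, t in zip(ks, ann.terms)]
    p_adj = bh_adjust(p_raw)
    rows: list[EnrichmentRow] = []
    for t, k, pr, pa in zip(ann.terms, ks, p_raw, p_adj):
        if k < 1:
            continue
        K = len(t.members)
        factor = (k / n_query) / (K / N)
        rows.append(EnrichmentRow(
            term_id=t.id, term_name=t.name, k=k, n_query=n_query, K_term=K, N=N,
            p_raw=pr, p_adj=float(pa), enrichment_factor=factor,
            passes_go_filter=(pr < GO_MAX_P and k >= GO_MIN_COUNT and factor > GO_MIN_FACTOR),
            passes_kegg_filter=(pr < KEGG_MAX_P),
            overlap_genes=tuple(sorted(q & t.members)),
        ))
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | os.PathLike | IO[str]) -> None:
    close = isinstance(path, (str, os.PathLike))
    handle = open(path, "w", encoding="utf-8") if close else path
    try:
        handle.write("term_id\tterm_name\tk\tn_query\tK_term\tN\tp_raw\tp_adj\t"
                     "enrichment_factor\tpasses_go_filter\tpasses_kegg_filter\toverlap_genes\n")
        for r in rows:
            handle.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n_query}\t{r.K_term}\t{r.N}\t"
                f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{r.enrichment_factor:.6g}\t"
                f"{r.passes_go_filter}\t{r.passes_kegg_filter}\t"
                f"{','.join(map(str, r.overlap_genes))}\n"
            )
    finally:
        if close:
            handle.close()
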