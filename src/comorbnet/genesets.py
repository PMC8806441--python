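"""Disease/phenotype gene sets: loading, network restriction and overlaps.

Gene lists for each phenotype (e.g. hypertension, NAFLD, inflammation,
fibrosis) are plain sets of integer gene identifiers.  This module reads
them from one-id-per-line files or GMT lines, restricts them to a network
before topological analysis, and computes exact multi-way (Venn) overlap
partitions and pairwise overlap percentages.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import IO, Iterable, Iterator, Sequence

from .interactome import Interactome, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named set of positive-integer gene identifiers."""

    name: str
    ids: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(int(g) for g in self.ids))
        if any(g <= 0 for g in self.ids):
            raise ValueError(f"gene set {self.name!r} contains non-positive identifiers")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.ids))

    def __contains__(self, gene: int) -> bool:
        return gene in self.ids


def _parse_gmt_line(line: str) -> tuple[str, str, list[int]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError("GMT line needs at least 3 tab-separated fields (name, description, ids)")
    try:
        ids = [int(f) for f in fields[2:] if f.strip()]
    except ValueError:
        raise ParseError(f"GMT line {fields[0]!r}: non-integer gene identifier") from None
    return fields[0], fields[1], ids


def load_gene_set(source: str | os.PathLike | IO[str], name: str | None = None) -> GeneSet:
    """Load a gene set from a one-id-per-line file or a single GMT line.

    A line whose first tab-field is not an integer is treated as a GMT record
    (``term<TAB>description<TAB>id...``); otherwise the first whitespace
    column of each non-comment line is parsed as an identifier.  Duplicates
    are collapsed with a logged count; zero identifiers is an error.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        if name is None:
            name = os.path.splitext(os.path.basename(os.fspath(source)))[0]
        handle: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        ids: list[int] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            first = line.split("\t")[0].split()[0]
            try:
                int(first)
            except ValueError:
                gmt_name, _, gmt_ids = _parse_gmt_line(line)
                ids.extend(gmt_ids)
                if name is None:
                    name = gmt_name
                continue
            try:
                ids.append(int(line.split()[0]))
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer gene identifier") from None
        if not ids:
            raise ParseError("gene set source contains no identifiers")
        unique = frozenset(ids)
        n_dup = len(ids) - len(unique)
        if n_dup:
            logger.info("load_gene_set(%s): removed %d duplicate identifiers", name, n_dup)
        return GeneSet(name=name or "geneset", ids=unique)
    finally:
        if close:
            handle.close()


def write_gene_set(s: GeneSet, path: str | os.PathLike | IO[str]) -> None:
    close = False
    if isinstance(path, (str, os.PathLike)):
        handle: IO[str] = open(path, "w", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        for g in s:
            handle.write(f"{g}\n")
    finally:
        if close:
            handle.close()


def restrict_to_network(s: GeneSet, g: Interactome) -> tuple[GeneSet, set[int]]:
    """Intersect a gene set with the network nodes.

    Returns the restricted set and the dropped identifiers; a warning is
    logged when genes are dropped and an empty intersection is an error
    (downstream distance statistics would be undefined).
    """
    kept = s.ids & g.nodes
    dropped = set(s.ids) - kept
    if not kept:
        raise ValueError(f"no gene of set {s.name!r} is present in network {g.name!r}")
    if dropped:
        logger.warning(
            "restrict_to_network(%s): %d of %d genes absent from network %r",
            s.name, len(dropped), len(s), g.name,
        )
    return GeneSet(name=s.name, ids=frozenset(kept)), dropped


@dataclass(frozen=True)
class VennPartition:
    """Exact exclusive-region partition of 2-4 gene sets.

    ``regions`` maps each nonempty subset of set names (as a frozenset) to
    the genes belonging to exactly those sets; regions are disjoint and
    their union is the union of all inputs.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset, tuple[int, ...]] = field(repr=False)

    def count(self, *names: str) -> int:
        return len(self.regions[frozenset(names)])

    def members(self, *names: str) -> tuple[int, ...]:
        return self.regions[frozenset(names)]

    def to_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        close = False
        if isinstance(path, (str, os.PathLike)):
            handle: IO[str] = open(path, "w", encoding="utf-8")
            close = True
        else:
            handle = path
        try:
            handle.write("region\tcount\tmembers\n")
            for r in sorted(self.regions, key=lambda fs: (len(fs), sorted(fs))):
                members = self.regions[r]
                label = "&".join(sorted(r, key=self.set_names.index))
                handle.write(f"{label}\t{len(members)}\t{','.join(map(str, members))}\n")
        finally:
            if close:
                handle.close()


def multiway_overlap(sets: Sequence[GeneSet]) -> VennPartition:
    """Exact Venn partition of 2-4 named gene sets (all 2^k - 1 regions)."""
    k = len(sets)
    if not 2 <= k <= 4:
        raise ValueError(f"multiway_overlap takes 2-4 sets, got {k}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != k:
        raise ValueError(f"gene set names must be distinct, got {names}")
    regions: dict[frozenset, list[int]] = {}
    for r in range(1, k + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = []
    by_name = {s.name: s.ids for s in sets}
    universe = set().union(*(s.ids for s in sets))
    for gene in sorted(universe):
        membership = frozenset(n for n in names if gene in by_name[n])
        regions[membership].append(gene)
    return VennPartition(set_names=names, regions={r: tuple(m) for r, m in regions.items()})


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap count and percentages (half-up rounded to 2 decimals).

    ``frac_of_a``/``frac_of_b`` retain full precision.
    """

    count: int
    pct_of_a: float
    pct_of_b: float
    frac_of_a: float
    frac_of_b: float


def overlap_percentages(a: GeneSet, b: GeneSet) -> OverlapResult:
    """Shared-gene count and the share of each set it represents.

    E.g. 13 genes shared between a 71-gene and a 212-gene list account for
    18.31% of the first and 6.13% of the second.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap_percentages requires nonempty sets")
    count = len(a.ids & b.ids)
    fa, fb = count / len(a), count / len(b)
    return OverlapResult(
        count=count,
        pct_of_a=_round2(100.0 * fa),
        pct_of_b=_round2(100.0 * fb),
        frac_of_a=fa,
        frac_of_b=fb,
    )
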