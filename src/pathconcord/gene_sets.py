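"""Gene-set collections: GMT I/O, size filtering, and collection-level summaries.

A *gene set* (pathway) is a named set of gene symbols; a *collection* is an
ordered list of uniquely named sets (e.g. the curated Biocarta/KEGG/Reactome
pathways distributed as a GMT file).  Gene symbols are opaque, case-sensitive
strings; no alias resolution is attempted.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "overlap_coefficient_matrix",
    "membership_summary",
    "intersect_significant",
    "VennResult",
]


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: a non-empty set of gene symbols plus a description."""

    name: str
    description: str = ""
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        genes = frozenset(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def restricted(self, background: Iterable[str]) -> "GeneSet":
        """Return a copy with membership intersected with *background*."""
        kept = self.genes & frozenset(background)
        if not kept:
            raise ValueError(
                f"gene set {self.name!r} has no genes in the background"
            )
        return GeneSet(self.name, self.description, kept)


class GeneSetCollection:
    """Ordered list of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            seen, dupes = set(), set()
            for n in names:
                (dupes if n in seen else seen).add(n)
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")
        self._by_name = {s.name: s for s in self.sets}

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def universe_genes(self) -> frozenset:
        """Exact union of all member genes."""
        if not self.sets:
            return frozenset()
        return frozenset(itertools.chain.from_iterable(s.genes for s in self.sets))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key) -> GeneSet:
        if isinstance(key, str):
            return self._by_name[key]
        return self.sets[key]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return [(s.name, s.description, s.genes) for s in self.sets] == [
            (s.name, s.description, s.genes) for s in other.sets
        ]

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets, {len(self.universe_genes)} genes)"


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Duplicate gene symbols within a line are deduplicated with a warning;
    a line with fewer than three fields, or a duplicate set name, is a hard
    error naming the offending line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d: set %r contains %d duplicate gene symbols "
                    "(deduplicated)",
                    path, lineno, name, len(genes) - len(unique),
                )
            sets.append(GeneSet(name, description, unique))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write *collection* as a GMT file (genes sorted within each line)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 500,
    background: Iterable[str] | None = None,
):
    """Restrict sets to *background* genes, then drop sets outside [min, max].

    This mirrors how a preranked GSEA engine handles its gene-set database:
    membership is first intersected with the genes actually measured (the
    ranked list), then the intersected size is tested against the bounds.
    Retained sets carry the restricted membership.

    Returns ``(filtered_collection, dropped_report)`` where the report is a
    DataFrame with columns ``set, original_size, restricted_size, reason``.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got {min_size}, {max_size}")
    if background is None:
        raise ValueError("a non-empty background of measured/scored genes is required")
    bg = frozenset(background)
    if not bg:
        raise ValueError("background is empty")

    kept: list[GeneSet] = []
    dropped: list[tuple[str, int, int, str]] = []
    for s in collection:
        restricted = s.genes & bg
        n = len(restricted)
        if n < min_size:
            dropped.append((s.name, len(s), n, "too_small"))
        elif n > max_size:
            dropped.append((s.name, len(s), n, "too_large"))
        else:
            kept.append(GeneSet(s.name, s.description, restricted))
    if dropped:
        logger.info("filter_by_size dropped %d of %d sets", len(dropped), len(collection))
    report = pd.DataFrame(
        dropped, columns=["set", "original_size", "restricted_size", "reason"]
    )
    return GeneSetCollection(kept), report


def overlap_coefficient_matrix(
    collection: GeneSetCollection, threshold: float = 0.01
):
    """Szymkiewicz–Simpson overlap coefficients between all set pairs.

    Entry (i, j) is ``|Gi ∩ Gj| / min(|Gi|, |Gj|)``; the diagonal is 1 and the
    matrix is symmetric.  Also returns the fraction of off-diagonal entries
    below *threshold* — a reporting hook for characterising how disjoint a
    pathway database is.

    Returns ``(matrix, fraction_below_threshold)`` with the matrix as a
    DataFrame indexed by set name.
    """
    if len(collection) < 2:
        raise ValueError("need at least two sets")
    genes = sorted(collection.universe_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    m = np.zeros((len(collection), len(genes)), dtype=bool)
    for i, s in enumerate(collection):
        for g in s.genes:
            m[i, gene_index[g]] = True
    inter = (m.astype(np.int64) @ m.T.astype(np.int64)).astype(float)
    sizes = m.sum(axis=1)
    min_sizes = np.minimum.outer(sizes, sizes)
    coef = inter / min_sizes
    np.fill_diagonal(coef, 1.0)
    off = ~np.eye(len(collection), dtype=bool)
    frac_below = float(np.mean(coef[off] < threshold))
    mat = pd.DataFrame(coef, index=collection.names, columns=collection.names)
    return mat, frac_below


def membership_summary(collection: GeneSetCollection, k: int = 3):
    """Per-gene set-membership counts plus the shared/unique tallies.

    Returns ``(table, summary)``: *table* has columns ``gene, n_sets`` (sorted
    by gene symbol); *summary* is a dict with ``unique_to_one`` (genes in
    exactly one set) and ``in_more_than_k`` (genes in strictly more than *k*
    sets, default k=3).
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    counts: dict[str, int] = {}
    for s in collection:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["gene", "n_sets"]
    )
    summary = {
        "k": k,
        "unique_to_one": int((table["n_sets"] == 1).sum()),
        "in_more_than_k": int((table["n_sets"] > k).sum()),
    }
    return table, summary


@dataclass
class VennResult:
    """Regionwise intersection of m named lists of gene-set names.

    ``cells`` maps each non-empty membership pattern (frozenset of list
    names) to its exclusive count; ``cell_names`` holds the names in each
    cell; ``full_intersection`` is the sorted list of names present in every
    input list.
    """

    list_names: list[str]
    full_intersection: list[str]
    cells: dict
    cell_names: dict

    @property
    def union_size(self) -> int:
        return sum(self.cells.values())


def intersect_significant(lists: Mapping[str, Sequence[str]]) -> VennResult:
    """All 2^m − 1 Venn cell counts and the full intersection of m lists."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    as_sets: dict[str, set] = {}
    for lname, members in lists.items():
        members = list(members)
        if len(set(members)) != len(members):
            raise ValueError(f"list {lname!r} contains duplicate names")
        as_sets[lname] = set(members)
    list_names = list(as_sets)
    universe = set().union(*as_sets.values())
    cells: dict[frozenset, int] = {}
    cell_names: dict[frozenset, list] = {}
    for item in universe:
        pattern = frozenset(l for l in list_names if item in as_sets[l])
        cells[pattern] = cells.get(pattern, 0) + 1
        cell_names.setdefault(pattern, []).append(item)
    for names in cell_names.values():
        names.sort()
    full = sorted(set.intersection(*as_sets.values()))
    return VennResult(list_names, full, cells, cell_names)
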