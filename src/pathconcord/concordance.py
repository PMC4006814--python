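"""Cross-modal concordance: intersect per-dataset expression pathway lists
and test their overlap with GWAS-significant pathways.

The two arms of the study produce pathway name lists drawn from one shared
collection.  The expression lists are intersected across datasets (by
direction), and the common list is compared with the GWAS list by an
upper-tail hypergeometric test over the collection as the universe: under
the null of independent draws, the number of shared pathways k follows
Hypergeom(N = collection size, K = |expression list|, n = |GWAS list|).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .gene_sets import VennResult, intersect_significant

logger = logging.getLogger(__name__)

__all__ = ["OverlapResult", "ConcordanceReport", "cross_modal_overlap", "build_report"]


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two pathway name lists."""

    n_universe: int
    n_expression: int
    n_gwas: int
    k: int
    p_hyper: float


@dataclass
class ConcordanceReport:
    """Full cross-modal report.

    up / down : Venn intersections of the per-dataset significant lists.
    gwas_significant : pathway names flagged by the GWAS arm.
    overlap : hypergeometric test of the common expression list (direction
        chosen at build time) against the GWAS list.
    flags : per-set table with in_expression / in_gwas / in_both booleans.
    """

    up: VennResult
    down: VennResult
    gwas_significant: list
    overlap: OverlapResult
    direction: str
    flags: pd.DataFrame


def cross_modal_overlap(
    expr_sets: Iterable[str], gwas_sets: Iterable[str], universe_size: int
) -> OverlapResult:
    """Upper-tail hypergeometric P for the overlap of two pathway lists.

    ``k = |expr ∩ gwas|`` and ``p = P[X >= k]`` with
    ``X ~ Hypergeom(N = universe_size, K = |expr|, n = |gwas|)``; the test is
    symmetric in the two lists.  The universe must contain their union.
    """
    expr = frozenset(expr_sets)
    gwas = frozenset(gwas_sets)
    if universe_size < len(expr | gwas):
        raise ValueError(
            f"universe_size {universe_size} smaller than the union "
            f"({len(expr | gwas)})"
        )
    k = len(expr & gwas)
    if k == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(expr), len(gwas)))
    return OverlapResult(universe_size, len(expr), len(gwas), k, p)


def build_report(
    expr_significant: Mapping[str, Mapping[str, Sequence[str]]],
    gwas_significant: Sequence[str],
    universe: Sequence[str] | int,
    direction: str = "up",
) -> ConcordanceReport:
    """Assemble the cross-modal concordance report.

    expr_significant : dataset name -> {"up": [...], "down": [...]} pathway
        lists (at least two datasets).
    gwas_significant : GWAS-significant pathway names.
    universe : the full collection's set names (used for the flags table and
        the universe size), or just the collection size.
    direction : which common expression list to test against GWAS — "up"
        (default), "down", or "both" (union of the two common lists).
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    up = intersect_significant({d: v["up"] for d, v in expr_significant.items()})
    down = intersect_significant({d: v["down"] for d, v in expr_significant.items()})
    if direction == "up":
        common = list(up.full_intersection)
    elif direction == "down":
        common = list(down.full_intersection)
    else:
        common = sorted(set(up.full_intersection) | set(down.full_intersection))

    if isinstance(universe, int):
        universe_size = universe
        universe_names = None
    else:
        universe_names = list(universe)
        universe_size = len(universe_names)
    overlap = cross_modal_overlap(common, gwas_significant, universe_size)

    if universe_names is None:
        universe_names = sorted(set(common) | set(gwas_significant))
    expr_set = set(common)
    gwas_set = set(gwas_significant)
    flags = pd.DataFrame(
        {
            "set": universe_names,
            "in_expression": [s in expr_set for s in universe_names],
            "in_gwas": [s in gwas_set for s in universe_names],
        }
    )
    flags["in_both"] = flags["in_expression"] & flags["in_gwas"]
    return ConcordanceReport(
        up=up,
        down=down,
        gwas_significant=sorted(gwas_set),
        overlap=overlap,
        direction=direction,
        flags=flags,
    )
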