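"""GWAS arm: SNP-to-gene scoring, per-cohort hypergeometric pathway
enrichment, cross-cohort meta-combination, and Benjamini–Hochberg control.

Each cohort contributes per-SNP association P-values.  A gene's region is its
annotated boundary extended by a flank (100 kb by default); the gene-level P
is the minimal SNP P in the region, Bonferroni-adjusted by the number of SNPs
in the region and capped at 1.  Genes at adjusted P <= alpha form the
"significant" class, and each pathway is tested for over-representation of
significant genes by an upper-tail hypergeometric test within the cohort's
tested-gene universe.  Per-cohort pathway P-values are combined (Fisher by
default) and the meta P-values are BH-adjusted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_sets import GeneSetCollection, filter_by_size

logger = logging.getLogger(__name__)

__all__ = [
    "read_snp_stats",
    "read_gene_regions",
    "assign_snps_to_genes",
    "gene_level_p",
    "build_gene_scores",
    "classify_genes",
    "pathway_enrichment",
    "combine_cohorts",
    "bh_fdr",
    "run_gwas_arm",
    "GwasArmResult",
]

_TINY_P = 1e-300  # floor applied before log-based combination


def read_snp_stats(path) -> pd.DataFrame:
    """Read association summary statistics (columns SNP, CHR, BP, P).

    Whitespace- or tab-delimited with a header, the dialect of PLINK
    ``.assoc`` output.  Rows with a missing P or P outside (0, 1] are
    rejected (counts logged); a missing required column is a hard error.
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = ["SNP", "CHR", "BP", "P"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[required].copy()
    df["P"] = pd.to_numeric(df["P"], errors="coerce")
    bad = df["P"].isna() | (df["P"] <= 0) | (df["P"] > 1)
    if bad.any():
        logger.info("%s: rejected %d rows with invalid P", path, int(bad.sum()))
    df = df[~bad].reset_index(drop=True)
    df.columns = ["snp", "chrom", "pos", "p"]
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    return df


def read_gene_regions(path, bed: bool | None = None) -> pd.DataFrame:
    """Read gene regions as (gene, chrom, start, end), 1-based inclusive.

    A ``.bed`` file (0-based, half-open, columns chrom/start/end/name) is
    converted on read; otherwise a header-less tab-delimited table with
    columns gene, chrom, start, end is expected.
    """
    path = str(path)
    if bed is None:
        bed = path.endswith(".bed")
    if bed:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
        )
        df["start"] = df["start"].astype(int) + 1
        df = df[["gene", "chrom", "start", "end"]]
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene", "chrom", "start", "end"]
        )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: region with start > end")
    return df


def assign_snps_to_genes(
    snps: pd.DataFrame, regions: pd.DataFrame, flank: int = 100_000
) -> dict:
    """Map each gene to the P-values of SNPs inside its flanked region.

    A SNP belongs to a gene iff it lies on the same chromosome and within
    ``[max(1, start - flank), end + flank]`` (inclusive).  A SNP may belong
    to several genes; genes with no assigned SNP are omitted.  Coordinates
    are assumed to share one assembly.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, snp_grp in snps.groupby("chrom", sort=False):
        pos = snp_grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        p_sorted = snp_grp["p"].to_numpy()[order]
        reg = regions[regions["chrom"] == chrom]
        for gene, start, end in zip(reg["gene"], reg["start"], reg["end"]):
            lo = max(1, int(start) - flank)
            hi = int(end) + flank
            i = np.searchsorted(pos_sorted, lo, side="left")
            j = np.searchsorted(pos_sorted, hi, side="right")
            if j > i:
                out[gene] = p_sorted[i:j].copy()
    return out


def gene_level_p(snp_ps: Sequence[float]) -> float:
    """Min-P Bonferroni gene score: ``min(1, min(p) * n_snps)``."""
    ps = np.asarray(list(snp_ps), float)
    if ps.size == 0:
        raise ValueError("gene has no SNP p-values")
    return float(min(1.0, ps.min() * ps.size))


def build_gene_scores(assignments: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Gene score table: n_snps, min_p, adj_p and the significance call.

    ``significant`` uses the inclusive convention ``adj_p <= alpha``.
    """
    rows = []
    for gene in sorted(assignments):
        ps = np.asarray(list(assignments[gene]), float)
        adj = gene_level_p(ps)
        rows.append((gene, ps.size, float(ps.min()), adj, adj <= alpha))
    return pd.DataFrame(
        rows, columns=["gene", "n_snps", "min_p", "adj_p", "significant"]
    )


def classify_genes(scores: pd.DataFrame, alpha: float = 0.05):
    """Partition scored genes into (significant, non-significant) sets."""
    if len(scores) == 0:
        raise ValueError("empty gene score table")
    sig = scores["adj_p"] <= alpha
    return set(scores.loc[sig, "gene"]), set(scores.loc[~sig, "gene"])


def _hypergeom_sf(k: int, n_universe: int, n_set: int, n_draw: int) -> float:
    """Upper tail P[X >= k], X ~ Hypergeom(N, K, n); survival at k - 1."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_draw))


def pathway_enrichment(
    significant: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_size: int | None = None,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Per-set hypergeometric over-representation of significant genes.

    For each set with at least one gene in *universe*, reports
    ``k`` (significant member genes), ``K`` (member genes in the universe),
    ``n`` (significant genes), ``N`` (universe size) and the upper-tail
    hypergeometric ``p_hyper`` = P[X >= k].  Sets with no universe overlap
    are skipped.  An optional [min_size, max_size] filter on K can be
    applied (off by default: the multiple-testing family is then every set
    with tested genes).
    """
    universe = frozenset(universe)
    significant = frozenset(significant)
    if not significant <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    n_universe = len(universe)
    n_sig = len(significant)
    if n_sig == 0:
        logger.warning("no significant genes; every pathway p is 1")
    rows = []
    for s in collection:
        members = s.genes & universe
        big_k = len(members)
        if big_k == 0:
            continue
        if min_size is not None and big_k < min_size:
            continue
        if max_size is not None and big_k > max_size:
            continue
        k = len(members & significant)
        p = _hypergeom_sf(k, n_universe, big_k, n_sig)
        rows.append((s.name, k, big_k, n_sig, n_universe, max(p, _TINY_P)))
    return pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p_hyper"])


def combine_cohorts(per_cohort_p: Sequence[float], method: str = "fisher") -> float:
    """Combine independent per-cohort P-values into one meta P.

    ``fisher`` (default): X^2 = -2 * sum(ln p) referred to chi-square with
    2m degrees of freedom.  ``stouffer``: equal-weight inverse-normal.
    A single cohort returns its own p unchanged; p = 0 is a hard error
    (upstream flooring prevents it).
    """
    ps = np.asarray(list(per_cohort_p), float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if ps.size == 1:
        return float(ps[0])
    if method == "fisher":
        x2 = -2.0 * np.log(ps).sum()
        return float(stats.chi2.sf(x2, 2 * ps.size))
    if method == "stouffer":
        z = stats.norm.isf(np.clip(ps, _TINY_P, 1 - 1e-16))
        return float(stats.norm.sf(z.sum() / np.sqrt(ps.size)))
    raise ValueError(f"unknown combination method {method!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    ps = np.asarray(list(p_values), float)
    if ps.size == 0:
        return ps
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]


@dataclass
class GwasArmResult:
    """Outputs of the full GWAS arm.

    meta : per-set table with per-cohort p columns, meta_p, bh_q, significant.
    per_cohort : cohort name -> per-set enrichment table (k, K, n, N, p_hyper).
    gene_scores : cohort name -> per-gene score table.
    """

    meta: pd.DataFrame
    per_cohort: dict
    gene_scores: dict

    def significant_sets(self) -> list[str]:
        return sorted(self.meta.loc[self.meta["significant"], "set"])


def run_gwas_arm(
    cohorts,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    flank: int = 100_000,
    fdr: float = 0.05,
    combine: str = "fisher",
    min_size: int | None = None,
    max_size: int | None = None,
) -> GwasArmResult:
    """Run the GWAS pathway arm over one or more cohorts.

    *cohorts* is a mapping name -> (snp_stats, regions) or a sequence of such
    pairs (auto-named cohort1, cohort2, ...).  Per cohort: SNPs are assigned
    to flanked gene regions, gene-level min-P Bonferroni scores are computed,
    the universe is the set of scored genes that belong to at least one
    collection set, and each pathway is tested hypergeometrically.  Pathway
    P-values are then combined across cohorts and BH-adjusted; a pathway is
    significant when ``bh_q < fdr``.
    """
    if not isinstance(cohorts, Mapping):
        cohorts = {f"cohort{i + 1}": c for i, c in enumerate(cohorts)}
    if len(cohorts) == 0:
        raise ValueError("at least one cohort is required")

    pathway_universe = collection.universe_genes
    per_cohort: dict[str, pd.DataFrame] = {}
    gene_scores: dict[str, pd.DataFrame] = {}
    for name, (snps, regions) in cohorts.items():
        assignments = assign_snps_to_genes(snps, regions, flank)
        if not assignments:
            raise ValueError(f"cohort {name!r}: no SNP maps to any gene region")
        scores = build_gene_scores(assignments, alpha)
        universe = set(scores["gene"]) & pathway_universe
        sig = set(scores.loc[scores["significant"], "gene"]) & universe
        enr = pathway_enrichment(sig, universe, collection, min_size, max_size)
        per_cohort[name] = enr
        gene_scores[name] = scores

    all_sets: list[str] = []
    for enr in per_cohort.values():
        for s in enr["set"]:
            if s not in all_sets:
                all_sets.append(s)
    cohort_p = pd.DataFrame(index=all_sets)
    for name, enr in per_cohort.items():
        cohort_p[f"p_{name}"] = enr.set_index("set")["p_hyper"]

    meta_p = [
        combine_cohorts(row.dropna().to_numpy(), combine)
        for _, row in cohort_p.iterrows()
    ]
    meta = cohort_p.reset_index(names="set")
    meta["meta_p"] = np.maximum(meta_p, _TINY_P)
    meta["bh_q"] = bh_fdr(meta["meta_p"])
    meta["significant"] = meta["bh_q"] < fdr
    meta = meta.sort_values(["meta_p", "set"]).reset_index(drop=True)
    return GwasArmResult(meta=meta, per_cohort=per_cohort, gene_scores=gene_scores)
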