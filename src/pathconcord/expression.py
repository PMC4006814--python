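"""Expression datasets, probe collapsing, moderated-t ranking, and RNK I/O.

The expression arm starts from a feature × sample matrix with a two-group
design (e.g. healthy control vs. active-disease biopsies).  Probes are
collapsed to gene symbols, genes are scored by a moderated t-statistic, and
the resulting signed rank list feeds the preranked enrichment engine in
:mod:`pathconcord.gsea`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "RankedList",
    "collapse_probes",
    "rank_genes",
    "read_rnk",
    "write_rnk",
    "read_expression_matrix",
    "read_labels",
    "read_feature_map",
]


@dataclass
class ExpressionDataset:
    """A feature × sample expression matrix with a two-group design.

    values : DataFrame, rows are probes or genes, columns are samples.
    labels : Series mapping sample id -> group tag (exactly two groups,
        each with at least two samples).
    feature_to_gene : optional mapping row id -> gene symbol, required for
        probe collapsing; ``None`` once the matrix is keyed by gene.
    """

    values: pd.DataFrame
    labels: pd.Series
    feature_to_gene: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        missing = [c for c in self.values.columns if c not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.labels = self.labels.loc[list(self.values.columns)]
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        groups = self.labels.value_counts()
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, got {list(groups.index)}")
        if (groups < 2).any():
            raise ValueError("each group needs at least two samples")

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())


def collapse_probes(dataset: ExpressionDataset, mode: str = "maxprobe") -> ExpressionDataset:
    """Collapse a probe-level matrix to gene symbols.

    ``mode="maxprobe"`` (default) takes, for each gene and each sample, the
    maximum value over that gene's probes.  ``mode="max_mean_probe"`` instead
    keeps the single probe with the highest mean across samples.  Features
    with no gene mapping are dropped (count logged).
    """
    if not dataset.feature_to_gene:
        raise ValueError("collapse_probes requires a feature -> gene mapping")
    mapping = dataset.feature_to_gene
    mapped = [f for f in dataset.values.index if f in mapping]
    n_dropped = len(dataset.values.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d features with no gene mapping", n_dropped)
    if not mapped:
        raise ValueError("no feature maps to a gene symbol")
    sub = dataset.values.loc[mapped]
    genes = pd.Index([mapping[f] for f in mapped], name="gene")
    if mode == "maxprobe":
        collapsed = sub.groupby(genes).max()
    elif mode == "max_mean_probe":
        means = sub.mean(axis=1)
        best = (
            pd.DataFrame({"gene": genes, "mean": means.to_numpy()}, index=sub.index)
            .sort_values(["gene", "mean"])
            .groupby("gene")
            .tail(1)
        )
        collapsed = sub.loc[best.index]
        collapsed.index = pd.Index(best["gene"], name="gene")
        collapsed = collapsed.sort_index()
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    return ExpressionDataset(collapsed, dataset.labels, feature_to_gene=None)


@dataclass
class RankedList:
    """Genes ordered by a signed score, highest first.

    Ties in score are broken lexicographically by gene symbol so that output
    is deterministic.  Gene symbols are unique.
    """

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.shape != self.scores.shape or self.genes.ndim != 1:
            raise ValueError("genes and scores must be 1-D and the same length")
        if np.isnan(self.scores).any():
            raise ValueError("scores contain NaN")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing; use from_unsorted")

    @classmethod
    def from_unsorted(cls, genes, scores) -> "RankedList":
        genes = np.asarray(genes, dtype=object)
        scores = np.asarray(scores, dtype=float)
        # lexsort: last key is primary -> descending score, ascending symbol
        order = np.lexsort((genes, -scores))
        return cls(genes[order], scores[order])

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


def rank_genes(
    dataset: ExpressionDataset,
    prior_df: float = 4.0,
    reference_group: str | None = None,
) -> RankedList:
    """Score genes by a moderated t-statistic and return the signed rank list.

    For gene g with pooled within-group variance s_g^2 on d_g = n1 + n2 - 2
    degrees of freedom, the variance is shrunk toward the median variance
    s0^2 over genes with a fixed prior weight d0 = *prior_df*:

        s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
        t_g    = (mean_case - mean_reference) / (s~_g * sqrt(1/n1 + 1/n2))

    This is a deliberately simplified empirical-Bayes shrinkage: the prior
    degrees of freedom are fixed rather than estimated from the data.  Any
    externally produced RNK list can be substituted via :func:`read_rnk`.

    *reference_group* defaults to the group of the first sample column (the
    usual layout lists the control samples first); positive scores mean
    higher expression in the non-reference (case) group.
    """
    if dataset.feature_to_gene is not None:
        raise ValueError("rank_genes expects a gene-level matrix; collapse probes first")
    groups = dataset.groups
    if reference_group is None:
        reference_group = str(dataset.labels.iloc[0])
    if reference_group not in groups:
        raise ValueError(f"unknown reference group {reference_group!r}")
    case_group = [g for g in groups if g != reference_group][0]

    ref_cols = dataset.labels.index[dataset.labels == reference_group]
    case_cols = dataset.labels.index[dataset.labels == case_group]
    x0 = dataset.values[ref_cols].to_numpy(float)
    x1 = dataset.values[case_cols].to_numpy(float)
    n0, n1 = x0.shape[1], x1.shape[1]

    diff = x1.mean(axis=1) - x0.mean(axis=1)
    v0 = x0.var(axis=1, ddof=1)
    v1 = x1.var(axis=1, ddof=1)
    dg = n0 + n1 - 2
    s2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / dg
    if np.all(s2 == 0):
        raise ValueError("zero variance in every gene; cannot rank")
    s0sq = float(np.median(s2))
    s2_tilde = (prior_df * s0sq + dg * s2) / (prior_df + dg)
    denom = np.sqrt(s2_tilde * (1.0 / n0 + 1.0 / n1))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        # a gene constant in both groups with zero mean difference scores 0
        t = np.where(
            denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
        )
    return RankedList.from_unsorted(dataset.values.index.to_numpy(object), t)


def read_rnk(path) -> RankedList:
    """Read a two-column RNK file (gene TAB score); returns a sorted list."""
    path = Path(path)
    genes: list[str] = []
    scores: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            gene, score = fields
            try:
                value = float(score)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {score!r}"
                ) from None
            genes.append(gene)
            scores.append(value)
    if len(set(genes)) != len(genes):
        raise ValueError(f"{path}: duplicate gene symbols in RNK file")
    return RankedList.from_unsorted(genes, scores)


def write_rnk(ranked: RankedList, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{float(score)!r}\n")


def read_expression_matrix(path) -> pd.DataFrame:
    """Tab-delimited matrix: first column feature id, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_labels(path) -> pd.Series:
    """Two-column label file: sample TAB group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return pd.Series(df["group"].to_numpy(), index=df["sample"], name="group")


def read_feature_map(path) -> dict:
    """Two-column mapping file: feature id TAB gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature", "gene"])
    return dict(zip(df["feature"], df["gene"]))
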