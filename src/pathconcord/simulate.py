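"""Synthetic study generator with planted pathway signals.

Generates every input the pipeline consumes — a gene-set collection over a
synthetic gene namespace, replicate two-group expression datasets, and
per-cohort GWAS summary statistics with gene-region annotations — together
with the ground truth of which pathways carry signal.  This makes each stage
of the dual-modality analysis testable for calibration (null configurations)
and parameter recovery (planted configurations).

Study shape defaults mirror the motivating design: three independent
expression datasets sharing the same planted up/down pathways, and eight
GWAS cohorts in which a fraction of each planted pathway's member genes
carry enriched small SNP P-values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .gene_sets import GeneSet, GeneSetCollection, write_gmt

__all__ = ["SimConfig", "SyntheticTruth", "StudyBundle", "make_collection",
           "make_truth", "make_gene_regions", "make_expression_dataset",
           "make_gwas_cohort", "make_study", "write_study"]


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions.

    Collection: *n_sets* sets over *n_genes* synthetic genes, set sizes
    log-uniform over *set_size_range*; *overlap_fraction* is the expected
    fraction of each set drawn from a small shared "hub" pool (0 gives only
    the random-chance overlap between sets).

    Expression: *n_expression_datasets* replicates; *samples_per_group* is
    an integer applied to both groups of every dataset (default 12, a
    representative biopsy-study size), a (controls, cases) pair, or one
    pair per dataset for unbalanced designs.  Member genes of planted
    up-sets gain *effect_size* standard deviations in the case group
    (down-sets lose it) on top of unit-variance Gaussian noise.

    GWAS: *n_cohorts* cohorts; each gene carries snps_per_gene SNPs drawn
    uniformly from *snps_per_gene_range*; within each planted GWAS pathway a
    *causal_gene_fraction* of member genes (fixed across cohorts) draw SNP
    P-values from Beta(*causal_beta_a*, 1) with a < 1 (enriched near 0),
    all other SNPs from Uniform(0, 1).

    Planting: *n_planted_up* / *n_planted_down* expression pathways and
    *n_planted_gwas* GWAS pathways.  With ``gwas_planting="concordant"``
    (default) the GWAS pathways are taken from the planted up-set list, the
    study's concordance scenario; ``"independent"`` plants disjoint sets.
    """

    n_genes: int = 1200
    n_sets: int = 200
    set_size_range: tuple = (15, 120)
    overlap_fraction: float = 0.0
    hub_fraction: float = 0.1

    n_expression_datasets: int = 3
    samples_per_group: int | tuple = 12
    effect_size: float = 0.8

    n_cohorts: int = 8
    snps_per_gene_range: tuple = (5, 50)
    causal_gene_fraction: float = 0.3
    causal_beta_a: float = 0.1

    n_planted_up: int = 10
    n_planted_down: int = 5
    n_planted_gwas: int = 10
    gwas_planting: str = "concordant"

    gene_body_length: int = 20_000
    gene_spacing: int = 110_000  # < body + flank, so neighbouring regions overlap
    genes_per_chromosome: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.set_size_range[1]:
            raise ValueError("n_genes must be at least the maximum set size")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 < self.causal_beta_a <= 1:
            raise ValueError("causal_beta_a must lie in (0, 1]")
        if not 0 <= self.causal_gene_fraction <= 1:
            raise ValueError("causal_gene_fraction must lie in [0, 1]")
        if self.gwas_planting not in ("concordant", "independent"):
            raise ValueError("gwas_planting must be 'concordant' or 'independent'")

    def group_sizes(self, dataset_index: int) -> tuple:
        sp = self.samples_per_group
        if isinstance(sp, int):
            return (sp, sp)
        if isinstance(sp[0], (tuple, list)):
            return tuple(sp[dataset_index % len(sp)])
        return (int(sp[0]), int(sp[1]))

    def gene_names(self) -> list:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study."""

    planted_up: list
    planted_down: list
    planted_gwas: list
    causal_genes: dict  # planted GWAS set name -> list of causal member genes
    config: SimConfig

    def causal_union(self) -> frozenset:
        out: set = set()
        for genes in self.causal_genes.values():
            out.update(genes)
        return frozenset(out)


def make_collection(config: SimConfig, rng: np.random.Generator) -> GeneSetCollection:
    """Draw the gene-set collection over the synthetic namespace.

    Set sizes are log-uniform integers in *set_size_range*.  When
    *overlap_fraction* > 0, that expected fraction of each set is drawn from
    a hub pool of ``hub_fraction * n_genes`` genes shared across sets, which
    raises the expected pairwise overlap coefficient; the remainder is drawn
    uniformly from the rest of the namespace.
    """
    genes = np.array(config.gene_names(), dtype=object)
    lo, hi = config.set_size_range
    if not 1 <= lo <= hi <= config.n_genes:
        raise ValueError("infeasible set size range")
    n_hub = max(1, int(round(config.hub_fraction * config.n_genes)))
    hub = genes[:n_hub]
    rest = genes[n_hub:]
    width = len(str(config.n_sets - 1))
    sets = []
    for i in range(config.n_sets):
        size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        size = min(max(size, lo), hi)
        k_hub = min(int(round(config.overlap_fraction * size)), n_hub)
        members = list(rng.choice(hub, size=k_hub, replace=False)) if k_hub else []
        members += list(rng.choice(rest, size=size - k_hub, replace=False))
        sets.append(GeneSet(f"SET{i:0{width}d}", f"synthetic pathway {i}", frozenset(members)))
    return GeneSetCollection(sets)


def make_truth(
    collection: GeneSetCollection, config: SimConfig, rng: np.random.Generator
) -> SyntheticTruth:
    """Choose the planted pathways and their causal genes (fixed per study)."""
    names = np.array(collection.names, dtype=object)
    n_expr = config.n_planted_up + config.n_planted_down
    if n_expr > len(names):
        raise ValueError("more planted expression sets than sets in the collection")
    chosen = list(rng.choice(names, size=n_expr, replace=False))
    planted_up = sorted(chosen[: config.n_planted_up])
    planted_down = sorted(chosen[config.n_planted_up:])

    if config.gwas_planting == "concordant":
        pool = planted_up + [n for n in names if n not in set(chosen)]
        planted_gwas = sorted(pool[: config.n_planted_gwas])
    else:
        remaining = np.array([n for n in names if n not in set(chosen)], dtype=object)
        if config.n_planted_gwas > remaining.size:
            raise ValueError("not enough unplanted sets for independent GWAS planting")
        planted_gwas = sorted(rng.choice(remaining, size=config.n_planted_gwas, replace=False))

    causal: dict[str, list] = {}
    for name in planted_gwas:
        members = sorted(collection[name].genes)
        n_causal = max(1, int(round(config.causal_gene_fraction * len(members)))) \
            if config.causal_gene_fraction > 0 else 0
        causal[name] = sorted(rng.choice(np.array(members, dtype=object),
                                         size=n_causal, replace=False)) if n_causal else []
    return SyntheticTruth(planted_up, planted_down, planted_gwas, causal, config)


def make_gene_regions(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene layout on synthetic chromosomes.

    Gene bodies are non-overlapping (*gene_body_length* long, spaced
    *gene_spacing* apart) but with the default 100 kb flank the regions of
    neighbouring genes overlap, so the one-SNP-to-many-genes assignment rule
    is exercised by default.  The first gene of each chromosome starts at
    position 1, so flank clipping at the chromosome start is exercised too.
    """
    rows = []
    for i, gene in enumerate(config.gene_names()):
        chrom = f"chr{i // config.genes_per_chromosome + 1}"
        start = 1 + (i % config.genes_per_chromosome) * config.gene_spacing
        rows.append((gene, chrom, start, start + config.gene_body_length - 1))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def make_expression_dataset(
    collection: GeneSetCollection,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator,
    dataset_index: int = 0,
) -> ExpressionDataset:
    """One two-group expression replicate with planted shifts.

    Background entries are N(0, 1).  Case-group means of genes belonging to
    any planted up-set are shifted by +effect_size; genes of planted
    down-sets by -effect_size (a gene in both kinds of planted set keeps the
    up shift).  Noise is independent across replicates.
    """
    genes = config.gene_names()
    n_ctrl, n_case = config.group_sizes(dataset_index)
    samples = [f"ctrl{j + 1}" for j in range(n_ctrl)] + [
        f"case{j + 1}" for j in range(n_case)
    ]
    x = rng.standard_normal((len(genes), len(samples)))

    up_genes: set = set()
    for name in truth.planted_up:
        up_genes |= collection[name].genes
    down_genes: set = set()
    for name in truth.planted_down:
        down_genes |= collection[name].genes
    down_genes -= up_genes

    idx = {g: i for i, g in enumerate(genes)}
    case_cols = slice(n_ctrl, None)
    for g in up_genes:
        x[idx[g], case_cols] += config.effect_size
    for g in down_genes:
        x[idx[g], case_cols] -= config.effect_size

    values = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    labels = pd.Series(
        ["control"] * n_ctrl + ["case"] * n_case, index=samples, name="group"
    )
    return ExpressionDataset(values, labels)


def make_gwas_cohort(
    collection: GeneSetCollection,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator,
    regions: pd.DataFrame | None = None,
):
    """One cohort's SNP association summaries plus the gene-region table.

    Every gene receives a uniform-random number of SNPs placed uniformly in
    its gene body.  SNPs of causal genes (fixed in *truth*) draw P-values
    from Beta(a, 1); all others from Uniform(0, 1).  Draws are independent
    across cohorts; the region table is the study-wide deterministic layout.
    """
    if regions is None:
        regions = make_gene_regions(config)
    causal = truth.causal_union()
    lo, hi = config.snps_per_gene_range
    rows = []
    snp_i = 0
    for gene, chrom, start, end in zip(
        regions["gene"], regions["chrom"], regions["start"], regions["end"]
    ):
        m = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.integers(start, end + 1, size=m))
        if gene in causal:
            ps = rng.beta(config.causal_beta_a, 1.0, size=m)
        else:
            ps = rng.random(m)
        ps = np.clip(ps, 1e-300, 1.0)
        for bp, p in zip(pos, ps):
            rows.append((f"rs{snp_i}", chrom, int(bp), float(p)))
            snp_i += 1
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])
    return snps, regions


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: SimConfig
    collection: GeneSetCollection
    truth: SyntheticTruth
    expression: list = field(default_factory=list)
    cohorts: dict = field(default_factory=dict)
    regions: pd.DataFrame | None = None


def make_study(config: SimConfig | None = None) -> StudyBundle:
    """Generate the full study: collection, expression replicates, cohorts.

    A pure function of the configuration (including its seed): component
    generators get independent child streams spawned from one seed sequence,
    so regenerating any part is reproducible.
    """
    if config is None:
        config = SimConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + config.n_expression_datasets + config.n_cohorts)
    coll_rng = np.random.default_rng(children[0])
    truth_rng = np.random.default_rng(children[1])
    collection = make_collection(config, coll_rng)
    truth = make_truth(collection, config, truth_rng)
    regions = make_gene_regions(config)

    expression = []
    for d in range(config.n_expression_datasets):
        rng = np.random.default_rng(children[2 + d])
        expression.append(
            make_expression_dataset(collection, truth, config, rng, dataset_index=d)
        )
    cohorts = {}
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(children[2 + config.n_expression_datasets + c])
        snps, _ = make_gwas_cohort(collection, truth, config, rng, regions)
        cohorts[f"cohort{c + 1}"] = (snps, regions)
    return StudyBundle(config, collection, truth, expression, cohorts, regions)


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write all study inputs in the formats the pipeline reads.

    GMT collection, per-dataset expression matrix + label files, per-cohort
    SNP stats (SNP/CHR/BP/P) + a shared region table, and the truth manifest.
    Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    gmt = outdir / "gene_sets.gmt"
    write_gmt(bundle.collection, gmt)
    paths["gene_sets"] = gmt

    paths["expression"] = []
    for d, ds in enumerate(bundle.expression):
        mat = outdir / f"expr{d + 1}.tsv"
        lab = outdir / f"expr{d + 1}.labels.tsv"
        ds.values.to_csv(mat, sep="\t")
        ds.labels.to_csv(lab, sep="\t", header=False)
        paths["expression"].append({"matrix": mat, "labels": lab})

    reg = outdir / "regions.tsv"
    bundle.regions.to_csv(reg, sep="\t", header=False, index=False)
    paths["regions"] = reg
    paths["cohorts"] = []
    for name, (snps, _) in bundle.cohorts.items():
        path = outdir / f"{name}.snps.tsv"
        out = snps.rename(columns={"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"})
        out.to_csv(path, sep="\t", index=False)
        paths["cohorts"].append({"snps": path, "regions": reg, "name": name})

    truth_path = outdir / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("kind\tset\tcausal_genes\n")
        for name in bundle.truth.planted_up:
            fh.write(f"planted_up\t{name}\t\n")
        for name in bundle.truth.planted_down:
            fh.write(f"planted_down\t{name}\t\n")
        for name in bundle.truth.planted_gwas:
            genes = ",".join(bundle.truth.causal_genes.get(name, []))
            fh.write(f"planted_gwas\t{name}\t{genes}\n")
    paths["truth"] = truth_path
    return paths
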