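"""End-to-end study orchestration from one configuration.

Runs the expression arm (rank each dataset, preranked GSEA), the GWAS arm
(gene scoring, per-cohort enrichment, meta-combination, BH), intersects the
per-dataset significant pathway lists and tests the cross-modal overlap —
writing every intermediate table with a reproducibility header (package
version, seed, parameters).  Deterministic given the seed: rerunning with
the same configuration reproduces every output byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import ConcordanceReport, build_report
from .expression import (ExpressionDataset, read_expression_matrix,
                         read_feature_map, read_labels, read_rnk, write_rnk,
                         collapse_probes, rank_genes)
from .gene_sets import read_gmt
from .gsea import GseaParams, gsea_preranked, significant_sets
from .gwas import read_gene_regions, read_snp_stats, run_gwas_arm

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "write_table"]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a tab-delimited table with ``# key: value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pathconcord {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class StudyConfig:
    """Paths and stage parameters for one full run.

    expression entries are dicts with either ``rnk`` or ``matrix`` +
    ``labels`` (optional ``feature_map`` for probe-level matrices and
    ``name``); cohort entries are dicts with ``snps``, ``regions`` and
    optional ``name``.  An empty cohort list gives an expression-only run
    (the concordance stage is skipped with a notice).
    """

    gene_sets: str
    expression: list = field(default_factory=list)
    cohorts: list = field(default_factory=list)
    outdir: str = "pathconcord_out"
    seed: int = 0

    # expression arm
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_size: int = 15
    max_size: int = 500
    gsea_fdr: float = 0.05
    prior_df: float = 4.0
    reference_group: str | None = None

    # GWAS arm
    flank: int = 100_000
    alpha: float = 0.05
    combine: str = "fisher"
    gwas_fdr: float = 0.05

    # concordance
    universe_size: int | None = None  # default: collection size as read
    direction: str = "up"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["expression"] = [
            {k: str(v) for k, v in e.items()} for e in self.expression
        ]
        data["cohorts"] = [{k: str(v) for k, v in c.items()} for c in self.cohorts]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def params_line(self) -> str:
        return (
            f"weight={self.weight_exponent} nperm={self.n_permutations} "
            f"min={self.min_size} max={self.max_size} gsea_fdr={self.gsea_fdr} "
            f"flank={self.flank} alpha={self.alpha} combine={self.combine} "
            f"gwas_fdr={self.gwas_fdr} direction={self.direction}"
        )


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _load_expression(entry: dict, config: StudyConfig):
    name = entry.get("name")
    if "rnk" in entry:
        return name or Path(entry["rnk"]).stem, read_rnk(entry["rnk"])
    values = read_expression_matrix(entry["matrix"])
    labels = read_labels(entry["labels"])
    fmap = read_feature_map(entry["feature_map"]) if entry.get("feature_map") else None
    ds = ExpressionDataset(values, labels, feature_to_gene=fmap)
    if fmap is not None:
        ds = collapse_probes(ds)
    ranked = rank_genes(ds, prior_df=config.prior_df,
                        reference_group=config.reference_group)
    return name or Path(entry["matrix"]).stem, ranked


def run_study(config: StudyConfig) -> ConcordanceReport | None:
    """Run the full study; returns the concordance report (None if skipped).

    Every output table carries a header with the package version, seed and
    stage parameters.  Any stage error aborts with a stage-named message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    pkg_logger = logging.getLogger("pathconcord")
    pkg_logger.addHandler(counter)
    meta = {"seed": config.seed, "parameters": config.params_line()}
    try:
        collection = read_gmt(config.gene_sets)
    except Exception as exc:
        raise RuntimeError(f"[gene_sets] {exc}") from exc

    expr_significant: dict = {}
    try:
        if not config.expression:
            raise ValueError("at least one expression dataset is required")
        params = GseaParams(
            weight_exponent=config.weight_exponent,
            n_permutations=config.n_permutations,
            min_size=config.min_size,
            max_size=config.max_size,
            seed=config.seed,
            fdr_threshold=config.gsea_fdr,
        )
        for entry in config.expression:
            name, ranked = _load_expression(entry, config)
            write_rnk(ranked, outdir / f"rank_{name}.rnk")
            table = gsea_preranked(ranked, collection, params)
            write_table(table, outdir / f"gsea_{name}.tsv", meta)
            expr_significant[name] = significant_sets(table, config.gsea_fdr)
    except Exception as exc:
        raise RuntimeError(f"[expression_enrichment] {exc}") from exc

    gwas_result = None
    if config.cohorts:
        try:
            cohorts = {}
            for i, entry in enumerate(config.cohorts):
                name = entry.get("name") or f"cohort{i + 1}"
                snps = read_snp_stats(entry["snps"])
                regions = read_gene_regions(entry["regions"])
                cohorts[name] = (snps, regions)
            gwas_result = run_gwas_arm(
                cohorts, collection, alpha=config.alpha, flank=config.flank,
                fdr=config.gwas_fdr, combine=config.combine,
            )
            for name, enr in gwas_result.per_cohort.items():
                write_table(enr, outdir / f"gwas_enrich_{name}.tsv", meta)
                write_table(gwas_result.gene_scores[name],
                            outdir / f"gwas_genes_{name}.tsv", meta)
            write_table(gwas_result.meta, outdir / "gwas_meta.tsv", meta)
        except Exception as exc:
            raise RuntimeError(f"[gwas_enrichment] {exc}") from exc

    report = None
    if gwas_result is not None and len(expr_significant) >= 2:
        try:
            universe = (
                config.universe_size
                if config.universe_size is not None
                else collection.names
            )
            report = build_report(
                expr_significant,
                gwas_result.significant_sets(),
                universe,
                direction=config.direction,
            )
            _write_concordance(report, outdir, meta, counter)
        except Exception as exc:
            raise RuntimeError(f"[concordance] {exc}") from exc
    else:
        logger.info("concordance stage skipped (needs >=2 expression datasets "
                    "and >=1 cohort)")
        (outdir / "concordance_summary.txt").write_text(
            f"# pathconcord {__version__}\n"
            f"# seed: {config.seed}\n"
            "concordance stage skipped: "
            "requires >=2 expression datasets and >=1 cohort\n"
        )
    pkg_logger.removeHandler(counter)
    return report


def _venn_frame(venn) -> pd.DataFrame:
    rows = []
    for pattern in sorted(venn.cells, key=lambda p: (len(p), sorted(p))):
        rows.append(("&".join(sorted(pattern)), venn.cells[pattern]))
    return pd.DataFrame(rows, columns=["lists", "exclusive_count"])


def _write_concordance(report: ConcordanceReport, outdir: Path, meta: dict,
                       counter: _WarningCounter) -> None:
    write_table(_venn_frame(report.up), outdir / "venn_up.tsv", meta)
    write_table(_venn_frame(report.down), outdir / "venn_down.tsv", meta)
    write_table(report.flags, outdir / "concordance_flags.tsv", meta)
    ov = report.overlap
    lines = [
        f"# pathconcord {__version__}",
        f"# seed: {meta['seed']}",
        f"# parameters: {meta['parameters']}",
        f"expression common ({report.direction}): {ov.n_expression}",
        f"gwas significant: {ov.n_gwas}",
        f"overlap k: {ov.k}",
        f"universe N: {ov.n_universe}",
        f"hypergeometric p: {ov.p_hyper:.6g}",
        f"warnings: {counter.count}",
    ]
    (outdir / "concordance_summary.txt").write_text("\n".join(lines) + "\n")
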