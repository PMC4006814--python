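"""Preranked gene-set enrichment: weighted running-sum statistic with
permutation-based normalisation and FDR.

Given a signed rank list and a gene-set collection, each set is scored by the
weighted Kolmogorov–Smirnov-style enrichment score (ES): walking down the
list, the running sum rises by ``|score|^w / N_R`` at member genes and falls
by ``1 / (N - N_H)`` at non-members; the ES is the running sum at its maximal
absolute deviation.  A null distribution is built by drawing random gene
subsets of matching size from the ranked list; ES values are normalised by
the mean of same-sign null scores (NES), and the FDR q-value compares the
tails of the pooled observed and null NES distributions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression import RankedList
from .gene_sets import GeneSetCollection, filter_by_size

logger = logging.getLogger(__name__)

__all__ = [
    "GseaParams",
    "EnrichmentResult",
    "EsResult",
    "enrichment_score",
    "permutation_null",
    "normalize_es",
    "gsea_fdr",
    "gsea_preranked",
    "significant_sets",
]


@dataclass
class GseaParams:
    """Engine parameters.

    weight_exponent : exponent w on |score| in the running-sum increments
        (w=1 is the standard weighted statistic; w=0 reduces the ES to the
        classical two-sample Kolmogorov–Smirnov statistic).
    n_permutations : random gene subsets drawn per set size for the null.
    min_size / max_size : set-size bounds after restriction to the ranked
        genes (15 and 500 by default).
    seed : base seed; each set size derives its own generator so the null
        pool for a size is reproducible regardless of evaluation order.
    fdr_threshold : q-value cut-off used when listing significant sets.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_size: int = 15
    max_size: int = 500
    seed: int = 0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must lie in [0, 1]")


class EsResult(NamedTuple):
    es: float
    running_sum: np.ndarray
    peak_index: int


@dataclass
class EnrichmentResult:
    """Per-set outcome of a preranked run."""

    set_name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    direction: str
    leading_edge_size: int


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = 1.0
) -> EsResult:
    """Weighted running-sum enrichment score of *gene_set* on *ranked*.

    The set is first restricted to the ranked genes.  Raises if no member is
    ranked, if every ranked gene is a member (no misses to walk down), or if
    all member scores are zero (the weighted increment is undefined).
    """
    members = frozenset(gene_set) & frozenset(ranked.genes)
    if not members:
        raise ValueError("gene set has no genes in the ranked list")
    n = len(ranked)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(ranked.scores) ** weight_exponent
    n_r = weights[hit].sum()
    if n_r == 0:
        raise ValueError("all member scores are zero")
    inc = np.where(hit, weights / n_r, -1.0 / (n - n_hit))
    running = np.cumsum(inc)
    peak = int(np.argmax(np.abs(running)))
    return EsResult(float(running[peak]), running, peak)


def permutation_null(
    ranked: RankedList, set_size: int, params: GseaParams, rng: np.random.Generator
) -> np.ndarray:
    """Null ES values for uniformly drawn gene subsets of *set_size*.

    Vectorised over permutations: member positions are sampled without
    replacement, the increment matrix is cumulatively summed per row, and the
    ES is the running sum at its peak absolute value.  Deterministic given
    the generator state; pools are cached per set size by the caller.
    """
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError(f"set_size must lie in [1, {n - 1}]")
    weights = np.abs(ranked.scores) ** params.weight_exponent
    nperm = params.n_permutations
    u = rng.random((nperm, n))
    idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    wsel = weights[idx]
    n_r = wsel.sum(axis=1, keepdims=True)
    if np.any(n_r == 0):
        raise ValueError("a null draw selected only zero scores")
    inc = np.full((nperm, n), -1.0 / (n - set_size))
    rows = np.arange(nperm)[:, None]
    inc[rows, idx] = wsel / n_r
    running = np.cumsum(inc, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(nperm), peaks]


def normalize_es(es_obs: float, null_es: np.ndarray) -> float:
    """ES divided by the mean magnitude of same-sign null ES values (NES).

    Positive observed scores are divided by the mean positive null score;
    negative observed scores by the mean magnitude of the negative nulls, so
    the NES keeps the sign of the ES.  Returns NaN (with a warning) when no
    null value shares the sign — such sets are excluded from the FDR
    computation by the caller.
    """
    null_es = np.asarray(null_es, float)
    if es_obs >= 0:
        same = null_es[null_es > 0]
    else:
        same = -null_es[null_es < 0]
    if same.size == 0:
        logger.warning("no same-sign null ES values; NES undefined")
        return float("nan")
    return float(es_obs / same.mean())


def _nominal_p(es_obs: float, null_es: np.ndarray) -> float:
    """Add-one-smoothed fraction of same-sign nulls at least as extreme."""
    null_es = np.asarray(null_es, float)
    if es_obs >= 0:
        same = null_es[null_es >= 0]
        b = int(np.count_nonzero(same >= es_obs))
    else:
        same = null_es[null_es < 0]
        b = int(np.count_nonzero(same <= es_obs))
    return (b + 1) / (same.size + 1)


def gsea_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """Permutation FDR q-values from observed and pooled null NES.

    For a positive NES* the raw estimate is the null tail fraction over the
    observed tail fraction,

        q = [#{null >= NES*} / #{null >= 0}] / [#{obs >= NES*} / #{obs >= 0}],

    mirrored for the negative side, clipped to [0, 1].  A final per-sign
    running-minimum pass (from least extreme to most extreme) makes q
    monotone non-increasing in |NES|.  NaN observed values yield NaN q.
    """
    obs = np.asarray(nes_obs, float)
    null = np.asarray(nes_null, float)
    null = null[np.isfinite(null)]
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null NES vectors must be non-empty")
    q = np.full(obs.shape, np.nan)
    finite = np.isfinite(obs)
    fobs = obs[finite]

    for sign in (+1, -1):
        if sign > 0:
            mask = finite & (obs >= 0)
            n_null_side = int(np.count_nonzero(null >= 0))
            n_obs_side = int(np.count_nonzero(fobs >= 0))
        else:
            mask = finite & (obs < 0)
            n_null_side = int(np.count_nonzero(null < 0))
            n_obs_side = int(np.count_nonzero(fobs < 0))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        if n_null_side == 0:
            # no null mass on this side: tail fraction is 0 for every value
            q[idx] = 0.0
            continue
        raw = np.empty(idx.size)
        for j, i in enumerate(idx):
            v = obs[i]
            if sign > 0:
                tail_null = np.count_nonzero(null >= v) / n_null_side
                tail_obs = np.count_nonzero(fobs >= v) / n_obs_side
            else:
                tail_null = np.count_nonzero(null <= v) / n_null_side
                tail_obs = np.count_nonzero(fobs <= v) / n_obs_side
            raw[j] = min(1.0, tail_null / tail_obs)
        # monotonicity: a set's q is the best (minimum) raw FDR over all
        # rejection thresholds at which it would be called — its own raw
        # estimate or any less extreme one.  Scanning in ascending |NES| with
        # a running minimum makes q monotone non-increasing in |NES| without
        # letting the extreme tail's small estimates leak to weak sets.
        order = np.argsort(np.abs(obs[idx]), kind="stable")  # ascending |NES|
        mins = np.empty(idx.size)
        running = np.inf
        for pos in range(idx.size):
            running = min(running, raw[order[pos]])
            mins[order[pos]] = running
        q[idx] = mins
    return q


def gsea_preranked(
    ranked: RankedList, collection: GeneSetCollection, params: GseaParams | None = None
) -> pd.DataFrame:
    """Run the full preranked analysis over a collection.

    The collection is size-filtered against the ranked genes, each retained
    set is scored, null pools are built once per distinct set size (seeded by
    ``(params.seed, size)`` so output is order-independent), and NES, nominal
    p (add-one smoothed) and permutation FDR q are reported.

    Returns a DataFrame with columns ``set, size, es, nes, nominal_p, fdr_q,
    direction, leading_edge_size`` sorted by NES descending.
    """
    if params is None:
        params = GseaParams()
    background = set(map(str, ranked.genes))
    filtered, dropped = filter_by_size(
        collection, params.min_size, params.max_size, background
    )
    if len(filtered) == 0:
        raise ValueError("no gene set survives size filtering against the ranked list")
    if len(dropped):
        logger.info("gsea_preranked: %d sets dropped by size filter", len(dropped))

    sizes = sorted({len(s) for s in filtered})
    pools: dict[int, np.ndarray] = {}
    for size in sizes:
        rng = np.random.default_rng([params.seed, size])
        pools[size] = permutation_null(ranked, size, params, rng)

    rows = []
    null_nes_parts = []
    hit_positions = {g: i for i, g in enumerate(ranked.genes)}
    for s in filtered:
        res = enrichment_score(ranked, s.genes, params.weight_exponent)
        size = len(s)
        pool = pools[size]
        nes = normalize_es(res.es, pool)
        p = _nominal_p(res.es, pool)
        positions = np.sort([hit_positions[g] for g in s.genes])
        if res.es >= 0:
            leading = int(np.count_nonzero(positions <= res.peak_index))
        else:
            leading = int(np.count_nonzero(positions >= res.peak_index))
        rows.append((s.name, size, res.es, nes, p, res.es >= 0, leading))
        # pooled null NES: each set contributes its size pool, normalised by
        # that pool's own same-sign means (meandiv)
        pos_mean = pool[pool > 0].mean() if np.any(pool > 0) else np.nan
        neg_mean = np.abs(pool[pool < 0]).mean() if np.any(pool < 0) else np.nan
        scaled = np.where(pool >= 0, pool / pos_mean, pool / neg_mean)
        null_nes_parts.append(scaled[np.isfinite(scaled)])

    nes_obs = np.array([r[3] for r in rows])
    nes_null = np.concatenate(null_nes_parts)
    n_undef = int(np.count_nonzero(~np.isfinite(nes_obs)))
    if n_undef:
        logger.warning("%d sets have undefined NES; excluded from FDR", n_undef)
    q = gsea_fdr(nes_obs, nes_null)

    table = pd.DataFrame(
        {
            "set": [r[0] for r in rows],
            "size": [r[1] for r in rows],
            "es": [r[2] for r in rows],
            "nes": nes_obs,
            "nominal_p": [r[4] for r in rows],
            "fdr_q": q,
            "direction": ["up" if r[5] else "down" for r in rows],
            "leading_edge_size": [r[6] for r in rows],
        }
    )
    table = table.sort_values(
        ["nes", "set"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return table


def significant_sets(table: pd.DataFrame, fdr_threshold: float = 0.05) -> dict:
    """Split sets with q below *fdr_threshold* by direction of enrichment."""
    sig = table[table["fdr_q"] < fdr_threshold]
    return {
        "up": sorted(sig.loc[sig["direction"] == "up", "set"]),
        "down": sorted(sig.loc[sig["direction"] == "down", "set"]),
    }
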