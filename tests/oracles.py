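"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions with plain Python loops and
exact integer arithmetic where possible, deliberately avoiding the code paths
(and vectorisation tricks) of the package under test.
"""
from __future__ import annotations

import math
from fractions import Fraction


def brute_enrichment_score(scores, member_flags, weight):
    """Running-sum ES by direct enumeration.

    scores: list of floats in ranked order; member_flags: list of bools.
    Returns (es, running_sum_list).
    """
    n = len(scores)
    n_hit = sum(member_flags)
    n_miss = n - n_hit
    n_r = sum(abs(s) ** weight for s, m in zip(scores, member_flags) if m)
    running = []
    total = 0.0
    for s, m in zip(scores, member_flags):
        if m:
            total += abs(s) ** weight / n_r
        else:
            total -= 1.0 / n_miss
        running.append(total)
    best = 0
    for i in range(1, n):
        if abs(running[i]) > abs(running[best]):
            best = i
    return running[best], running


def brute_hypergeom_upper_tail(k, n_universe, n_set, n_draw):
    """P[X >= k] by exact PMF summation with integer combinatorics."""
    hi = min(n_set, n_draw)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    num = 0
    for i in range(k, hi + 1):
        if n_draw - i > n_universe - n_set:
            continue
        num += math.comb(n_set, i) * math.comb(n_universe - n_set, n_draw - i)
    return float(Fraction(num, math.comb(n_universe, n_draw)))


def brute_fisher_even_df(p_values):
    """Fisher meta-P via the closed-form chi-square survival for even df:
    P[X2 > x] = exp(-x/2) * sum_{j<m} (x/2)^j / j!  with df = 2m."""
    m = len(p_values)
    x = -2.0 * sum(math.log(p) for p in p_values)
    half = x / 2.0
    return math.exp(-half) * sum(half ** j / math.factorial(j) for j in range(m))


def brute_bh(p_values):
    """Step-up BH q-values by the textbook formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = running
    return q


def brute_assign(snps, regions, flank):
    """Gene -> SNP p-values by a double loop over all pairs."""
    out = {}
    for gene, chrom, start, end in regions:
        ps = []
        lo = max(1, start - flank)
        hi = end + flank
        for _, schrom, pos, p in snps:
            if schrom == chrom and lo <= pos <= hi:
                ps.append(p)
        if ps:
            out[gene] = ps
    return out


def brute_venn(named_lists):
    """Membership-pattern tally over the union of all names."""
    universe = set()
    for members in named_lists.values():
        universe |= set(members)
    cells = {}
    for item in universe:
        pattern = frozenset(
            name for name, members in named_lists.items() if item in set(members)
        )
        cells[pattern] = cells.get(pattern, 0) + 1
    full = [
        x for x in sorted(universe)
        if all(x in set(m) for m in named_lists.values())
    ]
    return full, cells


def brute_gsea_fdr(nes_obs, nes_null):
    """Tail-ratio FDR q with the per-sign running-minimum, naive O(n^2)."""
    raw = {}
    finite_obs = [v for v in nes_obs if v == v]
    for i, v in enumerate(nes_obs):
        if v != v:  # NaN
            raw[i] = float("nan")
            continue
        if v >= 0:
            null_side = [x for x in nes_null if x >= 0]
            obs_side = [x for x in finite_obs if x >= 0]
            tail_null = sum(1 for x in null_side if x >= v)
            tail_obs = sum(1 for x in obs_side if x >= v)
        else:
            null_side = [x for x in nes_null if x < 0]
            obs_side = [x for x in finite_obs if x < 0]
            tail_null = sum(1 for x in null_side if x <= v)
            tail_obs = sum(1 for x in obs_side if x <= v)
        if not null_side:
            raw[i] = 0.0
            continue
        raw[i] = min(
            1.0, (tail_null / len(null_side)) / (tail_obs / len(obs_side))
        )
    q = {}
    for i, v in enumerate(nes_obs):
        if v != v:
            q[i] = float("nan")
            continue
        if raw[i] == 0.0 and not any(
            (x >= 0) == (v >= 0) for x in nes_null
        ):
            q[i] = 0.0
            continue
        same = [
            j for j, u in enumerate(nes_obs)
            if u == u and (u >= 0) == (v >= 0) and abs(u) <= abs(v)
        ]
        q[i] = min(raw[j] for j in same)
    return [q[i] for i in range(len(nes_obs))]
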