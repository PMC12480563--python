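"""Rank-test primitives and the two validation statistics.

Two checks accompany the transfer calls.  The contig-length check asks
whether transfer-called genes sit on shorter contigs than vertically
inherited ("ancestral") genes — the signature of uncaught assembly
contamination — via the Mann–Whitney U test and the Vargha–Delaney A
effect size (A = P(X > Y) + 0.5·P(X = Y); 0.5 means stochastic
equality).  The lineage-enrichment check asks whether the lineages
called as donors are over-represented inside transfer clades relative to
each tree's own taxonomic composition, via a paired one-sided Wilcoxon
signed-rank test on per-tree proportion differences, Benjamini–Hochberg
adjusted across lineages.

The rank tests are computed in-house: exact enumeration on small
samples (all :math:`\\binom{n_1+n_2}{n_1}` group assignments for U, a
rank-sum convolution over the :math:`2^m` sign assignments for the
signed-rank W) and a tie-corrected, continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tree_io import AnnotatedGeneTree
from .events import HgtEvent

#: largest pooled / nonzero-pair sample size handled by exact enumeration
EXACT_LIMIT = 20


@dataclass
class RankTestResult:
    statistic_name: str  # "U" or "W"
    statistic: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" | "normal"
    alternative: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


@dataclass
class EnrichmentResult:
    lineage: str
    n_trees: int
    statistic: Optional[float]  # W, None when the test is undefined
    p_value: Optional[float]
    p_adjusted: Optional[float]
    mean_clade_share: float  # mean x_t
    mean_tree_share: float  # mean y_t


# ---------------------------------------------------------------------------
# Mann-Whitney U and Vargha-Delaney A
# ---------------------------------------------------------------------------

def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_limit: int = EXACT_LIMIT,
) -> RankTestResult:
    """Mann–Whitney U test, U counting pairs where x exceeds y (ties half).

    Exact p by enumerating every assignment of the pooled values to the
    two groups when ``n1 + n2 <= exact_limit`` (valid under ties); a
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_limit:
        pooled = x + y
        idx = range(n1 + n2)
        total = 0
        hits = 0
        eps = 1e-9
        for comb in itertools.combinations(idx, n1):
            comb_set = set(comb)
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in idx if i not in comb_set]
            u = _u_statistic(xs, ys)
            total += 1
            if alternative == "greater":
                hits += u >= u_obs - eps
            elif alternative == "less":
                hits += u <= u_obs + eps
            else:
                hits += abs(u - mu) >= abs(u_obs - mu) - eps
        p = hits / total
        method = "exact"
    else:
        n = n1 + n2
        _, counts = np.unique(np.asarray(x + y), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "greater":
                z = (u_obs - mu - 0.5) / sd
                p = _norm_sf(z)
            elif alternative == "less":
                z = (u_obs - mu + 0.5) / sd
                p = 1.0 - _norm_sf(z)
            else:
                z = (abs(u_obs - mu) - 0.5) / sd
                p = 2.0 * _norm_sf(z)
        p = min(max(p, 0.0), 1.0)
        method = "normal"
    return RankTestResult("U", u_obs, n1, n2, p, method, alternative)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def vargha_delaney_a(x: Sequence[float], y: Sequence[float]) -> float:
    """A = (#{x_i > y_j} + 0.5·#ties) / (n1·n2), the probability that a
    random draw from x exceeds one from y (ties split)."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    return _u_statistic(x, y) / (len(x) * len(y))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    d: Sequence[float],
    alternative: str = "greater",
    exact_limit: int = EXACT_LIMIT,
) -> RankTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's original treatment), |d| ranked with
    average ranks for ties, W = sum of ranks of the positive
    differences.  Exact p by convolving the sign-assignment rank-sum
    distribution when the number of nonzero differences is at most
    ``exact_limit``; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = [float(v) for v in d]
    nz = [v for v in d if v != 0.0]
    m = len(nz)
    if m == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = _average_ranks([abs(v) for v in nz])
    w_obs = sum(r for r, v in zip(ranks, nz) if v > 0)
    mu = m * (m + 1) / 4.0
    if m <= exact_limit:
        # distribution of W over the 2^m equiprobable sign assignments,
        # convolved in half-rank integer units (average ranks are .0/.5)
        units = [int(round(2 * r)) for r in ranks]
        max_sum = sum(units)
        ways = np.zeros(max_sum + 1, dtype=np.float64)
        ways[0] = 1.0
        for u in units:
            shifted = np.zeros_like(ways)
            shifted[u:] = ways[: max_sum + 1 - u]
            ways = ways + shifted
        total = 2.0**m
        w2 = int(round(2 * w_obs))
        support = np.arange(max_sum + 1)
        if alternative == "greater":
            p = float(ways[support >= w2].sum() / total)
        elif alternative == "less":
            p = float(ways[support <= w2].sum() / total)
        else:
            dev = np.abs(support - 2 * mu)
            p = float(ways[dev >= abs(w2 - 2 * mu) - 1e-9].sum() / total)
        method = "exact"
    else:
        tie_counts = np.unique(np.round(np.array(ranks) * 2).astype(int),
                               return_counts=True)[1]
        var = m * (m + 1) * (2 * m + 1) / 24.0 - float(
            np.sum(tie_counts**3 - tie_counts)
        ) / 48.0
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "greater":
                p = _norm_sf((w_obs - mu - 0.5) / sd)
            elif alternative == "less":
                p = 1.0 - _norm_sf((w_obs - mu + 0.5) / sd)
            else:
                p = 2.0 * _norm_sf((abs(w_obs - mu) - 0.5) / sd)
        p = min(max(p, 0.0), 1.0)
        method = "normal"
    return RankTestResult("W", w_obs, m, m, p, method, alternative)


def _average_ranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input
    order: q(i) = min_{j >= i} (m/j)·p(j) over the ascending sort, capped
    at 1."""
    p = [float(v) for v in p]
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value {v} outside [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def contig_length_check(
    hgt_lengths: Sequence[int],
    ancestral_lengths: Sequence[int],
    p_threshold: float = 0.05,
) -> dict:
    """Contamination guard: compare contig lengths of transfer-called
    genes (x) against ancestral genes (y).  A below 0.5 with small
    two-sided p flags a shortening signal (transfer calls concentrated on
    short, possibly contaminant, contigs)."""
    if len(hgt_lengths) == 0 or len(ancestral_lengths) == 0:
        raise ValueError("both length lists must be non-empty")
    if any(v <= 0 for v in hgt_lengths) or any(v <= 0 for v in ancestral_lengths):
        raise ValueError("contig lengths must be positive")
    res = mann_whitney_u(hgt_lengths, ancestral_lengths, alternative="two_sided")
    a = vargha_delaney_a(hgt_lengths, ancestral_lengths)
    shortening = a < 0.5 and res.p_value < p_threshold
    return {
        "U": res.statistic,
        "p_two_sided": res.p_value,
        "A": a,
        "n1": res.n1,
        "n2": res.n2,
        "interpretation": "shortening signal" if shortening else "no-shortening signal",
    }


def _lineage_shares(
    tree: AnnotatedGeneTree, leaf_names: set[str], lineages: Sequence[str]
) -> Optional[dict[str, float]]:
    """Per-lineage share of the non-focal (sister + outgroup) leaves among
    ``leaf_names``; None when there are no non-focal leaves."""
    counts = {lin: 0 for lin in lineages}
    denom = 0
    for name in leaf_names:
        role = tree.roles[name]
        if role.role in ("sister", "outgroup"):
            denom += 1
            if role.role == "outgroup" and role.lineage in counts:
                counts[role.lineage] += 1
    if denom == 0:
        return None
    return {lin: n / denom for lin, n in counts.items()}


def lineage_enrichment(
    events: Sequence[HgtEvent],
    trees: Sequence[AnnotatedGeneTree],
    lineages: Sequence[str],
    exact_limit: int = EXACT_LIMIT,
) -> list[EnrichmentResult]:
    """Per-lineage enrichment inside transfer clades.

    For every tree contributing at least one event, the lineage's share
    of non-focal leaves inside the union of that tree's stopping clades
    (x_t) is paired with its share over the whole tree (y_t); a one-sided
    (greater) signed-rank test on d_t = x_t − y_t asks whether the
    lineage is over-represented in transfer clades beyond the tree's own
    composition.  P-values are BH-adjusted across the lineages for which
    the test is defined; lineages with fewer than two usable trees or
    all-zero differences are reported with p absent and excluded from
    the adjustment family.
    """
    by_og: dict[str, list[HgtEvent]] = {}
    for ev in events:
        by_og.setdefault(ev.og_id, []).append(ev)
    tree_index = {t.og_id: t for t in trees}
    contributing = [og for og in by_og if og in tree_index]
    if len(contributing) < 2:
        raise ValueError("enrichment needs >= 2 trees contributing events")

    pairs: dict[str, list[tuple[float, float]]] = {lin: [] for lin in lineages}
    for og in contributing:
        tree = tree_index[og]
        clade_union = set().union(*(ev.clade_leaves for ev in by_og[og]))
        x = _lineage_shares(tree, clade_union, lineages)
        y = _lineage_shares(tree, set(tree.tree.leaf_names()), lineages)
        if x is None or y is None:
            continue
        for lin in lineages:
            pairs[lin].append((x[lin], y[lin]))

    results: dict[str, EnrichmentResult] = {}
    testable: list[str] = []
    for lin in lineages:
        pts = pairs[lin]
        n_trees = len(pts)
        mean_x = float(np.mean([a for a, _ in pts])) if pts else 0.0
        mean_y = float(np.mean([b for _, b in pts])) if pts else 0.0
        d = [a - b for a, b in pts]
        if n_trees < 2 or all(v == 0.0 for v in d):
            results[lin] = EnrichmentResult(
                lin, n_trees, None, None, None, mean_x, mean_y
            )
            continue
        res = wilcoxon_signed_rank(d, alternative="greater",
                                   exact_limit=exact_limit)
        results[lin] = EnrichmentResult(
            lin, n_trees, res.statistic, res.p_value, None, mean_x, mean_y
        )
        testable.append(lin)

    adjusted = bh_adjust([results[lin].p_value for lin in testable])
    for lin, q in zip(testable, adjusted):
        results[lin].p_adjusted = q
    ordered = sorted(
        results.values(),
        key=lambda r: (r.p_adjusted is None, r.p_adjusted, r.lineage),
    )
    return ordered
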