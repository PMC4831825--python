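"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a statistic from its definition (enumeration,
log-space summation, hand step-up), deliberately avoiding the code paths
and libraries the package itself uses for that statistic.
"""

from __future__ import annotations

import math
from itertools import combinations


def poisson_sf_oracle(k: int, lam: float, tol: float = 1e-18) -> float:
    """P(X >= k) for X ~ Poisson(lam) by log-space pmf summation."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = 0.0
    j = k
    while True:
        log_pmf = j * math.log(lam) - lam - math.lgamma(j + 1)
        term = math.exp(log_pmf)
        total += term
        j += 1
        # terms decay once j > lam; stop when negligible
        if j > lam and term < tol * max(total, 1e-300):
            break
    return min(total, 1.0)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (promoter-enriched) Fisher p by hypergeometric enumeration.

    Exact integer arithmetic: P(X >= a) with X the top-left cell of a
    2x2 table with fixed margins, pmf(k) = C(r1,k) C(r2,c1-k) / C(N,c1).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (n - c1) == 0:
        return 1.0
    denom = math.comb(n, c1)
    num = 0
    for k in range(a, min(r1, c1) + 1):
        if c1 - k > r2:
            continue
        num += math.comb(r1, k) * math.comb(r2, c1 - k)
    return num / denom


def bh_oracle(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up by direct hand execution of the formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def mannwhitney_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of rank assignments.

    Assumes no ties. U for x is counted against the permutation null of
    which positions in the pooled sorted order belong to x; the
    two-sided p sums both tails symmetrically.
    """
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    x_set = set(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n = nx + ny
    us = []
    for positions in combinations(range(n), nx):
        pos_set = set(positions)
        u = sum(
            1
            for i in positions
            for j in range(n)
            if j not in pos_set and pooled[i] > pooled[j]
        )
        us.append(u)
    total = len(us)
    lo = sum(1 for u in us if u <= min(u_obs, nx * ny - u_obs))
    hi = sum(1 for u in us if u >= max(u_obs, nx * ny - u_obs))
    return min(1.0, (lo + hi) / total)


def g4_scan_oracle(
    sequence: str,
    min_run: int = 3,
    n_runs: int = 4,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[tuple[int, int]]:
    """Forward-strand G4 regions by brute-force run enumeration.

    Walks the sequence character by character to find maximal G-runs of
    length >= min_run, tests every window of n_runs consecutive runs for
    loop lengths in [loop_min, loop_max] (loops may contain sub-threshold
    G-runs; N never extends a run), and merges overlapping windows.
    Pure-python counterpart of the QuadParser-style motif definition.
    """
    runs: list[tuple[int, int]] = []
    i, n = 0, len(sequence)
    while i < n:
        if sequence[i] == "G":
            j = i
            while j < n and sequence[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    raw = []
    for k in range(len(runs) - n_runs + 1):
        window = runs[k : k + n_runs]
        if all(
            loop_min <= window[t + 1][0] - window[t][1] <= loop_max
            for t in range(n_runs - 1)
        ):
            raw.append((window[0][0], window[-1][1]))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(raw):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def count_reads_oracle(reads, regions) -> dict[str, tuple[int, int]]:
    """Per-gene (promoter, body) counts by testing every read vs every region.

    ``reads`` is an iterable of (chrom, start, end, strand); assignment
    is by strand-aware 5' end falling inside the half-open interval.
    """
    out = {r.gene_id: [0, 0] for r in regions}
    for chrom, start, end, strand in reads:
        p5 = start if strand == "+" else end - 1
        for r in regions:
            if r.chrom != chrom:
                continue
            if r.promoter_start <= p5 < r.promoter_end:
                out[r.gene_id][0] += 1
            if r.body_start <= p5 < r.body_end:
                out[r.gene_id][1] += 1
    return {g: (c[0], c[1]) for g, c in out.items()}
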