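"""Independent brute-force oracles used to validate the fast implementations.

Every function here recomputes a quantity by the most literal route
available (position-wise coverage arrays, all-pairs scans, exhaustive
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def coverage_merge(intervals, max_gap=0):
    """Merge via a boolean coverage array: paint every interval, bridge gaps
    <= max_gap, read off maximal runs.  intervals: (chrom, start, end)."""
    out = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        hi = max(e for _, e in ivs) + max_gap + 2
        cov = np.zeros(hi, dtype=bool)
        for s, e in ivs:
            cov[s:e] = True
        # bridge gaps of length <= max_gap between covered runs
        if max_gap > 0:
            runs = _runs(cov)
            for (s1, e1), (s2, _) in zip(runs, runs[1:]):
                if s2 - e1 <= max_gap:
                    cov[e1:s2] = True
        for s, e in _runs(cov):
            out.append((chrom, s, e))
    return out


def _runs(mask):
    """Maximal True runs of a boolean array as (start, end) half-open."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def coverage_consensus(groups, min_replicates):
    """Consensus by per-bp replicate counting.  groups: {group: [replicate
    interval lists]}; returns merged (chrom, start, end) regions."""
    kept = []
    for reps in groups.values():
        chroms = sorted({c for rep in reps for c, _, _ in rep})
        for chrom in chroms:
            his = [e for rep in reps for c, _, e in rep if c == chrom]
            if not his:
                continue
            count = np.zeros(max(his) + 1, dtype=int)
            for rep in reps:
                cov = np.zeros(max(his) + 1, dtype=bool)
                for c, s, e in rep:
                    if c == chrom:
                        cov[s:e] = True
                count += cov
            for s, e in _runs(count >= min_replicates):
                kept.append((chrom, s, e))
    return coverage_merge(kept, 0)


def pairwise_overlap_flags(query, annotation):
    """All-pairs >=1 bp overlap flags; both are (chrom, start, end) lists."""
    flags = []
    for qc, qs, qe in query:
        flags.append(
            any(qc == ac and qs < ae and as_ < qe for ac, as_, ae in annotation)
        )
    return np.array(flags)


def spearman_rank_oracle(x, y):
    """Spearman rho as the Pearson correlation of mid-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan
    return float(stats.pearsonr(rx, ry)[0])


def bh_oracle(p):
    """BH step-up by literal application of the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        k = pos + 1
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all same-margin tables no more probable than the
    observed one."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-10):
            total += px
    return min(1.0, float(total))


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled observations to the two groups (no ties assumed): the fraction of
    assignments whose U deviates from its mean at least as much as observed."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    center = n * m / 2.0
    dev = abs(u_obs - center)
    count = total = 0
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= dev - 1e-12:
            count += 1
    return count / total


def stitch_closure_oracle(peaks, gap):
    """Domain membership by transitive closure of the 'within gap on the same
    chromosome' relation.  peaks: (chrom, start, end, signal) tuples.
    Returns a set of frozensets of peak indices."""
    n = len(peaks)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            ci, si, ei, _ = peaks[i]
            cj, sj, ej, _ = peaks[j]
            if ci == cj and max(si, sj) - min(ei, ej) <= gap:
                adj[i][j] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if seen[k]:
                continue
            seen[k] = True
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and not seen[j])
        comps.append(frozenset(comp))
    return set(comps)


def super_cutoff_oracle(signals):
    """Expected super flags (aligned to ascending-signal order) by a literal
    scan of the scaled rank-signal curve for the point furthest below the
    diagonal, ties to the top rank; everything strictly above it is super,
    and a fully tied scan calls exactly the top-ranked point."""
    sig = np.sort(np.asarray(signals, dtype=float))
    n = len(sig)
    if n < 3:
        return np.zeros(n, dtype=bool)
    if sig[-1] == sig[0]:
        flags = np.zeros(n, dtype=bool)
        flags[-1] = True
        return flags
    y = (sig - sig[0]) / (sig[-1] - sig[0])
    x = np.arange(n) / (n - 1)
    best, best_i = -np.inf, 0
    for i in range(n):
        if x[i] - y[i] >= best - 1e-15:
            best, best_i = x[i] - y[i], i
    if best_i == n - 1:
        cutoff = sig[n - 1]
    else:
        cutoff = sig[best_i + 1]
    return sig >= cutoff
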