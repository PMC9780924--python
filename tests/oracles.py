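"""Independent brute-force oracles used by the test suite.

These are deliberately written without reusing package internals: plain
dict/loop dynamic programs and exhaustive enumerations, so agreement with
the package is a genuine two-route check.
"""
from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_oracle(query: str, target: str, gap_open: float, gap_extend: float) -> float:
    """Explicit 3-state local-alignment DP (no vectorization, no shortcuts).

    M[i][j]: best alignment ending in a match/mismatch at (i, j).
    X[i][j]: ending in a gap in the query (target residue j consumed last).
    Y[i][j]: ending in a gap in the target.
    """
    m, n = len(query), len(target)
    NEG = float("-inf")
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = blosum62_score(query[i - 1], target[j - 1])
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = prev + s
            X[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                X[i][j - 1] - gap_extend,
                Y[i][j - 1] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                Y[i - 1][j] - gap_extend,
                X[i - 1][j] - gap_open - gap_extend,
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def ng86_oracle(codon_pairs: list[tuple[str, str]]):
    """Exhaustive NG86 counting: (Sd, Nd, S, N) by full enumeration.

    Sites: per codon position, the fraction of the three possible changes
    that are synonymous (changes to stop codons are never synonymous); each
    codon contributes 3 sites.  Differences: equal-weight average over all
    orderings of the differing positions, excluding orderings that pass
    through a stop codon (using all orderings when none survive, with the
    classifiable steps rescaled to the number of differences).
    """

    def translate(codon: str) -> str:
        return str(Seq(codon).translate())

    def site_counts(codon: str) -> float:
        syn = 0.0
        aa = translate(codon)
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if translate(mut) == aa and translate(mut) != "*":
                    syn += 1 / 3
        return syn

    s_total_a = s_total_b = 0.0
    sd = nd = 0.0
    for ca, cb in codon_pairs:
        s_total_a += site_counts(ca)
        s_total_b += site_counts(cb)
        positions = [k for k in range(3) if ca[k] != cb[k]]
        if not positions:
            continue
        clean, stopped = [], []
        for order in itertools.permutations(positions):
            cur = ca
            syn = non = 0
            bad = False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if translate(nxt) == "*" or translate(cur) == "*":
                    bad = True
                elif translate(nxt) == translate(cur):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            (stopped if bad else clean).append((syn, non))
        pool = clean if clean else stopped
        psyn = sum(p[0] for p in pool) / len(pool)
        pnon = sum(p[1] for p in pool) / len(pool)
        if not clean:
            total = psyn + pnon
            if total > 0:
                psyn *= len(positions) / total
                pnon *= len(positions) / total
        sd += psyn
        nd += pnon
    n_codons = len(codon_pairs)
    s_sites = (s_total_a + s_total_b) / 2
    n_sites = 3 * n_codons - s_sites
    return sd, nd, s_sites, n_sites


def jc_oracle(p: float) -> float:
    return -0.75 * math.log(1 - 4 * p / 3)


def complete_linkage_oracle(points, k: int):
    """Brute-force agglomeration: recompute every inter-cluster distance
    from scratch (max over member pairs) at every step; merge the smallest,
    ties broken by smallest (i, j) over current cluster list order."""

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > k:
        best = (float("inf"), -1, -1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    dist(points[a], points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters, merges


def msa3_optimum(s1: str, s2: str, s3: str, gap_res: float = -4.0) -> float:
    """Exhaustive three-way alignment optimum under sum-of-pairs scoring
    (BLOSUM62 for residue pairs, ``gap_res`` for residue-gap, 0 gap-gap)."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    NEG = float("-inf")
    dp = [[[NEG] * (n3 + 1) for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    dp[0][0][0] = 0.0

    def pair(x: str | None, y: str | None) -> float:
        if x is None and y is None:
            return 0.0
        if x is None or y is None:
            return gap_res
        return blosum62_score(x, y)

    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for l in range(n3 + 1):
                cur = dp[i][j][l]
                if cur == NEG:
                    continue
                for d1, d2, d3 in moves:
                    if i + d1 > n1 or j + d2 > n2 or l + d3 > n3:
                        continue
                    c1 = s1[i] if d1 else None
                    c2 = s2[j] if d2 else None
                    c3 = s3[l] if d3 else None
                    gain = pair(c1, c2) + pair(c1, c3) + pair(c2, c3)
                    nxt = cur + gain
                    if nxt > dp[i + d1][j + d2][l + d3]:
                        dp[i + d1][j + d2][l + d3] = nxt
    return dp[n1][n2][n3]
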