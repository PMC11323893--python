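"""Independent reference implementations used only to check the package.

Everything here is written as a direct, naive transliteration of the
algorithm definitions — no data structures or shortcuts shared with the
production code — so agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math


def cast_reference(n, edges, pref, t):
    """Naive CAST on an abstract graph.

    ``n`` nodes 0..n-1, ``edges`` a set of frozensets, ``pref`` a list
    giving each node's tie-break priority (lower preferred), ``t`` the
    affinity threshold.  Returns clusters as lists ordered by pref.
    Mirrors the published add/remove loop: open with the max-degree
    unassigned node, add the highest-affinity unassigned node while its
    affinity >= t*|C|, then remove the lowest-affinity member while its
    affinity < t*|C| (never emptying the cluster), until stable.
    """

    def connected(a, b):
        return frozenset((a, b)) in edges

    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_seed, best_deg = None, -1
        for u in sorted(unassigned, key=lambda x: pref[x]):
            deg = sum(1 for v in unassigned if v != u and connected(u, v))
            if deg > best_deg:
                best_seed, best_deg = u, deg
        cluster = [best_seed]
        unassigned.remove(best_seed)
        for _ in range(10 * n + 50):
            changed = False
            while unassigned:
                cand = sorted(
                    unassigned,
                    key=lambda u: (-sum(1 for v in cluster if connected(u, v)),
                                   pref[u]),
                )[0]
                aff = sum(1 for v in cluster if connected(cand, v))
                if aff >= t * len(cluster):
                    cluster.append(cand)
                    unassigned.remove(cand)
                    changed = True
                else:
                    break
            while len(cluster) > 1:
                worst = sorted(
                    cluster,
                    key=lambda u: (sum(1 for v in cluster
                                       if v != u and connected(u, v)), pref[u]),
                )[0]
                aff = sum(1 for v in cluster if v != worst and connected(worst, v))
                if aff < t * len(cluster):
                    cluster.remove(worst)
                    unassigned.add(worst)
                    changed = True
                else:
                    break
            if not changed:
                break
        clusters.append(sorted(cluster, key=lambda u: pref[u]))
    return clusters


def hamming_scan(spacer, genome, max_mm):
    """Pure-python both-strand Hamming scan; returns
    (position, strand, mismatches) triples.  N mismatches everything."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(spacer))
    out = []
    m = len(spacer)
    for strand, probe in (("+", spacer), ("-", rc)):
        for pos in range(len(genome) - m + 1):
            window = genome[pos:pos + m]
            mm = sum(
                1
                for a, b in zip(probe, window)
                if a != b or a == "N" or b == "N"
            )
            if mm <= max_mm:
                out.append((pos, strand, mm))
    return out


def fisher_one_sided(a, b, c, d):
    """P(X >= a) for the 2x2 table by direct hypergeometric summation."""
    total = a + b + c + d
    k_cat = a + c
    n_sv = a + b

    def hyper(x):
        return (
            math.comb(k_cat, x)
            * math.comb(total - k_cat, n_sv - x)
            / math.comb(total, n_sv)
        )

    return sum(hyper(x) for x in range(a, min(k_cat, n_sv) + 1))


def bh_qvalues(pvalues):
    """Benjamini-Hochberg step-up by the textbook formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        val = min(prev, pvalues[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def mwu_exact_two_sided(xs, ys):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free)."""
    pooled = list(xs) + list(ys)
    assert len(set(pooled)) == len(pooled), "enumeration assumes no ties"
    nx = len(xs)

    def u_stat(group_x, group_y):
        return sum(1 for x in group_x for y in group_y if x > y)

    u_obs = u_stat(xs, ys)
    u_other = len(xs) * len(ys) - u_obs
    u_min = min(u_obs, u_other)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(gx, gy)
        if min(u, len(gx) * len(gy) - u) <= u_min:
            count += 1
        total += 1
    return count / total


def interval_overlap_label(gene_start, gene_end, svs):
    """Per-base brute-force gene labelling: svs are (start, end, type)
    with type 'INS' meaning a breakpoint at start."""
    for s, e, typ in svs:
        if typ == "INS":
            if gene_start <= s < gene_end:
                return "SV"
        else:
            for base in range(s, e):
                if gene_start <= base < gene_end:
                    return "SV"
    return "conserved"
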