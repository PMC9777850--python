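"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (per-base arrays, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict



def per_base_union(intervals):
    """Transitive closure of >= 1 bp overlap for (chrom, start, end) triples.

    Overlap is decided by literal base-set intersection, components by
    union-find over the pairwise overlap graph — the definition of
    "1 bp or more overlap" merging.  Abutting half-open intervals share no
    base and therefore never join (unlike coverage connectivity).
    Returns {chrom: sorted [(start, end), ...] component spans}.
    """
    by_chrom = defaultdict(list)
    for chrom, start, end in intervals:
        by_chrom[chrom].append((start, end))
    out = {}
    for chrom, ivs in by_chrom.items():
        parent = list(range(len(ivs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if set(range(*a)) & set(range(*b)):
                    parent[find(i)] = find(j)
        comps = defaultdict(list)
        for i, iv in enumerate(ivs):
            comps[find(i)].append(iv)
        out[chrom] = sorted(
            (min(s for s, _ in c), max(e for _, e in c)) for c in comps.values()
        )
    return out


def hypergeom_upper_tail(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_step_up(p):
    """Benjamini–Hochberg step-up adjusted p-values, from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def interval_overlap_genes(cnvr, genes, exons):
    """Per-base classification of CNVR/gene overlaps.

    ``cnvr`` is (chrom, start, end); ``genes`` maps gene_id ->
    (chrom, start, end); ``exons`` maps gene_id -> [(start, end), ...].
    Returns {gene_id: 'spanning'|'exonic'|'intronic'} for overlapped genes.
    """
    chrom, cs, ce = cnvr
    hits = {}
    for gid, (gchrom, gs, ge) in genes.items():
        if gchrom != chrom:
            continue
        overlap_bases = set(range(cs, ce)) & set(range(gs, ge))
        if not overlap_bases:
            continue
        if cs <= gs and ce >= ge:
            hits[gid] = "spanning"
            continue
        exon_bases = set()
        for s, e in exons.get(gid, []):
            exon_bases |= set(range(s, e))
        hits[gid] = "exonic" if overlap_bases & exon_bases else "intronic"
    return hits
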