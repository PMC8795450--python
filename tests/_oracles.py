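"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package internals: naive per-read
loops over all genes, explicit interval arithmetic, no index structures.
"""

from __future__ import annotations

import numpy as np


def overlaps_exon_union(read_start: int, read_end: int, exons) -> bool:
    return any(read_start < e and s < read_end for s, e in exons)


def brute_force_count(reads, genes):
    """Per-read union-mode counting by scanning every gene.

    Returns (counts dict {(gene_id, sample? none, orientation, length): n},
    category tally dict). Multimappers (n_hits > 1) are excluded.
    """
    counts: dict[tuple, int] = {}
    tally = {"assigned": 0, "ambiguous": 0, "no_feature": 0, "multimapper": 0}
    for r in reads:
        if r.n_hits > 1:
            tally["multimapper"] += 1
            continue
        hits = [
            g
            for g in genes
            if g.chrom == r.chrom and overlaps_exon_union(r.start, r.end, g.exons)
        ]
        if not hits:
            tally["no_feature"] += 1
        elif len(hits) > 1:
            tally["ambiguous"] += 1
        else:
            g = hits[0]
            orient = "sense" if r.strand == g.strand else "antisense"
            key = (g.gene_id, orient, r.end - r.start)
            counts[key] = counts.get(key, 0) + 1
            tally["assigned"] += 1
    return counts, tally


def brute_force_coverage(reads, chrom: str, length: int) -> np.ndarray:
    """Per-base coverage by explicit base iteration (strand-pooled)."""
    cov = np.zeros(length)
    for r in reads:
        if r.chrom != chrom:
            continue
        for pos in range(r.start, min(r.end, length)):
            cov[pos] += 1
    return cov


def reference_bh(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up written independently (O(n^2) definitional form).

    q_i = min over j with p_(j) >= p_i of p_(j) * m / rank(j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev, 1.0)
        q[i] = val
        prev = val
    return q
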