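"""Per-base coverage tracks: RPTM-normalized bedGraph output and gene coverage.

Coverage is counted per reported alignment over its reference span; tracks
are written one per (sample, strand) in bedGraph (0-based half-open), with
values normalized to reads per ten million.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import GeneModel
from .counting import ReadAlignment, normalize_rptm


def strand_coverage(
    alignments: Iterable[ReadAlignment],
    chrom_lengths: Mapping[str, int],
) -> dict[tuple[str, str], np.ndarray]:
    """Raw per-base read coverage keyed by (chrom, strand)."""
    cov: dict[tuple[str, str], np.ndarray] = {}
    for aln in alignments:
        if aln.chrom not in chrom_lengths:
            continue
        key = (aln.chrom, aln.strand)
        if key not in cov:
            cov[key] = np.zeros(chrom_lengths[aln.chrom])
        arr = cov[key]
        arr[aln.start : min(aln.end, arr.size)] += 1.0
    return cov


def write_bedgraph(
    coverage: Mapping[tuple[str, str], np.ndarray],
    library_size: int,
    path_template: str,
) -> list[str]:
    """Write one RPTM bedGraph per strand; returns the written paths.

    ``path_template`` must contain ``{strand}`` (expanded to plus/minus).
    Runs of equal value are merged into single intervals; zero runs skipped.
    """
    written = []
    for strand_sym, strand_name in (("+", "plus"), ("-", "minus")):
        path = path_template.format(strand=strand_name)
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{strand_name}"\n')
            for (chrom, strand), arr in sorted(coverage.items()):
                if strand != strand_sym:
                    continue
                vals = normalize_rptm(arr, library_size)
                # run-length encode
                change = np.flatnonzero(np.diff(vals)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [vals.size]))
                for s, e in zip(starts, ends):
                    v = vals[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
        written.append(path)
    return written


def gene_coverage(
    alignment_sources: Mapping[str, Iterable[ReadAlignment]],
    genes: Sequence[GeneModel],
    library_sizes: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Strand-pooled per-base RPTM coverage over each gene body.

    Coverage is computed per sample, RPTM-normalized with that sample's
    library size, then averaged across samples — the pooled track used for
    metagene profiles. Arrays run left-to-right in genomic coordinates.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    pooled = {g.gene_id: np.zeros(g.length) for g in genes}
    n_samples = len(alignment_sources)
    if n_samples == 0:
        raise ValueError("no alignment sources")

    for sid, alns in alignment_sources.items():
        chrom_cov: dict[str, np.ndarray] = {}
        maxend: dict[str, int] = {}
        for g in genes:
            maxend[g.chrom] = max(maxend.get(g.chrom, 0), g.end)
        for c, e in maxend.items():
            chrom_cov[c] = np.zeros(e)
        for aln in alns:
            arr = chrom_cov.get(aln.chrom)
            if arr is None:
                continue
            arr[aln.start : min(aln.end, arr.size)] += 1.0
        scale = 1e7 / library_sizes[sid]
        for g in genes:
            pooled[g.gene_id] += chrom_cov[g.chrom][g.start : g.end] * scale
    for gid in pooled:
        pooled[gid] /= n_samples
    return pooled
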