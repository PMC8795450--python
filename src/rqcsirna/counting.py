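"""Small-RNA read counting: union-mode exon assignment and the count tensor.

Reads are assigned to genes with HTSeq-like union semantics on exon-union
intervals: a read overlapping the exon union of exactly one gene is assigned
to it, of two or more genes is *ambiguous*, of none is *no_feature*; reads
with more than one reported alignment are *multimapper* and excluded by
default (optionally counted fractionally at 1/n_hits per hit).

Counts live in a :class:`CountTensor` indexed by
(gene, sample, orientation, read length 15..35 nt) — the pipeline's central
container. Orientation is *sense* when the read strand equals the gene
strand. Normalization is reads per ten million (RPTM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

logger = logging.getLogger(__name__)

MIN_LENGTH, MAX_LENGTH = 15, 35
LENGTHS = tuple(range(MIN_LENGTH, MAX_LENGTH + 1))
ORIENTATIONS = ("sense", "antisense")
CATEGORIES = ("assigned", "ambiguous", "no_feature", "multimapper")

#: one ten-million scaling constant for RPTM tracks and profiles
RPTM_SCALE = 1e7

ALIGNMENT_TSV_COLUMNS = ("read_id", "chrom", "start", "end", "strand", "n_hits")


@dataclass(frozen=True)
class ReadAlignment:
    """A single reported small-RNA alignment (0-based half-open)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int = 1

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not (MIN_LENGTH <= length <= MAX_LENGTH):
            raise ValueError(
                f"read {self.read_id}: length {length} outside [{MIN_LENGTH},{MAX_LENGTH}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")
        if self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleInfo:
    """Library metadata; library_size is the RPTM denominator."""

    sample_id: str
    genotype: str
    replicate: int
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError(f"{self.sample_id}: library_size must be > 0")


def read_alignment_tsv(path: str) -> Iterator[ReadAlignment]:
    """Stream alignments from the tabular dialect (header required)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALIGNMENT_TSV_COLUMNS:
            raise ValueError(
                f"{path}: header must be {list(ALIGNMENT_TSV_COLUMNS)}, got {header}"
            )
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 6:
                continue
            yield ReadAlignment(f[0], f[1], int(f[2]), int(f[3]), f[4], int(f[5]))


def write_alignment_tsv(alignments: Iterable[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t{a.n_hits}\n")


def read_alignment_bam(path: str) -> Iterator[ReadAlignment]:
    """Stream alignments from BAM/SAM via pysam (NH tag -> n_hits, default 1)."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
            yield ReadAlignment(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                int(n_hits),
            )


def open_alignments(path: str) -> Iterator[ReadAlignment]:
    if str(path).endswith((".bam", ".sam")):
        return read_alignment_bam(path)
    return read_alignment_tsv(path)


class GeneIndex:
    """Interval lookup over exon-union intervals, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene_id in annotation")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e, g.gene_id)
        self._warned_chroms: set[str] = set()

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %r absent from annotation; reads -> no_feature", chrom)
                self._warned_chroms.add(chrom)
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


@dataclass(frozen=True)
class Assignment:
    category: str  # assigned | ambiguous | no_feature | multimapper
    gene_id: str | None = None
    orientation: str | None = None


def assign_read(aln: ReadAlignment, index: GeneIndex, count_multimappers: bool = False) -> Assignment:
    """Union-mode assignment of one alignment (see module docstring)."""
    if aln.n_hits > 1 and not count_multimappers:
        return Assignment("multimapper")
    hits = index.overlapping_genes(aln.chrom, aln.start, aln.end)
    if not hits:
        return Assignment("no_feature")
    if len(hits) > 1:
        return Assignment("ambiguous")
    gene_id = next(iter(hits))
    orientation = "sense" if aln.strand == index.genes[gene_id].strand else "antisense"
    return Assignment("assigned", gene_id, orientation)


class CountTensor:
    """gene x sample x orientation x length counts with labelled axes."""

    def __init__(self, counts: np.ndarray, gene_ids: Sequence[str], sample_ids: Sequence[str]):
        counts = np.asarray(counts, dtype=float)
        expected = (len(gene_ids), len(sample_ids), len(ORIENTATIONS), len(LENGTHS))
        if counts.shape != expected:
            raise ValueError(f"counts shape {counts.shape} != {expected}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self._gidx = {g: i for i, g in enumerate(self.gene_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._gidx) != len(self.gene_ids):
            raise ValueError("duplicate gene_id")
        if len(self._sidx) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")

    @classmethod
    def zeros(cls, gene_ids: Sequence[str], sample_ids: Sequence[str]) -> "CountTensor":
        return cls(
            np.zeros((len(gene_ids), len(sample_ids), len(ORIENTATIONS), len(LENGTHS))),
            gene_ids,
            sample_ids,
        )

    def add(self, gene_id: str, sample_id: str, orientation: str, length: int, weight: float = 1.0) -> None:
        self.counts[
            self._gidx[gene_id],
            self._sidx[sample_id],
            ORIENTATIONS.index(orientation),
            length - MIN_LENGTH,
        ] += weight

    def collapse(
        self,
        length_range: tuple[int, int] | None = None,
        orientation: str = "both",
    ) -> pd.DataFrame:
        """Sum over a (length, orientation) slice -> gene x sample matrix.

        ``length_range`` is an inclusive (lo, hi) interval or None for all
        lengths; ``orientation`` is sense, antisense or both. The all/both
        collapse reproduces unstranded counting.
        """
        if length_range is None:
            lsel = slice(None)
        else:
            lo, hi = length_range
            if lo > hi or hi < MIN_LENGTH or lo > MAX_LENGTH:
                raise ValueError(f"empty length selection {length_range}")
            if lo < MIN_LENGTH or hi > MAX_LENGTH:
                raise ValueError(f"length range {length_range} outside [{MIN_LENGTH},{MAX_LENGTH}]")
            lsel = slice(lo - MIN_LENGTH, hi - MIN_LENGTH + 1)
        if orientation == "both":
            osel = slice(None)
        elif orientation in ORIENTATIONS:
            osel = slice(ORIENTATIONS.index(orientation), ORIENTATIONS.index(orientation) + 1)
        else:
            raise ValueError(f"orientation must be sense/antisense/both, got {orientation!r}")
        mat = self.counts[:, :, osel, lsel].sum(axis=(2, 3))
        return pd.DataFrame(mat, index=self.gene_ids, columns=self.sample_ids)

    def total(self) -> float:
        return float(self.counts.sum())

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=(0, 2, 3)), index=self.sample_ids)

    def to_tsv(self, path: str) -> None:
        """Long-format TSV of non-zero entries (gene, sample, orientation, length, count)."""
        g, s, o, l = np.nonzero(self.counts)
        df = pd.DataFrame(
            {
                "gene_id": [self.gene_ids[i] for i in g],
                "sample_id": [self.sample_ids[i] for i in s],
                "orientation": [ORIENTATIONS[i] for i in o],
                "length": [LENGTHS[i] for i in l],
                "count": self.counts[g, s, o, l],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str, gene_ids: Sequence[str] | None = None, sample_ids: Sequence[str] | None = None
    ) -> "CountTensor":
        df = pd.read_csv(path, sep="\t")
        if gene_ids is None:
            gene_ids = sorted(df["gene_id"].unique())
        if sample_ids is None:
            sample_ids = sorted(df["sample_id"].unique())
        t = cls.zeros(gene_ids, sample_ids)
        for row in df.itertuples(index=False):
            t.add(row.gene_id, row.sample_id, row.orientation, int(row.length), float(row.count))
        return t


def build_count_tensor(
    alignment_sources: Mapping[str, str | Iterable[ReadAlignment]],
    genes: Sequence[GeneModel],
    samples: Sequence[SampleInfo],
    count_multimappers: bool = False,
) -> tuple[CountTensor, pd.DataFrame]:
    """Count every sample's alignments into a tensor.

    ``alignment_sources`` maps sample_id to a file path (TSV/BAM/SAM dialects)
    or an iterable of :class:`ReadAlignment`. With ``count_multimappers``,
    each reported hit contributes 1/n_hits. Returns the tensor and a
    per-sample assignment-statistics table (assigned/ambiguous/no_feature/
    multimapper).
    """
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in sample sheet")
    missing = [s for s in sample_ids if s not in alignment_sources]
    if missing:
        raise ValueError(f"samples without an alignment source: {missing}")

    index = GeneIndex(genes)
    tensor = CountTensor.zeros([g.gene_id for g in genes], sample_ids)
    stats = {s: dict.fromkeys(CATEGORIES, 0) for s in sample_ids}

    for sid in sample_ids:
        src = alignment_sources[sid]
        alns = open_alignments(src) if isinstance(src, (str,)) else src
        n = 0
        for aln in alns:
            n += 1
            res = assign_read(aln, index, count_multimappers=count_multimappers)
            if aln.n_hits > 1 and count_multimappers:
                stats[sid]["multimapper"] += 1
                if res.category == "assigned":
                    tensor.add(res.gene_id, sid, res.orientation, aln.length, 1.0 / aln.n_hits)
                continue
            stats[sid][res.category] += 1
            if res.category == "assigned":
                tensor.add(res.gene_id, sid, res.orientation, aln.length)
        if n == 0:
            logger.warning("sample %s: empty alignment source (all-zero column)", sid)
        logger.info("sample %s: %s", sid, stats[sid])

    stats_df = pd.DataFrame(stats).T[list(CATEGORIES)]
    stats_df.index.name = "sample_id"
    return tensor, stats_df


def effective_library_sizes(
    tensor: CountTensor, samples: Sequence[SampleInfo]
) -> pd.Series:
    """Per-sample RPTM denominators: sample-sheet value, else assigned total."""
    totals = tensor.sample_totals()
    out = {}
    for s in samples:
        out[s.sample_id] = float(s.library_size) if s.library_size else float(totals[s.sample_id])
        if out[s.sample_id] <= 0:
            raise ValueError(f"sample {s.sample_id}: library size is 0; cannot normalize")
    return pd.Series(out)


def normalize_rptm(count, library_size):
    """Reads per ten million: count / library_size * 1e7 (scalar or array)."""
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library_size must be > 0")
    return np.multiply(count, RPTM_SCALE) / library_size


def read_sample_sheet(path: str) -> tuple[list[SampleInfo], dict[str, str]]:
    """Sample sheet TSV -> (SampleInfo list, sample_id -> alignment path map).

    Columns: sample_id, genotype, replicate, optional library_size, optional
    path. The path map is empty when no path column is present.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    infos, paths = [], {}
    for row in df.itertuples(index=False):
        lib = getattr(row, "library_size", None)
        lib = int(lib) if lib is not None and not pd.isna(lib) else None
        infos.append(SampleInfo(str(row.sample_id), str(row.genotype), int(row.replicate), lib))
        p = getattr(row, "path", None)
        if p is not None and not pd.isna(p):
            paths[str(row.sample_id)] = str(p)
    return infos, paths


def write_sample_sheet(samples: Sequence[SampleInfo], path: str, paths: Mapping[str, str] | None = None) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "genotype": s.genotype,
            "replicate": s.replicate,
            "library_size": s.library_size if s.library_size else "",
        }
        if paths:
            row["path"] = paths.get(s.sample_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
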