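"""Gene annotation: parsing, exon-union models, biotypes and convergent partners.

All coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted on ingest and on write; BED is taken as-is. Genes are reduced to an
exon-union model: exons of all isoforms merged into disjoint intervals.

A *convergent partner* of a focal gene is the nearest opposite-strand gene
downstream of the focal gene's 3' end (tail-to-tail orientation). The distance
is the gap between annotated gene bodies; overlapping tail-to-tail pairs have
negative distance and fall in the "< threshold" class.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

#: canonical biotype classes used throughout the pipeline
BIOTYPE_CLASSES = (
    "protein_coding",
    "lncRNA",
    "structural_rna",
    "pseudogene_te",
    "other",
)

#: default mapping from annotation biotype strings to the five classes
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": "protein_coding",
    "mRNA": "protein_coding",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
    "long_noncoding_rna": "lncRNA",
    "antisense_long_noncoding_rna": "lncRNA",
    "antisense_rna": "lncRNA",
    "novel_transcribed_region": "lncRNA",
    "tRNA": "structural_rna",
    "snRNA": "structural_rna",
    "snoRNA": "structural_rna",
    "rRNA": "structural_rna",
    "structural_rna": "structural_rna",
    "pseudogene": "pseudogene_te",
    "transposable_element": "pseudogene_te",
    "transposable_element_gene": "pseudogene_te",
    "transposon_fragment": "pseudogene_te",
    "pseudogene_te": "pseudogene_te",
    "other": "other",
    "miRNA": "other",
    "otherRNA": "other",
}

DISTANCE_CLASSES = ("convergent_lt_threshold", "convergent_ge_threshold", "no_partner")

#: default 3'-3' distance (bp) separating the near from the far convergent class
DEFAULT_DISTANCE_THRESHOLD = 400
#: default window (bp) scanned downstream of a gene's 3' end for a partner
DEFAULT_MAX_SCAN_BP = 10_000


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records; carries the line number."""


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with exon-union intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown biotype class {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: exons must be non-empty")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene body ({self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (end for +, start for -)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class ConvergencePartner:
    """Nearest tail-to-tail partner of a focal gene, or absence thereof."""

    focal_gene_id: str
    partner_gene_id: str | None
    distance_bp: int | None
    distance_class: str

    def __post_init__(self) -> None:
        if self.distance_class not in DISTANCE_CLASSES:
            raise ValueError(f"unknown distance class {self.distance_class!r}")
        if (self.partner_gene_id is None) != (self.distance_bp is None):
            raise ValueError("partner and distance must be both present or both absent")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals as disjoint sorted intervals."""
    ivs = sorted(intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def classify_biotype(raw: str, biotype_map: Mapping[str, str] | None = None) -> str:
    """Map an annotation biotype string to one of the five classes.

    Unmapped strings become ``other`` with a logged warning.
    """
    table = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    try:
        return table[raw]
    except KeyError:
        logger.warning("unmapped biotype %r assigned to class 'other'", raw)
        return "other"


def load_biotype_map(path: str) -> dict[str, str]:
    """Load a biotype mapping table from a YAML file ({raw_string: class})."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    bad = {v for v in table.values() if v not in BIOTYPE_CLASSES}
    if bad:
        raise ValueError(f"biotype map contains unknown classes: {sorted(bad)}")
    return table


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff3(
    path: str,
    biotype_keys: Sequence[str] = ("locus_type", "biotype", "gene_biotype"),
    biotype_map: Mapping[str, str] | None = None,
    gene_features: frozenset[str] = frozenset(
        {"gene", "pseudogene", "transposable_element_gene"}
    ),
) -> list[GeneModel]:
    """Parse a GFF3 file into exon-union :class:`GeneModel` records.

    The biotype is taken from the first matching attribute key; for gene
    feature types other than plain ``gene`` the feature type itself is used as
    fallback. Exons are attached to genes either directly (``Parent=<gene>``)
    or through one transcript level, then merged across isoforms. A gene with
    no exon rows gets its whole body as a single exon.
    """
    genes_raw: dict[str, dict] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    exon_rows: list[tuple[str, int, int, int]] = []  # parent, start, end, line no

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gff3_attributes(attr_s)
            if ftype in gene_features:
                gid = attrs.get("ID")
                if gid is None:
                    raise AnnotationParseError(f"{path}:{lineno}: gene record lacks ID")
                raw_bt = next(
                    (attrs[k] for k in biotype_keys if k in attrs),
                    ftype if ftype != "gene" else "other",
                )
                genes_raw[gid] = {
                    "chrom": chrom,
                    "start": start1 - 1,  # GFF3 is 1-based closed
                    "end": end1,
                    "strand": strand,
                    "biotype": classify_biotype(raw_bt, biotype_map),
                    "exons": [],
                    "lineno": lineno,
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise AnnotationParseError(f"{path}:{lineno}: exon record lacks Parent")
                exon_rows.append((parent.split(",")[0], start1 - 1, end1, lineno))
            else:
                # transcript-level feature: remember its gene parent
                fid, parent = attrs.get("ID"), attrs.get("Parent")
                if fid and parent:
                    parent_of[fid] = parent.split(",")[0]

    for parent, s, e, lineno in exon_rows:
        gid = parent
        seen = set()
        while gid not in genes_raw:
            if gid in seen or gid not in parent_of:
                raise AnnotationParseError(
                    f"{path}:{lineno}: exon parent {parent!r} does not resolve to a gene"
                )
            seen.add(gid)
            gid = parent_of[gid]
        genes_raw[gid]["exons"].append((s, e))

    out = []
    for gid, rec in genes_raw.items():
        exons = merge_intervals(rec["exons"]) or ((rec["start"], rec["end"]),)
        out.append(
            GeneModel(gid, rec["chrom"], rec["start"], rec["end"], rec["strand"], rec["biotype"], exons)
        )
    return out


def read_bed12(path: str, biotype_map: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Parse BED12 into GeneModels; blocks become exons.

    An optional 13th column carries the biotype string (BED itself has no
    attributes); absent, genes are classified ``other``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationParseError(f"{path}:{lineno}: BED12 needs >= 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed BED12 record") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationParseError(f"{path}:{lineno}: blockCount mismatch")
            exons = merge_intervals((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            raw_bt = f[12] if len(f) > 12 else "other"
            out.append(
                GeneModel(name, chrom, start, end, strand, classify_biotype(raw_bt, biotype_map), exons)
            )
    return out


def read_annotation(path: str, format: str = "gff3", **kwargs) -> list[GeneModel]:
    """Read an annotation file in the named format (``gff3`` or ``bed12``)."""
    if format == "gff3":
        return read_gff3(path, **kwargs)
    if format == "bed12":
        return read_bed12(path, **kwargs)
    raise ValueError(f"unknown annotation format {format!r}")


def write_gff3(genes: Iterable[GeneModel], path: str, source: str = "rqcsirna") -> None:
    """Write GeneModels as GFF3 (gene + exon rows, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _check_sorted(genes: Sequence[GeneModel]) -> None:
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom and a.start > b.start:
            raise ValueError("gene list must be sorted by (chrom, start)")


def sort_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def distance_class_of(distance_bp: int | None, threshold: int = DEFAULT_DISTANCE_THRESHOLD) -> str:
    if distance_bp is None:
        return "no_partner"
    return "convergent_lt_threshold" if distance_bp < threshold else "convergent_ge_threshold"


def find_convergent_partner(
    focal: GeneModel,
    genes: Sequence[GeneModel],
    max_scan_bp: int = DEFAULT_MAX_SCAN_BP,
    threshold: int = DEFAULT_DISTANCE_THRESHOLD,
) -> ConvergencePartner:
    """Nearest opposite-strand gene downstream of the focal 3' end.

    Distance is the gap between gene bodies (negative for tail-to-tail
    overlap). No qualifying gene within ``max_scan_bp`` -> ``no_partner``.
    ``genes`` must be sorted by (chrom, start) and contain the focal gene.
    """
    if max_scan_bp <= 0:
        raise ValueError("max_scan_bp must be > 0")
    _check_sorted(genes)
    if not any(g.gene_id == focal.gene_id for g in genes):
        raise ValueError(f"focal gene {focal.gene_id} absent from gene list")

    best: tuple[int, str] | None = None  # (distance, partner_id)
    for g in genes:
        if g.chrom != focal.chrom or g.strand == focal.strand or g.gene_id == focal.gene_id:
            continue
        if focal.strand == "+":
            # partner's body must begin at/after the focal body start (tail-to-tail)
            if g.start < focal.start:
                continue
            d = g.start - focal.end
        else:
            if g.end > focal.end:
                continue
            d = focal.start - g.end
        if d > max_scan_bp:
            continue
        cand = (d, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return ConvergencePartner(focal.gene_id, None, None, "no_partner")
    d, pid = best
    return ConvergencePartner(focal.gene_id, pid, d, distance_class_of(d, threshold))


def convergence_table(
    genes: Sequence[GeneModel],
    max_scan_bp: int = DEFAULT_MAX_SCAN_BP,
    threshold: int = DEFAULT_DISTANCE_THRESHOLD,
) -> dict[str, ConvergencePartner]:
    """Convergent-partner record for every gene, keyed by gene_id.

    O(n log n) per chromosome via binary search on sorted opposite-strand
    coordinates, so it scales to genome-size annotations.
    """
    import bisect

    genes = sort_genes(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: dict[str, ConvergencePartner] = {}
    for chrom_genes in by_chrom.values():
        plus = [g for g in chrom_genes if g.strand == "+"]
        minus = [g for g in chrom_genes if g.strand == "-"]
        # + focal: nearest minus gene by smallest start >= focal.start
        minus_by_start = sorted(minus, key=lambda g: (g.start, g.gene_id))
        minus_starts = [g.start for g in minus_by_start]
        for focal in plus:
            i = bisect.bisect_left(minus_starts, focal.start)
            rec = None
            if i < len(minus_by_start):
                g = minus_by_start[i]  # ties already resolved by gene_id sort
                d = g.start - focal.end
                if d <= max_scan_bp:
                    rec = ConvergencePartner(
                        focal.gene_id, g.gene_id, d, distance_class_of(d, threshold)
                    )
            out[focal.gene_id] = rec or ConvergencePartner(focal.gene_id, None, None, "no_partner")
        # - focal: nearest plus gene by largest end <= focal.end
        # stable two-pass sort: id descending, then end ascending, so among
        # equal ends the last element carries the lexicographically smallest id
        plus_by_end = sorted(plus, key=lambda g: g.gene_id, reverse=True)
        plus_by_end.sort(key=lambda g: g.end)
        plus_ends = [g.end for g in plus_by_end]
        for focal in minus:
            i = bisect.bisect_right(plus_ends, focal.end) - 1
            rec = None
            if i >= 0:
                g = plus_by_end[i]  # ties: last element has lexicographically smallest id
                d = focal.start - g.end
                if d <= max_scan_bp:
                    rec = ConvergencePartner(
                        focal.gene_id, g.gene_id, d, distance_class_of(d, threshold)
                    )
            out[focal.gene_id] = rec or ConvergencePartner(focal.gene_id, None, None, "no_partner")
    return out
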