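"""Candidate filter cascade for rqc-siRNA source genes.

Genes with significantly elevated small RNAs are winnowed in three stages:

1. biotype — only protein-coding genes can be rqc-siRNA sources; structural
   RNAs, lncRNAs, pseudogenes/transposons are set aside;
2. strandedness — genuine RNA-quality-control siRNAs derive from
   double-stranded RNA, so the sense/antisense read ratio must fall within
   [0.25, 4] (inclusive); strongly one-sided genes are mRNA degradation
   fragments, not siRNAs;
3. methylation hotspots — genes with more than 20% of all cytosines
   methylated produce siRNAs constitutively (RdDM hotspots) and are excluded
   as pre-existing sources rather than mutant-specific ones.

Survivors are the rqc-siRNA candidate set. Each input gene receives exactly
one category, so the tallies partition the significant set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import BIOTYPE_CLASSES, GeneModel
from .counting import CountTensor

logger = logging.getLogger(__name__)

CATEGORIES = ("non_protein_coding", "one_strand_only", "hotspot_only", "both_flags", "rqc_candidate")
DEFAULT_RATIO_BOUNDS = (0.25, 4.0)
DEFAULT_METHYLATION_THRESHOLD = 0.20

REPORT_COLUMNS = (
    "gene_id",
    "biotype",
    "strand_ratio",
    "one_strand",
    "methylation_fraction",
    "hotspot",
    "wt_rptm",
    "category",
)


@dataclass(frozen=True)
class MethylationRecord:
    gene_id: str
    methylated_c: int
    total_c: int

    def __post_init__(self) -> None:
        if self.methylated_c < 0 or self.total_c < 0:
            raise ValueError(f"{self.gene_id}: negative cytosine counts")
        if self.methylated_c > self.total_c:
            raise ValueError(f"{self.gene_id}: methylated_c > total_c")

    @property
    def fraction(self) -> float | None:
        return self.methylated_c / self.total_c if self.total_c > 0 else None


def read_methylation_tsv(path: str) -> dict[str, MethylationRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "methylated_c", "total_c"}
    if not need.issubset(df.columns):
        raise ValueError(f"methylation table needs columns {sorted(need)}")
    return {
        str(r.gene_id): MethylationRecord(str(r.gene_id), int(r.methylated_c), int(r.total_c))
        for r in df.itertuples(index=False)
    }


def partition_biotype(
    gene_ids: Sequence[str] | set[str], annotation: Mapping[str, GeneModel]
) -> tuple[dict[str, int], set[str]]:
    """Count genes per biotype class; return counts and the coding subset."""
    missing = sorted(g for g in gene_ids if g not in annotation)
    if missing:
        raise KeyError(f"genes absent from annotation: {missing}")
    counts = dict.fromkeys(BIOTYPE_CLASSES, 0)
    coding = set()
    for g in gene_ids:
        bt = annotation[g].biotype
        counts[bt] += 1
        if bt == "protein_coding":
            coding.add(g)
    return counts, coding


def strand_ratio(
    sense_count: float,
    antisense_count: float,
    bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS,
) -> tuple[float | None, bool]:
    """Sense/antisense ratio and the double-strand criterion (inclusive bounds).

    A zero antisense count leaves the ratio undefined and fails — a gene
    producing reads from one strand only is exactly what the filter removes.
    """
    if sense_count < 0 or antisense_count < 0:
        raise ValueError("counts must be non-negative")
    if antisense_count == 0:
        return None, False
    ratio = sense_count / antisense_count
    lo, hi = bounds
    return ratio, bool(lo <= ratio <= hi)


def methylation_hotspot(
    record: MethylationRecord, threshold: float = DEFAULT_METHYLATION_THRESHOLD
) -> bool:
    """True iff the methylated-cytosine fraction strictly exceeds threshold."""
    frac = record.fraction
    if frac is None:
        logger.warning("%s: no cytosines in methylation record; not a hotspot", record.gene_id)
        return False
    return frac > threshold


def categorize(biotype: str, one_strand: bool, hotspot: bool) -> str:
    """Filter category precedence: biotype, then the two flag combinations."""
    if biotype != "protein_coding":
        return "non_protein_coding"
    if one_strand and hotspot:
        return "both_flags"
    if one_strand:
        return "one_strand_only"
    if hotspot:
        return "hotspot_only"
    return "rqc_candidate"


def apply_filter_cascade(
    sig_genes: Sequence[str] | set[str],
    tensor: CountTensor,
    annotation: Mapping[str, GeneModel],
    methylation: Mapping[str, MethylationRecord],
    mutant_samples: Sequence[str],
    ratio_bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS,
    methylation_threshold: float = DEFAULT_METHYLATION_THRESHOLD,
    length_range: tuple[int, int] | None = None,
    wt_rptm: Mapping[str, float] | None = None,
    missing_methylation: str = "warn",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full cascade over the significant gene set.

    Strand counts are sense/antisense sums over the mutant replicates
    (raw counts; optionally restricted to ``length_range``). Genes without a
    methylation record are treated as non-hotspots with a logged warning
    (``missing_methylation='error'`` raises instead). ``wt_rptm`` is an
    optional informational column (constitutive wild-type siRNA output) and
    never filters.

    Returns (per-gene FilterReport table, category tallies).
    """
    sense = tensor.collapse(length_range, "sense")[list(mutant_samples)].sum(axis=1)
    anti = tensor.collapse(length_range, "antisense")[list(mutant_samples)].sum(axis=1)

    rows = []
    for gid in sorted(sig_genes):
        if gid not in annotation:
            raise KeyError(f"gene {gid} absent from annotation")
        biotype = annotation[gid].biotype
        ratio, passes = strand_ratio(float(sense.get(gid, 0)), float(anti.get(gid, 0)), ratio_bounds)
        one_strand = not passes
        rec = methylation.get(gid)
        if rec is None:
            if missing_methylation == "error":
                raise KeyError(f"gene {gid} has no methylation record")
            logger.warning("%s: no methylation record; hotspot assumed False", gid)
            frac, hot = np.nan, False
        else:
            frac = rec.fraction if rec.fraction is not None else np.nan
            hot = methylation_hotspot(rec, methylation_threshold)
        rows.append(
            {
                "gene_id": gid,
                "biotype": biotype,
                "strand_ratio": ratio if ratio is not None else np.nan,
                "one_strand": one_strand,
                "methylation_fraction": frac,
                "hotspot": hot,
                "wt_rptm": (wt_rptm or {}).get(gid, np.nan),
                "category": categorize(biotype, one_strand, hot),
            }
        )
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    tallies = dict.fromkeys(CATEGORIES, 0)
    for cat in report["category"]:
        tallies[cat] += 1
    return report, tallies


def rqc_candidates(report: pd.DataFrame) -> set[str]:
    return set(report.loc[report["category"] == "rqc_candidate", "gene_id"])


def write_filter_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_tallies(tallies: Mapping[str, int], path: str) -> None:
    pd.DataFrame(
        {"category": list(tallies.keys()), "n_genes": list(tallies.values())}
    ).to_csv(path, sep="\t", index=False)
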