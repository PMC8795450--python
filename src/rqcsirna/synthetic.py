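"""Seeded synthetic data embodying the generative structure the analysis assumes.

The generator emulates a plant-style genome arm in which a transcription-
termination mutant produces RNA-quality-control siRNAs from read-through-
affected convergent genes, alongside the confounders the filter cascade must
remove:

* ``rqc_readthrough`` genes — mostly members of tail-to-tail convergent
  pairs at short (< 400 bp) 3'-3' distances; mutant-elevated counts on BOTH
  strands with the characteristic 21/22/24-nt length profile;
* ``one_strand_degradation`` genes — highly expressed genes shedding
  sense-strand-only degradation fragments with a broad length profile,
  also elevated in the mutant (so they enter the significant set and must be
  caught by the strand-ratio filter);
* ``methylation_hotspot`` genes — constitutive 24-nt double-strand siRNA
  producers, high in both genotypes with a moderate extra mutant elevation,
  and methylated-cytosine fractions above 20%;
* ``unaffected`` genes — negative-binomial noise around a common mean in
  both genotypes.

Counts are generated first (fast path feeding the tensor directly); an
optional read-placement step materialises per-sample alignment TSVs for the
counting path. All randomness flows from one master seed through per-output
child streams, so adding one output never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, sort_genes, write_gff3
from .counting import (
    LENGTHS,
    CountTensor,
    ReadAlignment,
    SampleInfo,
    write_alignment_tsv,
    write_sample_sheet,
)

CLASSES = ("rqc_readthrough", "one_strand_degradation", "methylation_hotspot", "unaffected")

TRUTH_COLUMNS = (
    "gene_id",
    "class_label",
    "true_log2fc",
    "has_convergent_partner",
    "true_distance_bp",
    "methylation_fraction",
)


def _length_profile(peaks: dict[int, float]) -> np.ndarray:
    """Distribution over 15..35 nt: named peaks plus a uniform remainder."""
    p = np.full(len(LENGTHS), 0.0)
    for length, mass in peaks.items():
        p[length - LENGTHS[0]] = mass
    rest = 1.0 - p.sum()
    if rest < -1e-9:
        raise ValueError("peak masses exceed 1")
    p += max(rest, 0.0) / len(LENGTHS)
    return p / p.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for the default synthetic scenario.

    Defaults give a desk-scale, comfortably powered experiment: 2,000 genes
    on one chromosome arm, triplicate mutant and control libraries,
    NB dispersion 0.05, and a 5/5/5/85% class split with an 8-fold
    (log2FC = 3) read-through effect.
    """

    n_genes: int = 2000
    chrom: str = "Chr1"
    chrom_length: int = 60_000_000
    fraction_convergent: float = 0.25
    # background pair distances: uniform over [lo, hi] bp
    background_distance_range: tuple[int, int] = (50, 3000)
    # rqc pair distances: uniform over [lo, hi] bp (mostly < 400, overlap allowed)
    rqc_distance_range: tuple[int, int] = (-100, 350)
    rqc_convergent_prob: float = 0.9
    replicates_per_genotype: int = 3
    control_genotype: str = "wt"
    mutant_genotype: str = "mut"
    expression_log2_mean: float = 5.0
    expression_log2_sd: float = 1.0
    nb_dispersion: float = 0.05
    class_fractions: dict = field(
        default_factory=lambda: {
            "rqc_readthrough": 0.05,
            "one_strand_degradation": 0.05,
            "methylation_hotspot": 0.05,
            "unaffected": 0.85,
        }
    )
    rqc_effect_log2fc: float = 3.0
    one_strand_effect_log2fc: float = 3.0
    hotspot_effect_log2fc: float = 2.0
    hotspot_log2_mean: float = 7.0
    rqc_log2_mean: float = 4.0
    # biotype mix among unaffected genes (affected classes are protein-coding)
    noncoding_fraction: float = 0.12
    max_scan_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if set(self.class_fractions) != set(CLASSES):
            raise ValueError(f"class fractions must cover {CLASSES}")
        for f in (self.fraction_convergent, self.rqc_convergent_prob, self.noncoding_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.rqc_distance_range[0] < -200 or self.background_distance_range[0] < -200:
            raise ValueError("pair distances below -200 bp are not generated")
        if max(self.rqc_distance_range[1], self.background_distance_range[1]) > self.max_scan_bp:
            raise ValueError("pair distances must stay within max_scan_bp")

    #: per-class read-length distributions over 15..35 nt
    def length_profiles(self) -> dict[str, np.ndarray]:
        return {
            "rqc_readthrough": _length_profile({21: 0.33, 22: 0.17, 24: 0.33}),
            "one_strand_degradation": _length_profile({}),  # broad/uniform
            "methylation_hotspot": _length_profile({23: 0.05, 24: 0.75, 25: 0.05}),
            "unaffected": _length_profile({21: 0.25, 24: 0.35}),
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    samples: list[SampleInfo]
    tensor: CountTensor
    methylation: pd.DataFrame

    def write(self, outdir: str, alignments: bool = False) -> dict[str, str]:
        """Emit all artefacts under one directory; returns the path manifest."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "annotation": os.path.join(outdir, "annotation.gff3"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "counts": os.path.join(outdir, "counts.tsv"),
            "sample_sheet": os.path.join(outdir, "samples.tsv"),
            "methylation": os.path.join(outdir, "methylation.tsv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        write_gff3(self.genes, paths["annotation"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.tensor.to_tsv(paths["counts"])
        self.methylation.to_csv(paths["methylation"], sep="\t", index=False)
        aln_paths: dict[str, str] = {}
        if alignments:
            per_sample = place_reads(self.tensor, self.genes, self.config)
            for sid, alns in per_sample.items():
                p = os.path.join(outdir, f"alignments_{sid}.tsv")
                write_alignment_tsv(alns, p)
                aln_paths[sid] = p
                paths[f"alignments_{sid}"] = p
        write_sample_sheet(self.samples, paths["sample_sheet"], paths=aln_paths or None)
        with open(paths["manifest"], "w") as fh:
            cfg = dataclasses.asdict(self.config)
            json.dump({"config": cfg, "seed": self.config.seed, "files": paths}, fh, indent=2, default=str)
        return paths


def _spawn(seed: int, n: int = 5) -> list[np.random.Generator]:
    # fixed child-stream roles: 0 layout, 1 classes, 2 counts, 3 reads, 4 methylation
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_annotation(cfg: SyntheticConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out genes (singles and tail-to-tail pairs) and assign truth classes.

    Units (pairs or singles) are separated by gaps larger than the partner
    scan window, so the only convergent relationships are the constructed
    ones. Deterministic per seed.
    """
    rng_layout, rng_class = _spawn(cfg.seed)[:2]
    n = cfg.n_genes

    class_labels = rng_class.choice(
        CLASSES, size=n, p=[cfg.class_fractions[c] for c in CLASSES]
    )
    # convergent membership: rqc genes with high probability, then top up from
    # the other classes until the configured overall fraction is met
    is_rqc = class_labels == "rqc_readthrough"
    convergent = np.zeros(n, dtype=bool)
    convergent[is_rqc] = rng_class.random(is_rqc.sum()) < cfg.rqc_convergent_prob
    target = int(round(cfg.fraction_convergent * n))
    deficit = max(target - int(convergent.sum()), 0)
    pool = np.flatnonzero(~convergent & ~is_rqc)
    if deficit > len(pool):
        deficit = len(pool)
    extra = rng_class.choice(pool, size=deficit, replace=False)
    convergent[extra] = True

    # biotypes: affected classes are protein-coding; a slice of the unaffected
    # genes carries the other four biotype classes
    biotypes = np.array(["protein_coding"] * n, dtype=object)
    unaffected = np.flatnonzero(class_labels == "unaffected")
    n_nc = int(round(cfg.noncoding_fraction * n))
    nc_idx = rng_class.choice(unaffected, size=min(n_nc, len(unaffected)), replace=False)
    nc_classes = rng_class.choice(["lncRNA", "structural_rna", "pseudogene_te", "other"], size=len(nc_idx))
    biotypes[nc_idx] = nc_classes

    # pair up convergent genes: rqc genes pair preferentially with unaffected
    # partners; remaining convergent genes pair among themselves
    conv_rqc = [int(i) for i in np.flatnonzero(convergent & is_rqc)]
    conv_other = [int(i) for i in np.flatnonzero(convergent & ~is_rqc)]
    rng_layout.shuffle(conv_other)
    pairs: list[tuple[int, int, int]] = []  # (gene_a, gene_b, distance)
    for i in conv_rqc:
        if not conv_other:
            break
        j = conv_other.pop()
        d = int(rng_layout.integers(cfg.rqc_distance_range[0], cfg.rqc_distance_range[1] + 1))
        pairs.append((i, j, d))
    while len(conv_other) >= 2:
        i, j = conv_other.pop(), conv_other.pop()
        d = int(
            rng_layout.integers(
                cfg.background_distance_range[0], cfg.background_distance_range[1] + 1
            )
        )
        pairs.append((i, j, d))
    paired = {i for p in pairs for i in p[:2]}
    convergent = np.zeros(n, dtype=bool)
    convergent[list(paired)] = True
    singles = [int(i) for i in range(n) if i not in paired]

    # genomic layout: shuffle unit order, place sequentially with wide gaps
    units: list[tuple] = [("pair", p) for p in pairs] + [("single", i) for i in singles]
    rng_layout.shuffle(units)
    lengths = np.clip(
        rng_layout.lognormal(mean=np.log(1500), sigma=0.4, size=n).astype(int), 400, 8000
    )
    cursor = 1000
    starts = np.zeros(n, dtype=int)
    ends = np.zeros(n, dtype=int)
    strands = np.array(["+"] * n, dtype=object)
    distance = np.full(n, np.nan)
    for unit in units:
        gap = int(rng_layout.integers(cfg.max_scan_bp + 500, cfg.max_scan_bp + 5000))
        if unit[0] == "single":
            i = unit[1]
            strands[i] = rng_layout.choice(["+", "-"])
            starts[i], ends[i] = cursor, cursor + lengths[i]
            cursor = ends[i] + gap
        else:
            i, j, d = unit[1]
            # overlap capped so both bodies keep tail-to-tail geometry
            d = max(d, -int(min(lengths[i], lengths[j]) // 2))
            strands[i], strands[j] = "+", "-"
            starts[i], ends[i] = cursor, cursor + lengths[i]
            starts[j] = ends[i] + d
            ends[j] = starts[j] + lengths[j]
            distance[i] = distance[j] = d
            cursor = ends[j] + gap
    if cursor > cfg.chrom_length:
        raise ValueError(
            f"layout needs {cursor} bp but chrom_length is {cfg.chrom_length}; "
            "reduce n_genes or enlarge the chromosome"
        )

    genes = []
    for i in range(n):
        gid = f"SYNG{i + 1:05d}"
        exons = _make_exons(int(starts[i]), int(ends[i]), rng_layout)
        genes.append(
            GeneModel(gid, cfg.chrom, int(starts[i]), int(ends[i]), str(strands[i]), str(biotypes[i]), exons)
        )

    effect = {
        "rqc_readthrough": cfg.rqc_effect_log2fc,
        "one_strand_degradation": cfg.one_strand_effect_log2fc,
        "methylation_hotspot": cfg.hotspot_effect_log2fc,
        "unaffected": 0.0,
    }
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "class_label": class_labels,
            "true_log2fc": [effect[c] for c in class_labels],
            "has_convergent_partner": convergent,
            "true_distance_bp": distance,
            "methylation_fraction": np.nan,  # filled by generate_methylation
        }
    )
    return sort_genes(genes), truth


def _make_exons(start: int, end: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """1-3 exons separated by short introns, covering the gene ends."""
    length = end - start
    n_exons = int(rng.integers(1, 4)) if length >= 900 else 1
    if n_exons == 1:
        return ((start, end),)
    cuts = np.sort(rng.integers(200, length - 200, size=2 * (n_exons - 1)))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    exons = []
    for k in range(n_exons):
        s, e = bounds[2 * k], bounds[2 * k + 1]
        if e - s < 50:
            e = s + 50
        exons.append((s, min(e, end)))
    exons[-1] = (exons[-1][0], end)
    return tuple(exons)


def generate_counts(
    genes: Sequence[GeneModel], truth: pd.DataFrame, cfg: SyntheticConfig
) -> tuple[CountTensor, list[SampleInfo]]:
    """Draw the count tensor: NB totals split multinomially over strand/length."""
    rng = _spawn(cfg.seed)[2]
    profiles = cfg.length_profiles()
    order = {g.gene_id: g for g in genes}
    truth = truth.set_index("gene_id")

    samples = []
    for geno, tag in ((cfg.control_genotype, "ctl"), (cfg.mutant_genotype, "mut")):
        for r in range(1, cfg.replicates_per_genotype + 1):
            samples.append(SampleInfo(f"{tag}_{r}", geno, r))
    sample_ids = [s.sample_id for s in samples]
    is_mut = np.array([s.genotype == cfg.mutant_genotype for s in samples])

    gene_ids = [g.gene_id for g in genes]
    tensor = CountTensor.zeros(gene_ids, sample_ids)
    n_len = len(LENGTHS)
    disp = cfg.nb_dispersion

    for gid in gene_ids:
        cls = truth.loc[gid, "class_label"]
        lfc = float(truth.loc[gid, "true_log2fc"])
        if cls == "methylation_hotspot":
            base = 2.0 ** rng.normal(cfg.hotspot_log2_mean, cfg.expression_log2_sd)
        elif cls == "rqc_readthrough":
            base = 2.0 ** rng.normal(cfg.rqc_log2_mean, cfg.expression_log2_sd)
        else:
            base = 2.0 ** rng.normal(cfg.expression_log2_mean, cfg.expression_log2_sd)
        if cls == "one_strand_degradation":
            sense_frac = 1.0
        elif cls == "unaffected":
            sense_frac = rng.uniform(0.5, 0.9)
        else:
            sense_frac = rng.uniform(0.35, 0.65)
        lp = profiles[cls]
        probs = np.concatenate([sense_frac * lp, (1.0 - sense_frac) * lp])
        for si, sid in enumerate(sample_ids):
            mean = base * (2.0**lfc if is_mut[si] else 1.0)
            if disp > 0:
                total = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mean))
            else:
                total = rng.poisson(mean)
            if total == 0:
                continue
            split = rng.multinomial(total, probs)
            block = split.reshape(2, n_len).astype(float)
            gi = tensor._gidx[gid]
            tensor.counts[gi, si, :, :] += block

    for i, s in enumerate(samples):
        samples[i] = SampleInfo(
            s.sample_id, s.genotype, s.replicate, int(tensor.sample_totals()[s.sample_id])
        )
    return tensor, samples


def place_reads(
    tensor: CountTensor, genes: Sequence[GeneModel], cfg: SyntheticConfig
) -> dict[str, list[ReadAlignment]]:
    """Materialise the tensor as uniformly placed exonic alignments per sample."""
    rng = _spawn(cfg.seed)[3]
    by_id = {g.gene_id: g for g in genes}
    out: dict[str, list[ReadAlignment]] = {s: [] for s in tensor.sample_ids}
    counter = 0
    g_nz, s_nz, o_nz, l_nz = np.nonzero(tensor.counts)
    for gi, si, oi, li in zip(g_nz, s_nz, o_nz, l_nz):
        gene = by_id[tensor.gene_ids[gi]]
        sid = tensor.sample_ids[si]
        length = LENGTHS[li]
        n = int(tensor.counts[gi, si, oi, li])
        sense = oi == 0
        strand = gene.strand if sense else ("-" if gene.strand == "+" else "+")
        # exons weighted by placeable width
        widths = np.array([max(e - s - length, 1) for s, e in gene.exons], dtype=float)
        widths /= widths.sum()
        exon_choice = rng.choice(len(gene.exons), size=n, p=widths)
        for k in range(n):
            s0, e0 = gene.exons[exon_choice[k]]
            hi = max(e0 - length, s0 + 1)
            start = int(rng.integers(s0, hi))
            counter += 1
            out[sid].append(
                ReadAlignment(f"r{counter:08d}", gene.chrom, start, start + length, strand, 1)
            )
    return out


def generate_methylation(
    truth: pd.DataFrame, genes: Sequence[GeneModel], cfg: SyntheticConfig
) -> pd.DataFrame:
    """Per-gene cytosine methylation: hotspots above 0.2, the rest near 0.05.

    Hotspot genes draw Beta(16, 24) (mean 0.4) truncated above 0.2 — above
    the filter threshold by construction; all other genes draw Beta(1.5, 28)
    (mean ~0.05). total_c scales with gene length at a 25% cytosine density.
    """
    rng = _spawn(cfg.seed)[4]
    lengths = {g.gene_id: g.length for g in genes}
    rows = []
    fracs = []
    for row in truth.itertuples(index=False):
        if row.class_label == "methylation_hotspot":
            f = float(rng.beta(16, 24))
            while f <= 0.21:
                f = float(rng.beta(16, 24))
        else:
            f = float(rng.beta(1.5, 28))
        total_c = max(int(lengths[row.gene_id] * 0.25), 1)
        meth_c = int(round(f * total_c))
        rows.append({"gene_id": row.gene_id, "methylated_c": meth_c, "total_c": total_c})
        fracs.append(meth_c / total_c)
    truth["methylation_fraction"] = fracs
    return pd.DataFrame(rows)


def generate_dataset(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """One-call generator for the default scenario (optionally reseeded)."""
    if cfg is None:
        cfg = SyntheticConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    genes, truth = generate_annotation(cfg)
    tensor, samples = generate_counts(genes, truth, cfg)
    methylation = generate_methylation(truth, genes, cfg)
    return SyntheticDataset(cfg, genes, truth, samples, tensor, methylation)


def audit_consistency(ds: SyntheticDataset) -> None:
    """Cross-file truth/annotation/methylation agreement; raises on violation."""
    gids = {g.gene_id for g in ds.genes}
    if set(ds.truth["gene_id"]) != gids:
        raise AssertionError("truth and annotation gene sets differ")
    if set(ds.methylation["gene_id"]) != gids:
        raise AssertionError("methylation and annotation gene sets differ")
    meth = ds.methylation.set_index("gene_id")
    for row in ds.truth.itertuples(index=False):
        rec = meth.loc[row.gene_id]
        frac = rec["methylated_c"] / rec["total_c"]
        if abs(frac - row.methylation_fraction) > 1e-12:
            raise AssertionError(f"{row.gene_id}: methylation fraction mismatch")
        if row.class_label == "methylation_hotspot" and frac <= 0.2:
            raise AssertionError(f"{row.gene_id}: hotspot gene with fraction <= 0.2")
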