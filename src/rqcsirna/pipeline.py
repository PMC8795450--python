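"""End-to-end orchestration: counting -> differential -> filters -> enrichment -> profiling.

A :class:`RunConfig` gathers the input paths and the analysis constants
(FDR 0.05, log2FC 1, 400 bp convergence threshold, 0.25-4 strand-ratio
window, 20% methylation threshold, permutation count, bin and bootstrap
settings, master seed). :func:`run_pipeline` executes the stages, writes one
TSV per stage plus a manifest JSON recording the resolved config, its hash,
the seed and per-stage row counts. Identical config and seed give identical
outputs. Every number in every output is produced by a library operation;
this module only wires them together.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import counting, differential, enrichment, filters, profiling

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

#: named length windows for the differential re-analysis
LENGTH_RANGES: dict[str, tuple[int, int] | None] = {
    "all": None,
    "21-22": (21, 22),
    "24": (24, 24),
}


@dataclass
class RunConfig:
    annotation: str
    sample_sheet: str
    methylation: str
    outdir: str
    counts: str | None = None  # tensor TSV; alternative to per-sample alignments
    annotation_format: str = "gff3"
    control_genotype: str = "wt"
    alpha: float = 0.05
    lfc_min: float = 1.0
    distance_threshold: int = 400
    max_scan_bp: int = 10_000
    ratio_bounds: tuple[float, float] = (0.25, 4.0)
    methylation_threshold: float = 0.20
    length_ranges: list[str] = field(default_factory=lambda: ["all", "21-22", "24"])
    n_perm: int = 100_000
    n_bins: int = 100
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.methylation_threshold <= 1:
            raise ValueError("methylation_threshold must be in [0, 1]")
        lo, hi = self.ratio_bounds
        if not 0 < lo <= hi:
            raise ValueError("ratio_bounds must satisfy 0 < lo <= hi")
        unknown = [r for r in self.length_ranges if r not in LENGTH_RANGES]
        if unknown:
            raise ValueError(f"unknown length ranges {unknown}; known: {list(LENGTH_RANGES)}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "ratio_bounds" in data:
            data["ratio_bounds"] = tuple(data["ratio_bounds"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ratio_bounds"] = list(self.ratio_bounds)
        return d


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns a summary dict (also written as manifest).

    Raises with a stage-named message on any stage failure.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    # --- annotation ---------------------------------------------------------
    stage = _stage("annotation")
    try:
        genes = ann.read_annotation(config.annotation, format=config.annotation_format)
        genes = ann.sort_genes(genes)
        gene_map = {g.gene_id: g for g in genes}
        partners = ann.convergence_table(
            genes, max_scan_bp=config.max_scan_bp, threshold=config.distance_threshold
        )
        manifest["stages"][stage] = {"n_genes": len(genes)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- counting -----------------------------------------------------------
    stage = _stage("counting")
    try:
        samples, aln_paths = counting.read_sample_sheet(config.sample_sheet)
        if config.counts:
            tensor = counting.CountTensor.from_tsv(
                config.counts,
                gene_ids=[g.gene_id for g in genes],
                sample_ids=[s.sample_id for s in samples],
            )
            stats = None
        else:
            if not aln_paths:
                raise ValueError("sample sheet has no alignment paths and no counts TSV given")
            base = os.path.dirname(os.path.abspath(config.sample_sheet))
            sources = {
                sid: p if os.path.isabs(p) else os.path.join(base, p)
                for sid, p in aln_paths.items()
            }
            tensor, stats = counting.build_count_tensor(sources, genes, samples)
            stats.to_csv(os.path.join(config.outdir, "assignment_stats.tsv"), sep="\t")
        lib_sizes = counting.effective_library_sizes(tensor, samples)
        tensor.to_tsv(os.path.join(config.outdir, "counts.tsv"))
        manifest["stages"][stage] = {
            "n_samples": len(samples),
            "total_counts": tensor.total(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    genotypes = np.array([s.genotype for s in samples])
    mutant_samples = [s.sample_id for s in samples if s.genotype != config.control_genotype]

    # --- differential (per length range) -----------------------------------
    stage = _stage("differential")
    results: dict[str, pd.DataFrame] = {}
    try:
        for name in config.length_ranges:
            matrix = tensor.collapse(LENGTH_RANGES[name], "both")
            res = differential.run_differential(
                matrix, genotypes, config.control_genotype,
                alpha=config.alpha, lfc_min=config.lfc_min, allow_zeros=True,
            )
            results[name] = res
            differential.write_results_tsv(
                res, os.path.join(config.outdir, f"differential_{name}.tsv")
            )
        manifest["stages"][stage] = {
            name: int(res["significant_up"].sum()) for name, res in results.items()
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    sig = differential.call_significant(
        results["all"], direction="up", alpha=config.alpha, lfc_min=config.lfc_min
    )

    # --- filters ------------------------------------------------------------
    stage = _stage("filters")
    try:
        methylation = filters.read_methylation_tsv(config.methylation)
        report, tallies = filters.apply_filter_cascade(
            sig, tensor, gene_map, methylation, mutant_samples,
            ratio_bounds=config.ratio_bounds,
            methylation_threshold=config.methylation_threshold,
        )
        filters.write_filter_report(report, os.path.join(config.outdir, "filter_report.tsv"))
        filters.write_tallies(tallies, os.path.join(config.outdir, "filter_tallies.tsv"))
        candidates = filters.rqc_candidates(report)
        manifest["stages"][stage] = {"n_significant": len(sig), **tallies}
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- enrichment ---------------------------------------------------------
    stage = _stage("enrichment")
    try:
        coding_universe = [g.gene_id for g in genes if g.biotype == "protein_coding"]
        coding_sig = sig & set(coding_universe)
        enr = enrichment.permutation_enrichment(
            coding_sig, coding_universe, partners,
            n_perm=config.n_perm, seed=config.seed, threshold=config.distance_threshold,
        )
        enr.to_tsv(
            os.path.join(config.outdir, "enrichment.tsv"),
            sidecar_json=os.path.join(config.outdir, "enrichment_meta.json"),
        )
        manifest["stages"][stage] = {
            "n_affected": enr.sample_size,
            "universe": enr.universe_size,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- profiling ----------------------------------------------------------
    stage = _stage("profiling")
    try:
        hist = profiling.length_histogram(tensor, sig or set(tensor.gene_ids), samples, fraction=True)
        hist.to_csv(os.path.join(config.outdir, "length_histogram.tsv"), sep="\t")
        frac = profiling.library_fraction(tensor, sig, lib_sizes.to_dict())
        frac.rename("library_fraction").to_csv(
            os.path.join(config.outdir, "library_fraction.tsv"), sep="\t"
        )
        manifest["stages"][stage] = {"n_genes_profiled": len(sig)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    manifest["candidates"] = sorted(candidates)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(os.path.join(config.outdir, "config.resolved.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    return manifest
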