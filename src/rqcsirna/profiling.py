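"""Where and what the siRNAs are: metagene profiles, length histograms,
library fractions.

The metagene profile rescales every gene body to a common relative
coordinate of ``n_bins`` bins (default 100), orienting minus-strand genes so
bin 1 is the 5' end, then averages within-bin mean RPTM coverage over genes.
The 0.95 confidence band is a nonparametric bootstrap over genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .counting import LENGTHS, CountTensor, SampleInfo

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 100
DEFAULT_BOOTSTRAP_REPS = 1000


@dataclass
class MetageneProfile:
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_genes: int
    bootstrap_reps: int
    seed: int

    @property
    def n_bins(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "mean_rptm": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rescale(cov: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean coverage within n_bins equal relative-coordinate bins."""
    L = cov.size
    edges = np.floor(np.arange(n_bins + 1) * L / n_bins).astype(int)
    sums = np.add.reduceat(cov, edges[:-1])
    widths = np.diff(edges)
    return sums / widths


def metagene_profile(
    genes: Sequence[GeneModel],
    coverage: Mapping[str, np.ndarray],
    n_bins: int = DEFAULT_N_BINS,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    ci: float = 0.95,
) -> MetageneProfile:
    """Length-adjusted mean coverage profile with bootstrap confidence band.

    ``coverage`` maps gene_id to a per-base RPTM array over the gene body in
    genomic (left-to-right) order; strand orientation is applied here. Genes
    shorter than ``n_bins`` bp are dropped with a logged count; an empty
    usable set is an error. With a single gene the CI collapses to the mean.
    """
    usable = []
    for g in genes:
        if g.length < n_bins:
            continue
        usable.append(g)
    dropped = len(genes) - len(usable)
    if dropped:
        logger.info("metagene: dropped %d genes shorter than %d bp", dropped, n_bins)
    if not usable:
        raise ValueError("no gene is long enough to profile")

    profiles = np.empty((len(usable), n_bins))
    for i, g in enumerate(usable):
        cov = np.asarray(coverage[g.gene_id], dtype=float)
        if cov.size != g.length:
            raise ValueError(f"{g.gene_id}: coverage length {cov.size} != gene length {g.length}")
        binned = _rescale(cov, n_bins)
        profiles[i] = binned[::-1] if g.strand == "-" else binned

    mean = profiles.mean(axis=0)
    if len(usable) == 1 or bootstrap_reps < 1:
        return MetageneProfile(mean, mean.copy(), mean.copy(), len(usable), 0, seed)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(usable), size=(bootstrap_reps, len(usable)))
    boot = profiles[idx].mean(axis=1)  # reps x bins
    tail = (1.0 - ci) / 2.0
    ci_low = np.quantile(boot, tail, axis=0)
    ci_high = np.quantile(boot, 1.0 - tail, axis=0)
    # the band brackets the point estimate by construction of the percentile CI
    ci_low = np.minimum(ci_low, mean)
    ci_high = np.maximum(ci_high, mean)
    return MetageneProfile(mean, ci_low, ci_high, len(usable), bootstrap_reps, seed)


def length_histogram(
    tensor: CountTensor,
    gene_ids: Sequence[str] | set[str],
    samples: Sequence[SampleInfo] | None = None,
    fraction: bool = False,
) -> pd.DataFrame:
    """Read counts per length (15..35 nt) over a gene set.

    With ``samples`` the columns are genotypes (replicates summed), otherwise
    a single pooled ``all`` column. ``fraction`` normalizes each column to
    sum to 1 (zero totals stay zero).
    """
    if not gene_ids:
        raise ValueError("gene set must be non-empty")
    gsel = [tensor._gidx[g] for g in sorted(gene_ids)]
    sub = tensor.counts[gsel].sum(axis=2)  # gene x sample x length
    if samples is None:
        cols = {"all": sub.sum(axis=(0, 1))}
    else:
        cols = {}
        for s in samples:
            cols.setdefault(s.genotype, np.zeros(len(LENGTHS)))
            cols[s.genotype] += sub[:, tensor._sidx[s.sample_id], :].sum(axis=0)
    df = pd.DataFrame(cols, index=pd.Index(LENGTHS, name="length"))
    if fraction:
        totals = df.sum(axis=0)
        df = df.div(totals.where(totals > 0, 1.0), axis=1)
    return df


def library_fraction(
    tensor: CountTensor,
    gene_ids: Sequence[str] | set[str],
    library_sizes: Mapping[str, float],
) -> pd.Series:
    """Per-sample fraction of the library assigned to the gene set."""
    if not gene_ids:
        return pd.Series(0.0, index=tensor.sample_ids)
    gsel = [tensor._gidx[g] for g in sorted(gene_ids)]
    counts = tensor.counts[gsel].sum(axis=(0, 2, 3))
    libs = np.array([library_sizes[s] for s in tensor.sample_ids], dtype=float)
    return pd.Series(counts / libs, index=tensor.sample_ids)
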