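# Methods

`rqcsirna` identifies protein-coding genes that become sources of
RNA-quality-control siRNAs (rqc-siRNAs) in RNA-metabolism mutants, from
small-RNA sequencing alignments. This note describes the models and
procedures, the parameters that matter, what the synthetic benchmark does and
does not emulate, and the numerical choices made where the design was open.

## The analysis model

The biological premise: when Pol II transcription termination or mRNA
3'-end processing fails, read-through transcripts can run into the downstream
*convergent* (tail-to-tail) gene, pair with its mRNA, and trigger
RNA-dependent-RNA-polymerase-driven siRNA production from the whole
transcript. Such rqc-siRNAs are distinguishable from two confounders: mRNA
degradation fragments (sense-strand-only, no RDR involvement) and
constitutive siRNA/DNA-methylation hotspots (RdDM loci that produce 24-nt
siRNAs and carry high methylation even in wild type).

The pipeline therefore runs five stages:

1. **Counting.** Reads are assigned to genes with union-mode semantics over
   exon-union intervals (the merged exons of all isoforms): a read
   overlapping the exon union of exactly one gene is assigned, of two or
   more genes is ambiguous, of none is no-feature; reads with more than one
   reported alignment are excluded by default (a flag counts each hit at
   1/n_hits instead, for bowtie-style multi-hit reporting). Counts are
   indexed by gene x sample x orientation (sense/antisense relative to the
   gene) x read length (15-35 nt). Coverage tracks and profiles are
   normalized to reads per ten million (RPTM); the denominator defaults to
   each sample's total assigned reads and can be overridden per sample in
   the sample sheet, since different groups normalize to different totals.
   Reads overlapping a gene only in intronic sequence are no-feature
   (exon-union semantics).

2. **Differential call.** Genes with elevated small RNAs in the mutant are
   called by a two-condition negative-binomial generalized linear model:
   median-of-ratios size factors (with a positive-counts pseudo-reference
   fallback for sparse matrices); per-gene method-of-moments dispersion on
   normalized counts, pooled within conditions after centering and floored
   at 1e-4; a log-link NB GLM fitted by vectorized Fisher scoring with the
   log size factors as offsets; and a Wald test on the condition
   coefficient. This is a deliberately transparent stand-in for DESeq2 —
   no dispersion shrinkage toward a fitted trend, no fold-change shrinkage,
   no independent filtering — and an ingestion path for externally computed
   (DESeq2-shaped) result tables preserves full fidelity for users who
   prefer to run DESeq2 themselves. The headline set is FDR < 0.05 and
   log2FC > 1 on the up-regulated side, with Benjamini-Hochberg FDR
   control; genes with all-zero counts are excluded from the BH m.

   *Small-sample calibration.* With 3+3 replicates and unshrunk
   method-of-moments dispersions, the nominal-normal Wald statistic is
   markedly anticonservative (empirical type-I fraction ~0.12 at the 0.05
   level in our null simulations). The Wald statistic is therefore referred
   to a t distribution with n_samples - 2 degrees of freedom, the standard
   small-sample correction, which brings the empirical type-I rate to
   0.04-0.05. The cost is tail power: length-restricted re-analyses (21-22
   nt, 24 nt), which work on roughly half the counts, are noticeably less
   powered at triplicate scale.

3. **Filter cascade.** Significant genes are assigned exactly one category,
   in precedence order: non-protein-coding (structural RNAs, lncRNAs,
   pseudogenes/transposons — set aside first); then the two flags —
   *one-strand* (sense/antisense mutant read ratio outside [0.25, 4]) and
   *methylation hotspot* (more than 20% of the gene's cytosines
   methylated) — combined as both-flags / one-strand-only / hotspot-only;
   survivors are rqc-siRNA candidates. The ratio window is closed (exactly
   0.25 and 4 pass); a zero antisense count leaves the ratio undefined and
   fails, since a one-strand gene is exactly what the filter removes. The
   methylation threshold is strict (exactly 20% is not a hotspot). The
   ratio is computed on raw counts summed over the mutant replicates; which
   samples and which read lengths enter is configurable because the
   aggregation is not canonical. Wild-type siRNA output (RPTM) can be
   attached as an informational column but never filters. Genes lacking a
   methylation record default to non-hotspot with a warning (configurable
   to an error).

4. **Convergence enrichment.** Every gene's convergent partner is the
   nearest opposite-strand gene downstream of its 3' end within a scan
   window (default 10 kb); the distance is the gap between annotated gene
   bodies, negative for tail-to-tail overlap, and the class boundary is
   400 bp (overlapping pairs fall in the "< 400 bp" class). Distances are
   defined on gene bodies, not transcripts, and nearest-partner ties break
   to the lexicographically smaller gene id for determinism. The affected
   genes' class counts are compared with drawing equally many genes without
   replacement from the protein-coding universe. Because only the class
   labels enter the statistic, the null class-count vector is multivariate
   hypergeometric and is sampled directly — distributionally identical to
   enumerating gene subsets and fast enough for one million repetitions.
   Empirical p-values use the add-one rule p = (1 + #{null >= obs})/(1 + B),
   reported per class as (p_greater, p_less); the seed is recorded in the
   output. An exhaustive subset-enumeration oracle (bounded at 1e6 subsets)
   and the closed-form hypergeometric tail verify the sampler in tests.

5. **Profiling.** The metagene profile rescales every gene body to a fixed
   number of relative-coordinate bins (default 100), orienting minus-strand
   genes so bin 1 is the 5' end, and averages within-bin mean RPTM over
   genes; the 0.95 confidence band is a nonparametric bootstrap over genes
   (default 1000 replicates, seeded), chosen for being assumption-light.
   Genes shorter than the bin count are dropped with a logged tally. Length
   histograms (15-35 nt, per genotype) and per-library fractions of reads
   from a gene set complete the picture. Profiles are gene-body only, no
   flanks; replicates are pooled by default.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| alpha | 0.05 | FDR threshold of the differential call |
| lfc_min | 1 | log2 fold-change threshold (up-regulated side) |
| ratio_bounds | [0.25, 4] | closed sense/antisense window for double-strand siRNAs |
| methylation_threshold | 0.20 | strict hotspot cutoff (fraction of all cytosines) |
| distance_threshold | 400 bp | convergent-partner class boundary |
| max_scan_bp | 10,000 | partner search window downstream of the 3' end |
| n_perm | 1e5 (up to 1e6) | permutation repetitions for the null |
| n_bins | 100 | metagene bins over the length-adjusted gene body |
| bootstrap_reps | 1000 | bootstrap replicates for the 0.95 band |
| length ranges | all / 21-22 / 24 | windows for the differential re-analysis |

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on ingest and write, exactly. "Length-adjusted 10-bp bins" is
internally contradictory (length-adjusted coordinates are unitless), so it is
implemented as a fixed number of relative-coordinate bins, configurable.

## The synthetic benchmark

The generator plants four gene classes on one chromosome arm — 2,000 genes,
triplicate libraries per genotype, NB dispersion 0.05:

* `rqc_readthrough` (5%): with probability 0.9 a member of a convergent pair
  at a 3'-3' gap drawn uniformly from [-100, 350] bp; control-side
  expression lognormal around 2^4 reads (read-through siRNA production
  concerns reasonably expressed gene pairs); mutant elevation log2FC 3 on
  both strands with a 21/22/24-nt length profile.
* `one_strand_degradation` (5%): sense-strand-only reads (antisense exactly
  zero by construction), broad length profile, mutant elevation log2FC 3 so
  these genes enter the significant set and the strand filter has real work.
* `methylation_hotspot` (5%): 24-nt-dominated, both strands, high baseline
  (2^7) in both genotypes with a moderate extra mutant elevation (log2FC 2),
  and methylated-cytosine fractions drawn above 0.2 by construction
  (Beta(16,24) truncated); non-hotspot genes draw Beta(1.5, 28), mean ~0.05.
* `unaffected` (85%): equal means in both genotypes; carries the
  non-protein-coding biotype mix (12%).

Background convergent pairs top the convergent fraction up to 25%, with gaps
uniform on [50, 3000] bp; units are separated by more than the scan window so
only constructed pairs are convergent. Counts are generated first (fast
path); an optional placement step materialises uniformly positioned exonic
alignments per sample for testing the counting path. All randomness flows
from one master seed through fixed-role child streams (layout, classes,
counts, reads, methylation), so adding one output never perturbs another.

What the benchmark does *not* emulate: real genome gene-density and
distance distributions (defaults are not calibrated to any genome and are
documented as arbitrary), sequence content (no nucleotides, no FASTQ),
chimeric/ambiguous loci, expression-dependent biases in library preparation,
context-resolved (CpG/CHG/CHH) methylation, or non-coding genes that respond
to the mutation. Passing the benchmark therefore demonstrates correctness of
the statistical machinery and the filter logic under the assumed generative
structure, not performance on any particular genome.

Desk-scale consequences worth knowing: the synthetic libraries contain only
assigned reads, so "library fraction" values are far larger than in real
libraries where most reads come from canonical sRNA loci; and all affected
classes are planted as protein-coding, so the biotype stage of the cascade
only does visible work when non-coding genes are injected into the
significant set by hand (the unit tests do this).

## Numerical choices and degenerate inputs

* Fisher-scoring updates are damped (step clamp 5) and coefficients bounded
  (|b1| <= 30) so separated designs (a group with all zeros) stay finite;
  all-zero genes get NaN p-values and FDR.
* Dispersion floor 1e-4; zero-variance and zero-mean genes fall to the
  floor.
* BH is step-up with enforced monotonicity; NaN entries are excluded from m
  and stay NaN.
* Empty length or orientation selections, empty gene sets for profiling,
  unsorted gene lists for partner search, and affected sets outside the
  universe are errors, not silent results.
* Bootstrap confidence bands are percentile-based and clamped to bracket
  the point estimate; with a single gene the band collapses to the mean.
* Nearest-partner ties and all tabular outputs are deterministically
  ordered; identical config and seed give byte-identical stage outputs.

## Known limitations

* The NB test is not DESeq2: no shrinkage of dispersions or fold changes,
  no outlier handling (Cook's distance), no independent filtering. Expect
  conservative behaviour at low counts; use the external-results path for
  publication-grade calls.
* The strand-ratio aggregation (raw counts, mutant replicates summed) is an
  assumption; the canonical aggregation is not established.
* The permutation null is unmatched (no GC/length/expression matching).
* Problem sizes in the test-suite simulations (2,000 genes, 1e5
  permutations, hundreds of bootstrap trials) are the package's default
  desk-scale settings; every knob scales up by configuration.
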