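# rqcsirna

Identify protein-coding source genes of RNA-quality-control siRNAs
(rqc-siRNAs) from small-RNA sequencing of RNA-metabolism mutants.

When Pol II transcription termination or mRNA 3'-end processing fails,
read-through transcripts can invade the downstream tail-to-tail (convergent)
gene, form double-stranded RNA with its mRNA, and trigger siRNA production
from protein-coding genes that normally make none. Distinguishing these
genuine rqc-siRNA sources from look-alikes — sense-strand mRNA degradation
fragments and constitutive siRNA/DNA-methylation hotspots — is the job of
this package. It is a library first (with a thin `rqcsirna` CLI), aimed at
plant small-RNA and RNA-decay researchers.

## What it computes

Given a gene annotation (GFF3/BED12), per-sample small-RNA alignments (BAM
or a simple TSV dialect) or a pre-made count tensor, a per-gene methylation
table and a sample sheet:

1. **Counting** — union-mode assignment over exon-union intervals into a
   gene x sample x orientation x length (15-35 nt) count tensor;
   reads-per-ten-million (RPTM) normalization and bedGraph tracks.
2. **Differential call** — a negative-binomial GLM Wald test (median-of-
   ratios size factors `s_j`, method-of-moments dispersions `alpha_i`,
   model `K_ij ~ NB(mu_ij, alpha_i)`, `log mu_ij = log s_j + beta_0i +
   beta_1i x_j`) with Benjamini-Hochberg FDR; the affected set is
   FDR < 0.05 and log2FC > 1. DESeq2-shaped result tables can be ingested
   instead.
3. **Filter cascade** — biotype partition; sense/antisense strand ratio
   within [0.25, 4] (double-strand-derived siRNAs); methylated-cytosine
   fraction > 20% flags constitutive hotspots. Survivors are the
   rqc-siRNA candidates, with Fig.-style category tallies.
4. **Convergence enrichment** — nearest tail-to-tail partner distances
   (< 400 bp / >= 400 bp / none) of affected genes versus a permutation
   null (sampling without replacement from the protein-coding universe;
   add-one empirical p-values), with exhaustive-enumeration and
   hypergeometric oracles.
5. **Profiling** — length-adjusted metagene coverage profiles with
   bootstrap 0.95 bands, read-length histograms, per-library fractions.
6. **Synthetic data** — a seeded generator planting read-through,
   degradation, hotspot and unaffected gene classes with known truth, so
   the whole pipeline is testable end to end without downloads.

## Worked example

```python
import numpy as np
from rqcsirna import (SyntheticConfig, generate_dataset, run_differential,
                      call_significant, convergence_table, permutation_enrichment)

ds = generate_dataset(seed=1)                      # 2,000 genes, 3+3 libraries
cond = np.array([s.genotype for s in ds.samples])
res = run_differential(ds.tensor.collapse(None, "both"), cond, "wt", allow_zeros=True)
sig = call_significant(res)                        # FDR < 0.05, log2FC > 1

partners = convergence_table(ds.genes)
universe = [g.gene_id for g in ds.genes if g.biotype == "protein_coding"]
enr = permutation_enrichment(sig & set(universe), universe, partners,
                             n_perm=100_000, seed=1)
print(len(sig))
print(enr.table.round(4))
```

prints

```
222
                         observed  null_mean  null_sd  p_greater  p_less
distance_class
convergent_lt_threshold        81    22.6906   4.2274      0.000  1.0000
convergent_ge_threshold        21    33.0400   4.9653      0.996  0.0075
no_partner                    120   166.2694   6.0373      1.000  0.0000
```

222 genes gain siRNAs in the mutant; 81 of them have a convergent partner
closer than 400 bp where random protein-coding sampling expects ~22.7 — a
3.6-fold excess with empirical p = 1e-5 (the add-one lower bound at 1e5
permutations). That excess is the read-through signature. The
`examples/` directory walks through each capability the same way
(simulation, counting, differential call, filter cascade, enrichment,
profiles), and the `rqcsirna` CLI exposes the stages as subcommands
(`simulate`, `count`, `diff`, `filter`, `enrich`, `profile`, `run-all`).

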