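"""Call genes with significantly elevated small RNAs in the mutant.

The negative-binomial Wald test (median-of-ratios size factors,
method-of-moments dispersions, t-calibrated Wald statistic) is thresholded
at FDR < 0.05 and log2FC > 1 — the definition of the affected gene set.
The same call restricted to 21-22-nt reads isolates post-transcriptional
siRNA classes; 24-nt-only signal (RdDM hotspots) drops out.
"""

import numpy as np

from rqcsirna import call_significant, generate_dataset, run_differential

ds = generate_dataset(seed=1)
cond = np.array([s.genotype for s in ds.samples])

res_all = run_differential(ds.tensor.collapse(None, "both"), cond, "wt", allow_zeros=True)
res_2122 = run_differential(ds.tensor.collapse((21, 22), "both"), cond, "wt", allow_zeros=True)

sig_all = call_significant(res_all)
sig_2122 = call_significant(res_2122)
truth = ds.truth.set_index("gene_id")
hot = set(truth[truth["class_label"] == "methylation_hotspot"].index)

print(f"significant (all lengths): {len(sig_all)}")
print(f"significant (21-22 nt):    {len(sig_2122)}")
print(f"hotspot-class genes among them: {len(sig_all & hot)} -> {len(sig_2122 & hot)}")
print(res_all[res_all.significant_up].head().to_string(index=False))
# The hotspot genes' disappearance under the 21-22-nt restriction mirrors the
# nuclear 24-nt character of constitutive siRNA hotspots. Restricting the
# counts also cuts depth, so at triplicate desk scale the restricted call is
# markedly less powered than the all-length call.
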