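"""Single-gene-removal (SGR) backward elimination of a 10-gene signature.

At each step every one-gene removal is scored by the log-rank p of the
remaining signature's altered-vs-unaltered split; the removal with the
lowest p wins. The printed trace shows which genes go first (typically the
noise genes) and the p-value trajectory.
"""

import sigforge as sf

expr, clin, truth = sf.simulate_cohort(sf.CohortConfig(seed=3))
alt = sf.call_alterations(sf.zscore_vs_reference(expr))
start = sf.GeneSignature("all", list(alt.gene_ids))

trace = sf.sgr_refine(alt, clin, start, target_size=3)
print(f"start: {len(start)} genes, log-rank p = {trace.start_p:.2e}")
for step in trace.steps:
    print(f"  removed {step.removed_gene}: remaining {len(step.remaining)} genes, "
          f"p = {step.logrank_p:.2e}")
print(f"final signature: {trace.final_signature.genes}")
print(f"planted genes:   {truth.prognostic_genes}")
# Note the selected p is a minimum over all candidate removals at every
# step, so the trajectory is optimistically biased — the final set can
# swap a weak planted gene for a lucky noise gene.
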