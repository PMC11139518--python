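"""NB Wald differential expression and specific/signature gene calling.

Runs the full supervised analysis on a simulated 3-condition time course
with one planted condition-specific gene: temporal contrasts (ti vs t0 per
condition), pairwise condition contrasts at each time, and the combinatorial
calls built on top of them.
"""

import warnings

import temporade as tp

# gene g0000 is shifted only in condition A from t2 onward -> it is
# specific to A at t2 and, being DE vs t0 there, a signature gene of A.
effects = (tp.Effect(0, "A", "t2", 2.0),)
spec = tp.SimulationSpec(conditions=("A", "B", "C"), times=("t0", "t1", "t2"),
                         replicates=4, n_genes=400, effects=effects, seed=3)
counts, design, truth = tp.simulate(spec)

analysis = tp.run_de(counts, design, alpha=0.05)
print(f"tested {len(analysis.contrasts)} contrasts "
      f"({tp.count_analysis_units(design, 'temporal')} temporal + "
      f"{len(tp.enumerate_condition_contrasts(design))} pairwise)")

row = analysis.results["A:t2_vs_t0"].set_index("gene_id").loc["g0000"]
print(f"g0000 in A:t2_vs_t0: log2FC={row['log2_fold_change']:.2f} "
      f"(planted 2.0), padj={row['padj']:.2e}")

dm = tp.build_decision_matrix(analysis.results, analysis.contrasts, design,
                              alpha=0.05)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    specific_t2 = tp.call_specific(dm, "A", "t2")
    signature = tp.call_signature(dm, "A").query("signature")

print(f"specific to A at t2: {specific_t2}")
print(f"signature genes of A: {list(signature['gene_id'])} "
      f"at times {list(signature['times'])}")
fdt = tp.first_de_time(dm, "A")
print(f"first DE time of g0000 in A: {fdt['g0000']} "
      f"(activation cluster); genes never DE: {(fdt == 'never').sum()}")
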