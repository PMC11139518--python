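"""Simulate a reference-shape dataset and inspect its design.

Builds the 4-condition x 6-time-point x 4-replicate study layout with
planted temporal-DE and condition-specific genes, then shows how the two
contrast families are enumerated from the design.
"""

import temporade as tp

spec = tp.preset_reference_shape(seed=1, n_genes=500)
counts, design, truth = tp.simulate(spec)

print(f"samples: {len(design.samples)}  "
      f"(C={design.n_conditions} conditions x T={design.n_times} times "
      f"x 4 replicates), reference time {design.t0}")
print(f"temporal DE analyses (ti vs t0 per condition): "
      f"{tp.count_analysis_units(design, 'temporal')}")
print(f"condition analysis units (one per (condition, time)): "
      f"{tp.count_analysis_units(design, 'condition')}")
print(f"underlying pairwise condition contrasts: "
      f"{len(tp.enumerate_condition_contrasts(design))}")
print(f"planted: {int(truth.is_temporal_de.any(axis=1).sum())} temporal-DE "
      f"genes, {int(truth.is_specific.any(axis=1).sum())} condition-specific "
      f"genes (all of which are signature genes of their condition)")

# The first few contrast labels of each family, in canonical order:
print("temporal:", [c.label for c in tp.enumerate_temporal_contrasts(design)[:3]], "...")
print("condition:", [c.label for c in tp.enumerate_condition_contrasts(design)[:3]], "...")
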