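"""Size-factor normalization and unsupervised sample structure.

Median-of-ratios size factors correct library-size differences; PCA and
Ward clustering on the leading principal components (HCPC) then summarize
how samples group.  Here a strong shared response is planted at t2, so the
t2 samples should separate from the t0/t1 samples along the first
component.
"""

import numpy as np

import temporade as tp

# 80 genes respond strongly at t2 in both conditions
effects = tuple(tp.Effect(g, c, "t2", 3.0)
                for g in range(80) for c in ("A", "B"))
spec = tp.SimulationSpec(conditions=("A", "B"), times=("t0", "t1", "t2"),
                         replicates=3, n_genes=300, effects=effects, seed=4)
counts, design, _ = tp.simulate(spec)

sf = tp.size_factors(counts)
print("size factors (true library scalings were log-uniform in [0.5, 2]):")
print("  ", np.round(sf, 3))

logm = tp.log_transform(tp.normalize(counts, sf))
pca = tp.run_pca(logm, K=5)
print("explained variance fractions:", np.round(pca.explained_variance_fraction, 3))

hcpc = tp.run_hcpc(pca, k="auto", n_components=3)
print(f"HCPC chose k={hcpc.k} sample clusters:")
for cluster in range(1, hcpc.k + 1):
    members = [s.sample_id for s, l in zip(design.samples, hcpc.labels)
               if l == cluster]
    print(f"  cluster {cluster}: {members}")

corr = tp.correlation_matrix(logm)
t2 = [i for i, s in enumerate(design.samples) if s.time == "t2"]
rest = [i for i in range(len(design.samples)) if i not in t2]
print(f"mean correlation within t2 samples: {corr[np.ix_(t2, t2)].mean():.3f}; "
      f"t2 vs others: {corr[np.ix_(t2, rest)].mean():.3f}")
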