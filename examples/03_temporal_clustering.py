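"""Fuzzy c-means clustering of standardized temporal profiles.

For one condition, each gene's profile is its per-time mean log expression
standardized to mean 0 / sd 1, so clusters capture the *shape* of the
temporal response.  Three shapes are planted (early sustained induction,
late induction, repression); the elbow heuristic should recover k = 3 and
the centroids should mirror those shapes.
"""

import numpy as np

import temporade as tp

effects = []
for g in range(0, 50):        # early sustained induction
    effects += [tp.Effect(g, "A", t, 3.0) for t in ("t1", "t2", "t3")]
for g in range(50, 100):      # late induction
    effects += [tp.Effect(g, "A", "t3", 3.0)]
for g in range(100, 150):     # repression from t1 onward
    effects += [tp.Effect(g, "A", t, -3.0) for t in ("t1", "t2", "t3")]
spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1", "t2", "t3"),
                         replicates=4, n_genes=150, effects=tuple(effects),
                         seed=2)
counts, design, _ = tp.simulate(spec)

logm = tp.log_transform(tp.normalize(counts, tp.size_factors(counts)))
profiles = tp.temporal_profiles(logm, counts.gene_ids, design, "A")
print(f"{profiles.n_profiles} standardized profiles over times {profiles.times}")

m = tp.estimate_fuzzifier(profiles)
print(f"estimated fuzzifier m = {m:.3f} (default used below: m = 2)")

k = tp.select_k(profiles, (2, 6), m=2.0, seed=0)
print(f"selected k = {k} clusters (elbow of min centroid distance)")

result = tp.fuzzy_cmeans(profiles, k=k, m=2.0, seed=0)
print(f"converged={result.converged} after {result.n_iter} iterations; "
      f"membership rows sum to 1 (max dev "
      f"{abs(result.memberships.sum(axis=1) - 1).max():.1e})")
for c in range(result.k):
    n_hard = int((result.hard_labels() == c).sum())
    print(f"  cluster {c + 1}: {n_hard} genes, centroid "
          f"{np.round(result.centroids[c], 2)}")
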