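"""Local over-representation analysis and GSEA-family exports.

ORA is an exact hypergeometric test of a query list against GMT gene sets
(no network calls).  The writers emit the standard RNK/GCT/CLS dialects so
results can be handed to GSEA, Webgestalt, DAVID or g:Profiler.
"""

import tempfile
from pathlib import Path

import temporade as tp
from temporade.enrichment import GeneSetCollection, write_cls, write_gct

spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1"), replicates=3,
                         n_genes=100,
                         effects=tuple(tp.Effect(g, "A", "t1", 2.0)
                                       for g in range(10)),
                         seed=8)
counts, design, _ = tp.simulate(spec)
analysis = tp.run_de(counts, design)
df = analysis.results["A:t1_vs_t0"]

universe = list(counts.gene_ids)
query = sorted(df.loc[df["padj"] < 0.05, "gene_id"])
print(f"query: {len(query)} DE genes of {len(universe)}")

# a synthetic annotation: one set enriched in the planted genes, one random
collection = GeneSetCollection(
    {"planted_pathway": {f"g{i:04d}" for i in range(12)},
     "random_pathway": {f"g{i:04d}" for i in range(50, 70)}},
    {"planted_pathway": "", "random_pathway": ""})
ora = tp.ora_hypergeometric(query, universe, collection)
for _, r in ora.iterrows():
    print(f"  {r['set_name']}: overlap {r['overlap']}/{r['set_size']}, "
          f"p={r['p_value']:.2e}, padj={r['adjusted_p']:.2e}")

outdir = Path(tempfile.mkdtemp())
tp.write_rnk(df, outdir / "A_t1_vs_t0.rnk")
import pandas as pd
normed = pd.DataFrame(tp.normalize(counts, tp.size_factors(counts)),
                      index=list(counts.gene_ids),
                      columns=list(counts.sample_ids))
write_gct(normed, outdir / "expression.gct")
write_cls(design, outdir / "phenotypes.cls")
tp.write_gene_lists({"de_A_t1": query}, universe, outdir / "lists")
print("wrote:", sorted(p.name for p in outdir.rglob("*") if p.is_file()))
print("GCT header:", (outdir / "expression.gct").read_text().splitlines()[:2])
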