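"""Local over-representation analysis and enrichment-tool exports.

ORA is an exact hypergeometric upper-tail test of a query gene list against
user-supplied gene sets (GMT), BH-adjusted across sets — no network calls.
Writers produce the pinned dialects consumed by GSEA-family tools: RNK
(ranked gene list), GCT (expression matrix), CLS (sample classes), and
plain one-gene-per-line lists for DAVID / Webgestalt / g:Profiler.  All
writers are deterministic: no timestamps ever enter a data file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .design import ExperimentalDesign

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora_hypergeometric",
    "write_rnk",
    "read_rnk",
    "write_gct",
    "read_gct",
    "write_cls",
    "write_gene_lists",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, genes")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = set(genes)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + sorted(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora_hypergeometric(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    p = P(X >= overlap) with population |universe|, successes
    |set ∩ universe|, draws |query|; BH adjustment across tested sets.
    Sets with empty intersection with the universe are skipped.
    """
    query = set(query)
    universe = set(universe)
    outside = sorted(query - universe)
    if outside:
        raise ValueError(f"query genes outside the universe: {outside}")
    M, n = len(universe), len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = sorted(in_universe & query)
        k, K = len(overlap), len(in_universe)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({
            "set_name": name,
            "overlap": k,
            "set_size": K,
            "query_size": n,
            "universe_size": M,
            "p_value": min(p, 1.0),
            "genes": ";".join(overlap),
        })
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "query_size", "universe_size", "p_value",
                                     "genes"])
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
    return df


# -- GSEA-family writers ---------------------------------------------------

def write_rnk(
    results: pd.DataFrame,
    path: str | Path,
    statistic: str = "stat",
) -> None:
    """Two-column tab-separated ranked list, sorted descending, no header.

    ``results`` needs columns ``gene_id`` and the ranking statistic
    (default: the signed Wald statistic).  Genes with a non-finite
    statistic (untestable) are omitted.
    """
    ids = results["gene_id"].astype(str)
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in ranking: {dup}")
    stat = pd.to_numeric(results[statistic], errors="coerce")
    keep = np.isfinite(stat)
    if not keep.any():
        raise ValueError("nothing to rank: no finite ranking statistic")
    df = pd.DataFrame({"gene_id": ids[keep], "stat": stat[keep]})
    df = df.sort_values("stat", ascending=False, kind="mergesort")
    with open(path, "w") as fh:
        for g, s in zip(df["gene_id"], df["stat"]):
            fh.write(f"{g}\t{s:.10g}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "stat"])
    return df


def write_gct(matrix: pd.DataFrame, path: str | Path) -> None:
    """GCT v1.2: '#1.2', '<genes>\\t<samples>', then NAME/DESCRIPTION header."""
    G, S = matrix.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{G}\t{S}\n")
        fh.write("NAME\tDESCRIPTION\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for gene, row in matrix.iterrows():
            vals = "\t".join(f"{v:.10g}" for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{vals}\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "#1.2":
        raise ValueError("not a GCT 1.2 file")
    G, S = (int(x) for x in lines[1].split("\t"))
    header = lines[2].split("\t")
    samples = header[2:]
    if len(samples) != S:
        raise ValueError("GCT header sample count mismatch")
    data, index = [], []
    for line in lines[3:3 + G]:
        fields = line.split("\t")
        index.append(fields[0])
        data.append([float(v) for v in fields[2:]])
    return pd.DataFrame(data, index=index, columns=samples)


def write_cls(design: ExperimentalDesign, path: str | Path) -> None:
    """Categorical CLS: classes are the (condition, time) cells in design
    order."""
    cells = [cell for cell in design.cells() if design.sample_indices(*cell)]
    names = [f"{c}_{t}" for c, t in cells]
    index = {cell: i for i, cell in enumerate(cells)}
    labels = [index[s.cell] for s in design.samples]
    with open(path, "w") as fh:
        fh.write(f"{len(design.samples)} {len(cells)} 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(i) for i in labels) + "\n")


def write_gene_lists(
    calls: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    outdir: str | Path,
) -> list[Path]:
    """One plain gene-id-per-line file per named list, plus the universe.

    ``calls`` maps a file stem such as ``"specific_A_t3"`` or
    ``"signature_A_union"`` to its gene ids.  Empty lists still produce an
    (empty) file so absence is explicit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, genes in calls.items():
        p = outdir / f"{stem}.txt"
        genes = list(genes)
        p.write_text("".join(f"{g}\n" for g in genes))
        written.append(p)
    up = outdir / "universe.txt"
    up.write_text("".join(f"{g}\n" for g in universe))
    written.append(up)
    return written
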