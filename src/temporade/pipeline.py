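"""End-to-end pipeline: normalize -> explore -> cluster -> de -> combine ->
export, with a reproducibility manifest and the master results CSV.

The master CSV gathers, per gene: (log2FC, adjusted p, DE flag) for every
temporal and every pairwise condition contrast, then per condition the
first DE time, the times at which the gene is condition-specific, and the
signature flag.  Outputs carry no timestamps, so a rerun with the same
inputs, configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, combination, de, exploratory, normalization
from .design import (CountMatrix, ExperimentalDesign, count_analysis_units,
                     enumerate_condition_contrasts, enumerate_temporal_contrasts)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "master_table"]

_ALL_STAGES = ("normalize", "explore", "cluster", "de", "combine", "export")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    outdir: str | Path = "temporade_out"
    alpha: float = 0.05
    min_lfc: float = 0.0
    pseudocount: float = 1.0
    cluster_k: int = 4
    cluster_m: float = 2.0
    pca_components: int = 3
    hcpc_k: int | str = "auto"
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_lfc < 0:
            raise ValueError("min_lfc must be >= 0")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def master_table(dm: combination.DecisionMatrix,
                 analysis: de.DEAnalysis) -> pd.DataFrame:
    """Gene x everything: per-contrast (lfc, padj, de) then per-condition
    (first_de_time, specific_times, signature)."""
    genes = dm.gene_ids
    cols: dict[str, object] = {"gene_id": genes}
    for spec in dm.contrasts:
        df = analysis.results[spec.label].set_index("gene_id").reindex(genes)
        cols[f"{spec.label}_lfc"] = df["log2_fold_change"].to_numpy()
        cols[f"{spec.label}_padj"] = df["padj"].to_numpy()
        cols[f"{spec.label}_de"] = dm.calls[spec.label].to_numpy().astype(int)
    multi_condition = len(dm.conditions) >= 2
    for c in dm.conditions:
        cols[f"{c}_first_de_time"] = combination.first_de_time(dm, c).to_numpy()
        if multi_condition:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_time = {t: set(combination.call_specific(dm, c, t))
                            for t in dm.times}
                sig = combination.call_signature(dm, c).set_index("gene_id")
            cols[f"{c}_specific_times"] = [
                ";".join(t for t in dm.times if g in per_time[t]) for g in genes
            ]
            cols[f"{c}_signature"] = sig["signature"].reindex(genes).to_numpy().astype(int)
        else:
            cols[f"{c}_specific_times"] = [""] * len(genes)
            cols[f"{c}_signature"] = np.zeros(len(genes), dtype=int)
    return pd.DataFrame(cols)


def run_pipeline(
    counts: CountMatrix,
    design: ExperimentalDesign,
    config: RunConfig,
) -> dict:
    """Run the enabled stages in order, writing outputs and a manifest.

    Returns the manifest (also written as ``manifest.json``).  A stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    completed stages are retained next to a ``FAILED`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "design": {
            "conditions": list(design.conditions),
            "times": list(design.times),
            "n_samples": len(design.samples),
            "temporal_analysis_units": count_analysis_units(design, "temporal"),
            "condition_analysis_units": count_analysis_units(design, "condition"),
            "pairwise_condition_contrasts": (
                len(enumerate_condition_contrasts(design))
                if design.n_conditions >= 2 else 0
            ),
        },
        "stages": [],
    }
    state: dict = {}

    def record(stage: str, outputs: list[Path], **params) -> None:
        manifest["stages"].append({
            "stage": stage,
            "outputs": [str(p.relative_to(outdir)) for p in outputs],
            "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
            "parameters": params,
        })

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(name, str(exc)) from exc

    def stage_normalize() -> None:
        sf = normalization.size_factors(counts)
        normed = normalization.normalize(counts, sf)
        logm = normalization.log_transform(normed, config.pseudocount)
        state.update(sf=sf, normed=normed, log=logm)
        p1 = _write_csv(pd.DataFrame({"sample_id": list(counts.sample_ids),
                                      "size_factor": sf}),
                        outdir / "size_factors.csv")
        p2 = _write_csv(pd.DataFrame(normed, index=list(counts.gene_ids),
                                     columns=list(counts.sample_ids))
                        .rename_axis("gene_id").reset_index(),
                        outdir / "normalized_counts.csv")
        record("normalize", [p1, p2], pseudocount=config.pseudocount)

    def stage_explore() -> None:
        K = min(config.pca_components, min(counts.n_genes, counts.n_samples))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = exploratory.run_pca(state["log"], K=K)
            hcpc = exploratory.run_hcpc(pca, k=config.hcpc_k,
                                        n_components=pca.n_components)
            corr = exploratory.correlation_matrix(state["log"])
            scaled, kept = exploratory.scaled_expression_matrix(state["log"])
        sample_ids = list(counts.sample_ids)
        outs = [
            _write_csv(pd.DataFrame(pca.scores, index=sample_ids,
                                    columns=[f"PC{i+1}" for i in range(pca.n_components)])
                       .rename_axis("sample_id").reset_index(),
                       outdir / "pca_scores.csv"),
            _write_csv(pd.DataFrame(pca.loadings,
                                    index=[counts.gene_ids[i] for i in pca.kept_gene_idx],
                                    columns=[f"PC{i+1}" for i in range(pca.n_components)])
                       .rename_axis("gene_id").reset_index(),
                       outdir / "pca_loadings.csv"),
            _write_csv(pd.DataFrame({"component": [f"PC{i+1}" for i in range(pca.n_components)],
                                     "explained_fraction": pca.explained_variance_fraction}),
                       outdir / "pca_variance.csv"),
            _write_csv(pd.DataFrame({"sample_id": sample_ids, "cluster": hcpc.labels}),
                       outdir / "hcpc_labels.csv"),
            _write_csv(pd.DataFrame(corr, index=sample_ids, columns=sample_ids)
                       .rename_axis("sample_id").reset_index(),
                       outdir / "correlation.csv"),
            _write_csv(pd.DataFrame(scaled,
                                    index=[counts.gene_ids[i] for i in kept],
                                    columns=sample_ids)
                       .rename_axis("gene_id").reset_index(),
                       outdir / "scaled_expression.csv"),
        ]
        record("explore", outs, pca_components=K, hcpc_k=hcpc.k)

    def stage_cluster() -> None:
        outs = []
        for cond in design.conditions:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = clustering.temporal_profiles(state["log"], counts.gene_ids,
                                                    design, cond)
                k = min(config.cluster_k, max(1, prof.n_profiles - 1))
                res = clustering.fuzzy_cmeans(prof, k=k, m=config.cluster_m,
                                              seed=config.seed)
            outs.append(_write_csv(
                pd.DataFrame(res.memberships, index=list(prof.gene_ids),
                             columns=[f"cluster_{i+1}" for i in range(res.k)])
                .rename_axis("gene_id").reset_index(),
                outdir / f"memberships_{cond}.csv"))
            outs.append(_write_csv(
                pd.DataFrame(res.centroids,
                             index=[f"cluster_{i+1}" for i in range(res.k)],
                             columns=list(prof.times))
                .rename_axis("cluster").reset_index(),
                outdir / f"centroids_{cond}.csv"))
        record("cluster", outs, k=config.cluster_k, m=config.cluster_m,
               seed=config.seed)

    def stage_de() -> None:
        analysis = de.run_de(counts, design, alpha=config.alpha,
                             min_lfc=config.min_lfc, sf=state.get("sf"))
        state["de"] = analysis
        outs = []
        for label, df in analysis.results.items():
            safe = label.replace(":", "_")
            outs.append(_write_csv(df, outdir / f"de_{safe}.csv"))
        record("de", outs, alpha=config.alpha, min_lfc=config.min_lfc,
               n_contrasts=len(analysis.contrasts))

    def stage_combine() -> None:
        analysis: de.DEAnalysis = state["de"]
        dm = combination.build_decision_matrix(
            analysis.results, analysis.contrasts, design,
            alpha=config.alpha, min_lfc=config.min_lfc)
        state["dm"] = dm
        outs = []
        multi = design.n_conditions >= 2
        # activation clusters
        act = pd.concat(
            [combination.first_de_time(dm, c).rename("first_de_time")
             .rename_axis("gene_id").reset_index().assign(condition=c)
             for c in design.conditions], ignore_index=True)
        outs.append(_write_csv(act[["gene_id", "condition", "first_de_time"]],
                               outdir / "activation_clusters.csv"))
        if multi:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec_rows = [
                    {"gene_id": g, "condition": c, "time": t}
                    for c in design.conditions
                    for t in design.times
                    for g in combination.call_specific(dm, c, t)
                ]
                sig = pd.concat([combination.call_signature(dm, c)
                                 for c in design.conditions], ignore_index=True)
                spec_all = pd.concat([combination.specific_alluvial(dm, t)
                                      for t in design.times], ignore_index=True)
            outs.append(_write_csv(pd.DataFrame(spec_rows,
                                                columns=["gene_id", "condition", "time"]),
                                   outdir / "specific_genes.csv"))
            outs.append(_write_csv(sig[sig["signature"]],
                                   outdir / "signature_genes.csv"))
            outs.append(_write_csv(spec_all, outdir / "alluvial_specific.csv"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            allu = pd.concat([combination.alluvial_flows(dm, c).assign(condition=c)
                              for c in design.conditions], ignore_index=True)
        outs.append(_write_csv(allu, outdir / "alluvial_temporal.csv"))
        master = master_table(dm, analysis)
        outs.append(_write_csv(master, outdir / "master_results.csv"))
        record("combine", outs, alpha=config.alpha, min_lfc=config.min_lfc)

    def stage_export() -> None:
        from . import enrichment
        analysis: de.DEAnalysis = state["de"]
        dm: combination.DecisionMatrix = state["dm"]
        outs = []
        gsea_dir = outdir / "gsea"
        gsea_dir.mkdir(exist_ok=True)
        for label, df in analysis.results.items():
            safe = label.replace(":", "_")
            p = gsea_dir / f"{safe}.rnk"
            enrichment.write_rnk(df, p)
            outs.append(p)
        normed_df = pd.DataFrame(state["normed"], index=list(counts.gene_ids),
                                 columns=list(counts.sample_ids))
        pg = gsea_dir / "expression.gct"
        enrichment.write_gct(normed_df, pg)
        pc = gsea_dir / "phenotypes.cls"
        enrichment.write_cls(design, pc)
        outs += [pg, pc]
        lists_dir = outdir / "gene_lists"
        calls: dict[str, list[str]] = {}
        multi = design.n_conditions >= 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in design.conditions:
                fdt = combination.first_de_time(dm, c)
                for t in design.times[1:]:
                    calls[f"activated_{c}_{t}"] = sorted(fdt.index[fdt == t])
                if multi:
                    union: set[str] = set()
                    for t in design.times:
                        genes = combination.call_specific(dm, c, t)
                        calls[f"specific_{c}_{t}"] = sorted(genes)
                    sig = combination.call_signature(dm, c)
                    calls[f"signature_{c}_union"] = sorted(
                        sig.loc[sig["signature"], "gene_id"])
        universe = sorted(g for g, t in zip(dm.gene_ids, dm.tested.any(axis=1)) if t)
        outs += enrichment.write_gene_lists(calls, universe, lists_dir)
        record("export", outs)

    for name, fn in (("normalize", stage_normalize), ("explore", stage_explore),
                     ("cluster", stage_cluster), ("de", stage_de),
                     ("combine", stage_combine), ("export", stage_export)):
        run_stage(name, fn)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return manifest
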