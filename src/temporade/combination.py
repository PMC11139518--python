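"""Combinatorial calling of DE patterns across the two contrast families.

Starting from a boolean decision matrix (genes x contrasts, one column per
temporal ``ti vs t0`` contrast and per pairwise condition contrast at each
time), this module derives:

* activation clusters — for each condition, the gene sets sharing the same
  first DE time against t0 ("never" when a gene is never DE);
* *specific* genes of condition A at time ti — DE between A and every
  other condition at ti, while no other condition pair is DE at ti, i.e.
  the expression shift is attributable to A alone;
* *signature* genes of condition A — genes that at some time ti are both
  specific to A at ti and temporally DE (ti vs t0) within A: the
  condition's temporal transcriptional signature;
* alluvial flow tables tracking DE-state transitions of activated genes
  between consecutive times, and per-time specific-gene counts.

With only two conditions the "no other pair" clause is vacuous, so any DE
gene is specific to both conditions; a warning marks specificity as
uninformative there.  Untestable genes are treated as not-DE everywhere,
with the untestable mask carried alongside so consumers can distinguish
"tested, not DE" from "not testable".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import ContrastSpec, ExperimentalDesign

__all__ = [
    "DecisionMatrix",
    "build_decision_matrix",
    "call_specific",
    "call_signature",
    "first_de_time",
    "alluvial_flows",
    "specific_alluvial",
]

NEVER = "never"


@dataclass
class DecisionMatrix:
    """Boolean DE calls per gene per contrast, plus the thresholds used."""

    calls: pd.DataFrame      # genes x contrast labels, bool
    tested: pd.DataFrame     # genes x contrast labels, bool (False = untestable)
    contrasts: list[ContrastSpec]
    conditions: tuple[str, ...]
    times: tuple[str, ...]
    alpha: float
    min_lfc: float

    def __post_init__(self) -> None:
        labels = [c.label for c in self.contrasts]
        if list(self.calls.columns) != labels:
            raise ValueError("decision matrix columns must match contrast labels in order")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def t0(self) -> str:
        return self.times[0]

    def temporal_label(self, condition: str, time: str) -> str:
        return ContrastSpec("temporal", condition, None, time, t0=self.t0).label

    def condition_label(self, a: str, b: str, time: str) -> str:
        return ContrastSpec("condition", a, b, time).label


def build_decision_matrix(
    results: Mapping[str, pd.DataFrame],
    contrasts: list[ContrastSpec],
    design: ExperimentalDesign,
    alpha: float = 0.05,
    min_lfc: float = 0.0,
) -> DecisionMatrix:
    """DE calls: (adjusted p < alpha) AND (|log2FC| >= min_lfc).

    ``results`` maps contrast label to a per-gene frame with columns
    ``gene_id``, ``log2_fold_change``, ``padj``.  Untestable genes (absent
    adjusted p) are recorded as not-DE and masked in ``tested``.
    """
    missing = [c.label for c in contrasts if c.label not in results]
    if missing:
        raise ValueError(f"missing results for contrasts: {missing}")
    first = results[contrasts[0].label]
    genes = [str(g) for g in first["gene_id"]]
    calls = pd.DataFrame(index=genes, dtype=bool)
    tested = pd.DataFrame(index=genes, dtype=bool)
    for spec in contrasts:
        df = results[spec.label].set_index("gene_id")
        df = df.reindex(genes)
        padj = df["padj"].to_numpy(dtype=float)
        lfc = df["log2_fold_change"].to_numpy(dtype=float)
        ok = ~np.isnan(padj)
        call = np.zeros(len(genes), dtype=bool)
        call[ok] = (padj[ok] < alpha) & (np.abs(lfc[ok]) >= min_lfc)
        calls[spec.label] = call
        tested[spec.label] = ok
    return DecisionMatrix(calls, tested, list(contrasts), design.conditions,
                          design.times, alpha, min_lfc)


def _check_condition_family(dm: DecisionMatrix) -> None:
    if len(dm.conditions) < 2:
        raise ValueError("specificity needs at least 2 conditions")
    if not any(c.kind == "condition" for c in dm.contrasts):
        raise ValueError("decision matrix lacks the condition contrast family")


def call_specific(dm: DecisionMatrix, condition: str, time: str) -> list[str]:
    """Genes specific to ``condition`` at ``time``.

    gene in output iff DE(condition vs B at time) for every other B, and
    not DE(B vs C at time) for every pair {B, C} not containing the focal
    condition.
    """
    _check_condition_family(dm)
    if condition not in dm.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if time not in dm.times:
        raise ValueError(f"unknown time {time!r}")
    others = [c for c in dm.conditions if c != condition]
    if len(dm.conditions) == 2:
        warnings.warn(
            "specificity with only two conditions is uninformative: "
            "the 'no other pair' clause is vacuous"
        )
    focal_cols = [dm.condition_label(condition, b, time) for b in others]
    other_cols = [
        dm.condition_label(b, c, time)
        for i, b in enumerate(others)
        for c in others[i + 1:]
    ]
    mask = dm.calls[focal_cols].all(axis=1)
    if other_cols:
        mask &= ~dm.calls[other_cols].any(axis=1)
    return [g for g, flag in mask.items() if flag]


def call_signature(
    dm: DecisionMatrix,
    condition: str,
    same_time: bool = True,
) -> pd.DataFrame:
    """Signature genes of a condition.

    Default (``same_time=True``): a gene is a signature gene iff there is a
    non-reference time ti at which it is simultaneously specific to the
    condition and temporally DE (ti vs t0); the frame lists those times.
    Specificity at t0 never contributes (there is no temporal contrast at
    t0).  ``same_time=False`` applies the looser reading — DE at some time
    and specific at some (possibly different, possibly t0) time.
    """
    _check_condition_family(dm)
    if not any(c.kind == "temporal" for c in dm.contrasts):
        raise ValueError("decision matrix lacks the temporal contrast family")
    genes = dm.gene_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specific_at = {t: set(call_specific(dm, condition, t)) for t in dm.times}
    temporal_at = {
        t: dm.calls[dm.temporal_label(condition, t)] for t in dm.times[1:]
    }
    rows = []
    for g in genes:
        if same_time:
            times = [t for t in dm.times[1:]
                     if g in specific_at[t] and bool(temporal_at[t][g])]
            flag = bool(times)
        else:
            any_temporal = any(bool(temporal_at[t][g]) for t in dm.times[1:])
            any_specific = any(g in specific_at[t] for t in dm.times)
            flag = any_temporal and any_specific
            times = [t for t in dm.times[1:]
                     if g in specific_at[t] and bool(temporal_at[t][g])]
        rows.append({"gene_id": g, "condition": condition,
                     "times": ";".join(times), "signature": flag})
    return pd.DataFrame(rows)


def first_de_time(dm: DecisionMatrix, condition: str) -> pd.Series:
    """Earliest time (in time order) at which each gene is DE vs t0 within
    the condition, or ``"never"``."""
    if not any(c.kind == "temporal" for c in dm.contrasts):
        raise ValueError("decision matrix lacks the temporal contrast family")
    cols = [dm.temporal_label(condition, t) for t in dm.times[1:]]
    sub = dm.calls[cols].to_numpy()
    out = []
    for row in sub:
        hits = np.flatnonzero(row)
        out.append(dm.times[1:][hits[0]] if hits.size else NEVER)
    return pd.Series(out, index=dm.gene_ids, name=f"first_de_time_{condition}")


def alluvial_flows(dm: DecisionMatrix, condition: str) -> pd.DataFrame:
    """DE-state transitions of activated genes between consecutive times.

    Rows: (time_from, time_to, status_from, status_to, activation_cluster,
    gene_count), restricted to ever-activated genes (first DE time is not
    "never").  For each consecutive time pair the counts partition the
    activated genes.
    """
    nonref = dm.times[1:]
    if len(nonref) < 2:
        warnings.warn("fewer than two non-reference times: empty alluvial table")
        return pd.DataFrame(columns=["time_from", "time_to", "status_from",
                                     "status_to", "activation_cluster", "gene_count"])
    fdt = first_de_time(dm, condition)
    activated = fdt[fdt != NEVER]
    rows = []
    for t_from, t_to in zip(nonref[:-1], nonref[1:]):
        col_from = dm.calls[dm.temporal_label(condition, t_from)]
        col_to = dm.calls[dm.temporal_label(condition, t_to)]
        for g, cluster in activated.items():
            rows.append((t_from, t_to,
                         "DE" if col_from[g] else "not-DE",
                         "DE" if col_to[g] else "not-DE",
                         cluster))
    if not rows:
        return pd.DataFrame(columns=["time_from", "time_to", "status_from",
                                     "status_to", "activation_cluster", "gene_count"])
    df = pd.DataFrame(rows, columns=["time_from", "time_to", "status_from",
                                     "status_to", "activation_cluster"])
    out = (df.groupby(["time_from", "time_to", "status_from", "status_to",
                       "activation_cluster"], sort=False)
             .size().reset_index(name="gene_count"))
    return out


def specific_alluvial(dm: DecisionMatrix, time: str) -> pd.DataFrame:
    """Per-condition count of specific genes at one time."""
    _check_condition_family(dm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = [
            {"condition": c, "time": time,
             "gene_count": len(call_specific(dm, c, time))}
            for c in dm.conditions
        ]
    return pd.DataFrame(rows)
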