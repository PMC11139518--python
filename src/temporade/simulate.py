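"""Seeded negative-binomial count simulator with planted DE structure.

Counts for gene g in a sample of cell (condition, time) are drawn from
NB(mean = sf_sample * mu_{g,cell}, dispersion alpha) with variance
mu + alpha * mu^2 (alpha = 0 degenerates to Poisson).  Cell means are
mu_{g,cell} = baseline_g * 2^(sum of applicable log2 effects), with
baselines log-normal and per-sample size factors log-uniform.  The effect
grammar plants temporal-DE genes (an effect shared by all conditions from
an onset time onward), condition-specific genes (an effect in exactly one
condition), and hence signature genes.

Ground-truth labels are not bookkept by hand: they are obtained by running
the package's own specificity/signature set logic on the *true* fold
changes (threshold |log2FC| > 0), so truth semantics and calling semantics
coincide by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .combination import DecisionMatrix, call_signature, call_specific, first_de_time
from .design import (ContrastSpec, CountMatrix, ExperimentalDesign, SampleInfo,
                     enumerate_condition_contrasts, enumerate_temporal_contrasts)

__all__ = ["Effect", "SimulationSpec", "SimulationTruth", "simulate",
           "preset_reference_shape"]


@dataclass(frozen=True)
class Effect:
    """A planted log2 shift for one gene in one (condition, time) cell."""

    gene: int
    condition: str
    time: str
    log2fc: float


@dataclass
class SimulationSpec:
    conditions: tuple[str, ...] = ("A", "B")
    times: tuple[str, ...] = ("t0", "t1", "t2")
    replicates: int = 4
    n_genes: int = 100
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    effects: tuple[Effect, ...] = ()
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for e in self.effects:
            if not (0 <= e.gene < self.n_genes):
                raise ValueError(f"effect references unknown gene index {e.gene}")
            if e.condition not in self.conditions:
                raise ValueError(f"effect references unknown condition {e.condition!r}")
            if e.time not in self.times:
                raise ValueError(f"effect references unknown time {e.time!r}")


@dataclass
class SimulationTruth:
    """True cell means and the derived truth labels."""

    true_means: pd.DataFrame                 # genes x cells ("cond:time" columns)
    decision_matrix: DecisionMatrix | None   # DE calls on true fold changes
    is_temporal_de: pd.DataFrame             # genes x conditions (any time)
    is_specific: pd.DataFrame                # genes x conditions (any time)
    is_signature: pd.DataFrame               # genes x conditions
    specific_at: dict[tuple[str, str], set[str]]   # (condition, time) -> genes
    temporal_de_at: dict[tuple[str, str], set[str]]


def _build_design(spec: SimulationSpec) -> ExperimentalDesign:
    samples = tuple(
        SampleInfo(f"{c}_{t}_r{r}", c, t, r)
        for c in spec.conditions
        for t in spec.times
        for r in range(1, spec.replicates + 1)
    )
    return ExperimentalDesign(samples, spec.conditions, spec.times)


def _truth_from_means(mu: np.ndarray, gene_ids, design: ExperimentalDesign) -> SimulationTruth:
    """Apply the package's quantified definitions to the true fold changes."""
    cells = design.cells()
    cell_idx = {cell: i for i, cell in enumerate(cells)}
    contrasts = (list(enumerate_temporal_contrasts(design))
                 if design.n_times >= 2 else [])
    if design.n_conditions >= 2:
        contrasts += enumerate_condition_contrasts(design)
    genes = list(gene_ids)
    tm = pd.DataFrame(mu, index=genes, columns=[f"{c}:{t}" for c, t in cells])
    if not contrasts:  # degenerate single-cell-family design: no DE structure
        empty = pd.DataFrame(False, index=genes, columns=list(design.conditions))
        return SimulationTruth(tm, None, empty, empty.copy(), empty.copy(), {}, {})
    results = {}
    for spec in contrasts:
        (ca, cb) = spec.cells()
        a, b = mu[:, cell_idx[ca]], mu[:, cell_idx[cb]]
        lfc = np.log2(np.maximum(a, 1e-300) / np.maximum(b, 1e-300))
        results[spec.label] = pd.DataFrame({
            "gene_id": genes,
            "log2_fold_change": lfc,
            # any true fold change counts as DE in truth space
            "padj": np.where(lfc != 0, 0.0, 1.0),
        })
    from .combination import build_decision_matrix
    dm = build_decision_matrix(results, contrasts, design, alpha=0.5, min_lfc=0.0)

    conds = design.conditions
    temporal_at = {}
    specific_at = {}
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for c in conds:
            for t in design.times[1:]:
                col = dm.calls[dm.temporal_label(c, t)]
                temporal_at[(c, t)] = {g for g in genes if col[g]}
            if design.n_conditions >= 2:
                for t in design.times:
                    specific_at[(c, t)] = set(call_specific(dm, c, t))
        is_temp = pd.DataFrame(
            {c: [any(g in temporal_at[(c, t)] for t in design.times[1:]) for g in genes]
             for c in conds}, index=genes)
        if design.n_conditions >= 2:
            is_spec = pd.DataFrame(
                {c: [any(g in specific_at[(c, t)] for t in design.times) for g in genes]
                 for c in conds}, index=genes)
            if design.n_times >= 2:
                sig = {}
                for c in conds:
                    sdf = call_signature(dm, c).set_index("gene_id")
                    sig[c] = sdf["signature"].reindex(genes).to_numpy()
                is_sig = pd.DataFrame(sig, index=genes)
            else:
                is_sig = pd.DataFrame(False, index=genes, columns=list(conds))
        else:
            is_spec = pd.DataFrame(False, index=genes, columns=list(conds))
            is_sig = pd.DataFrame(False, index=genes, columns=list(conds))

    return SimulationTruth(tm, dm, is_temp, is_spec, is_sig, specific_at, temporal_at)


def simulate(spec: SimulationSpec) -> tuple[CountMatrix, ExperimentalDesign, SimulationTruth]:
    """Draw one dataset; identical spec (including seed) gives identical
    output.  Truth labels are computed exactly from the true means."""
    rng = np.random.default_rng(spec.seed)
    design = _build_design(spec)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                             size=spec.n_genes)
    lo, hi = spec.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design.samples)))

    cells = design.cells()
    cell_idx = {cell: i for i, cell in enumerate(cells)}
    log2_shift = np.zeros((spec.n_genes, len(cells)))
    for e in spec.effects:
        log2_shift[e.gene, cell_idx[(e.condition, e.time)]] += e.log2fc
    mu = baseline[:, None] * 2.0 ** log2_shift

    counts = np.zeros((spec.n_genes, len(design.samples)), dtype=np.int64)
    for j, s in enumerate(design.samples):
        m = mu[:, cell_idx[s.cell]] * sf[j]
        if spec.dispersion == 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / spec.dispersion
            p = r / (r + m)
            counts[:, j] = rng.negative_binomial(r, p)
    cm = CountMatrix(gene_ids, design.sample_ids, counts)
    return cm, design, _truth_from_means(mu, gene_ids, design)


def preset_reference_shape(
    seed: int,
    n_genes: int = 2000,
    frac_temporal: float = 0.05,
    frac_specific_per_condition: float = 0.02,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
) -> SimulationSpec:
    """The reference study shape: 4 conditions x 6 time points x 4
    replicates (96 samples), with 5% shared temporal-DE genes and 2%
    condition-specific genes per condition at |log2FC| = 2.

    Temporal genes get an identical +/-2 shift in every condition from a
    random onset time onward (so no condition pair differs); specific genes
    get the shift in exactly one condition, making them specific — and,
    being shifted vs t0, signature — genes of that condition by
    construction.
    """
    conditions = ("A", "B", "C", "D")
    times = ("t0", "t1", "t2", "t3", "t4", "t5")
    rng = np.random.default_rng(seed)
    n_temporal = int(round(frac_temporal * n_genes))
    n_specific = int(round(frac_specific_per_condition * n_genes))
    need = n_temporal + n_specific * len(conditions)
    if need > n_genes:
        raise ValueError("too many planted genes for n_genes")
    chosen = rng.choice(n_genes, size=need, replace=False)
    temporal_genes = chosen[:n_temporal]
    effects: list[Effect] = []
    for g in temporal_genes:
        sign = rng.choice([-1.0, 1.0])
        onset = rng.integers(1, len(times))
        for c in conditions:
            for t in times[onset:]:
                effects.append(Effect(int(g), c, t, sign * effect_log2fc))
    pos = n_temporal
    for c in conditions:
        for g in chosen[pos:pos + n_specific]:
            sign = rng.choice([-1.0, 1.0])
            onset = rng.integers(1, len(times))
            for t in times[onset:]:
                effects.append(Effect(int(g), c, t, sign * effect_log2fc))
        pos += n_specific
    return SimulationSpec(
        conditions=conditions,
        times=times,
        replicates=4,
        n_genes=n_genes,
        dispersion=dispersion,
        effects=tuple(effects),
        seed=seed,
    )
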