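import numpy as np
import pandas as pd
import pytest

import temporade as tp


@pytest.fixture
def small_design() -> tp.ExperimentalDesign:
    """2 conditions x 3 times x 2 replicates."""
    samples = tuple(
        tp.SampleInfo(f"{c}_{t}_r{r}", c, t, r)
        for c in ("A", "B") for t in ("t0", "t1", "t2") for r in (1, 2)
    )
    return tp.ExperimentalDesign(samples, ("A", "B"), ("t0", "t1", "t2"))


@pytest.fixture
def paper_shape_design() -> tp.ExperimentalDesign:
    """4 conditions x 6 times x 4 replicates (96 samples)."""
    conds = ("A", "B", "C", "D")
    times = tuple(f"t{i}" for i in range(6))
    samples = tuple(
        tp.SampleInfo(f"{c}_{t}_r{r}", c, t, r)
        for c in conds for t in times for r in range(1, 5)
    )
    return tp.ExperimentalDesign(samples, conds, times)


def random_design(rng: np.random.Generator, C: int, T: int,
                  replicates: int = 2) -> tp.ExperimentalDesign:
    conds = tuple(chr(ord("A") + i) for i in range(C))
    times = tuple(f"t{i}" for i in range(T))
    samples = tuple(
        tp.SampleInfo(f"{c}_{t}_r{r}", c, t, r)
        for c in conds for t in times for r in range(1, replicates + 1)
    )
    return tp.ExperimentalDesign(samples, conds, times)


def random_decision_matrix(rng: np.random.Generator, design: tp.ExperimentalDesign,
                           n_genes: int = 50, p_de: float = 0.3) -> tp.DecisionMatrix:
    """Random boolean DE calls over both contrast families."""
    contrasts = list(tp.enumerate_temporal_contrasts(design))
    if design.n_conditions >= 2:
        contrasts += tp.enumerate_condition_contrasts(design)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    results = {}
    for spec in contrasts:
        de = rng.random(n_genes) < p_de
        results[spec.label] = pd.DataFrame({
            "gene_id": genes,
            "log2_fold_change": np.where(de, 2.0, 0.0),
            "padj": np.where(de, 0.001, 0.9),
        })
    return tp.build_decision_matrix(results, contrasts, design, alpha=0.05)
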