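"""Specific/signature calling, activation clusters and alluvial tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import temporade as tp
from temporade.combination import NEVER

from conftest import random_decision_matrix, random_design


def brute_force_specific(dm: tp.DecisionMatrix, condition: str, time: str):
    """Literal quantified definition, evaluated gene by gene."""
    genes = []
    others = [c for c in dm.conditions if c != condition]
    for g in dm.gene_ids:
        ok = all(dm.calls.loc[g, dm.condition_label(condition, b, time)]
                 for b in others)
        for i, b in enumerate(others):
            for c in others[i + 1:]:
                if dm.calls.loc[g, dm.condition_label(b, c, time)]:
                    ok = False
        if ok:
            genes.append(g)
    return genes


def brute_force_signature(dm: tp.DecisionMatrix, condition: str):
    out = {}
    for g in dm.gene_ids:
        flag = False
        for t in dm.times[1:]:
            spec = g in set(brute_force_specific(dm, condition, t))
            temp = bool(dm.calls.loc[g, dm.temporal_label(condition, t)])
            if spec and temp:
                flag = True
        out[g] = flag
    return out


def _dm_from_patterns(design, patterns):
    """patterns: {contrast label: {gene: bool}}; unmentioned entries False."""
    contrasts = list(tp.enumerate_temporal_contrasts(design))
    if design.n_conditions >= 2:
        contrasts += tp.enumerate_condition_contrasts(design)
    genes = sorted({g for d in patterns.values() for g in d} | {"g_bg"})
    results = {}
    for spec in contrasts:
        flags = [patterns.get(spec.label, {}).get(g, False) for g in genes]
        results[spec.label] = pd.DataFrame({
            "gene_id": genes,
            "log2_fold_change": [2.0 if f else 0.0 for f in flags],
            "padj": [0.001 if f else 0.9 for f in flags],
        })
    return tp.build_decision_matrix(results, contrasts, design, alpha=0.05)


class TestDecisionMatrix:
    @pytest.mark.parametrize("padj,lfc,min_lfc,expected",
                             [(0.01, 0.5, 1.0, False),
                              (0.01, 2.0, 1.0, True),
                              (np.nan, 2.0, 0.0, False)])
    def test_call_predicate(self, padj, lfc, min_lfc, expected):
        design = random_design(np.random.default_rng(0), 1, 2)
        contrasts = tp.enumerate_temporal_contrasts(design)
        results = {contrasts[0].label: pd.DataFrame(
            {"gene_id": ["g1"], "log2_fold_change": [lfc], "padj": [padj]})}
        dm = tp.build_decision_matrix(results, contrasts, design,
                                      alpha=0.05, min_lfc=min_lfc)
        assert bool(dm.calls.iloc[0, 0]) is expected
        assert bool(dm.tested.iloc[0, 0]) is not np.isnan(padj)

    def test_missing_contrast_named(self):
        design = random_design(np.random.default_rng(0), 1, 3)
        contrasts = tp.enumerate_temporal_contrasts(design)
        results = {contrasts[0].label: pd.DataFrame(
            {"gene_id": ["g1"], "log2_fold_change": [0.0], "padj": [1.0]})}
        with pytest.raises(ValueError, match=contrasts[1].label):
            tp.build_decision_matrix(results, contrasts, design)


class TestCallSpecific:
    def test_three_condition_example(self):
        design = random_design(np.random.default_rng(0), 3, 2)
        t = "t1"
        dm = _dm_from_patterns(design, {
            f"{t}:A_vs_B": {"g1": True},
            f"{t}:A_vs_C": {"g1": True},
        })
        assert tp.call_specific(dm, "A", t) == ["g1"]
        assert tp.call_specific(dm, "B", t) == []

    def test_all_pairs_de_is_specific_to_none(self):
        design = random_design(np.random.default_rng(0), 3, 2)
        dm = _dm_from_patterns(design, {
            "t1:A_vs_B": {"g1": True}, "t1:A_vs_C": {"g1": True},
            "t1:B_vs_C": {"g1": True},
        })
        for c in design.conditions:
            assert tp.call_specific(dm, c, "t1") == []

    def test_two_conditions_specific_to_both_with_warning(self):
        design = random_design(np.random.default_rng(0), 2, 2)
        dm = _dm_from_patterns(design, {"t1:A_vs_B": {"g1": True}})
        with pytest.warns(UserWarning, match="uninformative"):
            assert tp.call_specific(dm, "A", "t1") == ["g1"]
        with pytest.warns(UserWarning):
            assert tp.call_specific(dm, "B", "t1") == ["g1"]

    def test_mutual_exclusivity_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            C = int(rng.integers(3, 5))
            T = int(rng.integers(2, 5))
            design = random_design(rng, C, T)
            dm = random_decision_matrix(rng, design, n_genes=30)
            for t in design.times:
                sets = [set(tp.call_specific(dm, c, t)) for c in design.conditions]
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        assert not (sets[i] & sets[j])

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            C = int(rng.integers(2, 5))
            design = random_design(rng, C, int(rng.integers(2, 5)))
            dm = random_decision_matrix(rng, design, n_genes=25)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for c in design.conditions:
                    for t in design.times:
                        assert tp.call_specific(dm, c, t) == \
                            brute_force_specific(dm, c, t)

    def test_monotone_in_other_pair_calls(self):
        """Flipping an other-pair call from True to False never removes an
        already-specific gene."""
        rng = np.random.default_rng(3)
        design = random_design(rng, 4, 3)
        dm = random_decision_matrix(rng, design, n_genes=40)
        t = design.times[1]
        before = set(tp.call_specific(dm, "A", t))
        col = dm.condition_label("B", "C", t)
        dm.calls[col] = False
        after = set(tp.call_specific(dm, "A", t))
        assert before <= after


class TestCallSignature:
    def test_same_time_conjunction(self):
        design = random_design(np.random.default_rng(0), 3, 3)
        dm = _dm_from_patterns(design, {
            "t2:A_vs_B": {"g1": True}, "t2:A_vs_C": {"g1": True},
            "A:t2_vs_t0": {"g1": True},
        })
        sig = tp.call_signature(dm, "A").set_index("gene_id")
        assert bool(sig.loc["g1", "signature"])
        assert sig.loc["g1", "times"] == "t2"

    def test_mismatched_times_not_signature_by_default_but_loose_reading_accepts(self):
        design = random_design(np.random.default_rng(0), 3, 5)
        dm = _dm_from_patterns(design, {
            "t2:A_vs_B": {"g1": True}, "t2:A_vs_C": {"g1": True},
            "A:t4_vs_t0": {"g1": True},
        })
        strict = tp.call_signature(dm, "A").set_index("gene_id")
        assert not bool(strict.loc["g1", "signature"])
        loose = tp.call_signature(dm, "A", same_time=False).set_index("gene_id")
        assert bool(loose.loc["g1", "signature"])

    def test_never_specific_is_not_signature(self):
        design = random_design(np.random.default_rng(0), 3, 3)
        dm = _dm_from_patterns(design, {"A:t1_vs_t0": {"g1": True}})
        sig = tp.call_signature(dm, "A").set_index("gene_id")
        assert not sig["signature"].any()

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            design = random_design(rng, int(rng.integers(2, 5)),
                                   int(rng.integers(2, 5)))
            dm = random_decision_matrix(rng, design, n_genes=20)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for c in design.conditions:
                    got = tp.call_signature(dm, c).set_index("gene_id")["signature"]
                    want = brute_force_signature(dm, c)
                    assert {g: bool(v) for g, v in got.items()} == want

    def test_signature_subset_of_necessary_conditions(self):
        rng = np.random.default_rng(5)
        design = random_design(rng, 4, 4)
        dm = random_decision_matrix(rng, design, n_genes=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in design.conditions:
                sig = tp.call_signature(dm, c).set_index("gene_id")
                any_temporal = dm.calls[
                    [dm.temporal_label(c, t) for t in design.times[1:]]
                ].any(axis=1)
                any_specific = {
                    g for t in design.times for g in tp.call_specific(dm, c, t)
                }
                for g in sig.index[sig["signature"]]:
                    assert any_temporal[g]
                    assert g in any_specific


class TestActivationAndAlluvial:
    def test_first_de_time_patterns(self):
        design = random_design(np.random.default_rng(0), 1, 6)
        dm = _dm_from_patterns(design, {
            "A:t3_vs_t0": {"g1": True}, "A:t5_vs_t0": {"g1": True},
            "A:t1_vs_t0": {"g2": True}, "A:t2_vs_t0": {"g2": True},
            "A:t3_vs_t0": {"g1": True, "g2": True},
            "A:t4_vs_t0": {"g2": True}, "A:t5_vs_t0": {"g1": True, "g2": True},
        })
        fdt = tp.first_de_time(dm, "A")
        assert fdt["g1"] == "t3"
        assert fdt["g2"] == "t1"
        assert fdt["g_bg"] == NEVER

    def test_alluvial_hand_enumeration(self):
        design = random_design(np.random.default_rng(0), 1, 3)
        dm = _dm_from_patterns(design, {
            "A:t1_vs_t0": {"g1": True, "g2": True},
            "A:t2_vs_t0": {"g1": True},
        })
        flows = tp.alluvial_flows(dm, "A")
        key = ["time_from", "time_to", "status_from", "status_to",
               "activation_cluster"]
        as_dict = {tuple(r[k] for k in key): r["gene_count"]
                   for _, r in flows.iterrows()}
        assert as_dict == {
            ("t1", "t2", "DE", "DE", "t1"): 1,
            ("t1", "t2", "DE", "not-DE", "t1"): 1,
        }

    def test_no_activated_genes_empty_table(self):
        design = random_design(np.random.default_rng(0), 1, 4)
        dm = _dm_from_patterns(design, {})
        flows = tp.alluvial_flows(dm, "A")
        assert len(flows) == 0

    def test_counts_conserved_across_time_pairs(self):
        rng = np.random.default_rng(6)
        design = random_design(rng, 2, 5)
        dm = random_decision_matrix(rng, design, n_genes=50)
        flows = tp.alluvial_flows(dm, "A")
        fdt = tp.first_de_time(dm, "A")
        n_activated = int((fdt != NEVER).sum())
        per_pair = flows.groupby(["time_from", "time_to"])["gene_count"].sum()
        assert (per_pair == n_activated).all()

    def test_fewer_than_two_nonreference_times_warns_empty(self):
        design = random_design(np.random.default_rng(0), 1, 2)
        dm = _dm_from_patterns(design, {"A:t1_vs_t0": {"g1": True}})
        with pytest.warns(UserWarning, match="alluvial"):
            flows = tp.alluvial_flows(dm, "A")
        assert flows.empty

    def test_specific_alluvial_matches_brute_force(self):
        rng = np.random.default_rng(7)
        design = random_design(rng, 3, 3)
        dm = random_decision_matrix(rng, design, n_genes=40)
        t = design.times[1]
        table = tp.specific_alluvial(dm, t).set_index("condition")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in design.conditions:
                assert table.loc[c, "gene_count"] == \
                    len(brute_force_specific(dm, c, t))
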