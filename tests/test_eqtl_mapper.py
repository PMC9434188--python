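"""eQTL detection, specificity and cis/trans classification."""

import numpy as np
import pytest

from conftest import make_matrix
from ilripe import (
    EQTLCall,
    EQTLClassification,
    GeneModel,
    ILSegment,
    classify_cis_trans,
    classify_panel,
    classify_specificity,
    detect_eqtls,
    locate_gene_ils,
)
from ilripe.eqtl_mapper import il_sample_groups_from_meta
from oracles import containment_scan, robust_eqtl_calls


def panel_matrix(il_means: dict, parent_mean: float, n_genes: int = 1):
    """One-gene matrix with one sample per IL plus a parent sample."""
    ils = list(il_means)
    sample_ids = ["M82_r1"] + [f"{il}_r1" for il in ils]
    genotypes = ["M82"] + ils
    values = np.array([[parent_mean] + [il_means[i] for i in ils]])
    return make_matrix(values, ["g1"], sample_ids, genotypes=genotypes)


class TestLocateGeneILs:
    def test_nested_ils_both_contain_the_gene(self):
        design = [
            ILSegment("IL4-1", "ch04", 0, 5_000_000),
            ILSegment("IL4-1-1", "ch04", 0, 2_000_000),
        ]
        gene = GeneModel("g", "ch04", 1_000_000, 1_002_000)
        assert locate_gene_ils(gene, design) == {"IL4-1", "IL4-1-1"}

    def test_whole_chromosome_il_contains_all_its_genes(self):
        design = [ILSegment("IL9-1", "ch09", 0, 10 ** 7)]
        gene = GeneModel("g", "ch09", 42, 2042)
        assert locate_gene_ils(gene, design) == {"IL9-1"}

    def test_random_genes_match_brute_force_scan(self):
        rng = np.random.default_rng(23)
        design = [
            ILSegment(f"IL{i}", f"ch{rng.integers(1, 5):02d}",
                      int(start), int(start) + int(rng.integers(1, 10 ** 6)))
            for i, start in enumerate(rng.integers(0, 10 ** 7, size=76))
        ]
        genes = [
            GeneModel(f"g{j}", f"ch{rng.integers(1, 5):02d}",
                      int(p), int(p) + 100)
            for j, p in enumerate(rng.integers(0, 10 ** 7 + 10 ** 6, size=500))
        ]
        oracle = containment_scan(genes, design)
        for g in genes:
            assert locate_gene_ils(g, design) == oracle[g.gene_id]


class TestDetectEQTLs:
    def test_flat_panel_yields_no_calls(self):
        il_means = {f"IL{i}": 16.0 for i in range(10)}
        m = panel_matrix(il_means, 16.0)
        groups = {il: [f"{il}_r1"] for il in il_means}
        assert detect_eqtls(m, "g1", ["M82_r1"], groups) == []

    def test_single_lowered_il_called_decreased_via_mad_fallback(self):
        # parent abundance 15 (log2(15+1)=4); one IL 8-fold down in
        # pseudocounted log2: abundance 1 -> log2(2)=1; all others at 15.
        il_means = {f"IL{i}": 15.0 for i in range(12)}
        il_means["IL5"] = 1.0
        m = panel_matrix(il_means, 15.0)
        groups = {il: [f"{il}_r1"] for il in il_means}
        calls = detect_eqtls(m, "g1", ["M82_r1"], groups)
        assert [c.il_id for c in calls] == ["IL5"]
        assert calls[0].direction == "decreased"
        assert calls[0].log2_ratio_vs_parent == pytest.approx(-3.0)

    def test_calls_match_independent_oracle_on_noisy_panel(self, small_panel):
        design, matrix, truth = small_panel
        groups = il_sample_groups_from_meta(matrix)
        parent = matrix.samples_where(genotype="M82")
        parent_arr = matrix.values[parent]
        for gene_id in matrix.gene_ids[:60]:
            row = matrix.values.loc[gene_id]
            il_log2 = {
                il: float(np.log2(row[s].mean() + 1.0))
                for il, s in groups.items()
            }
            parent_log2 = float(np.log2(parent_arr.loc[gene_id].mean() + 1.0))
            expected = robust_eqtl_calls(il_log2, parent_log2, 2.5, 1.0)
            got = {c.il_id for c in detect_eqtls(matrix, gene_id, parent, groups)}
            assert got == expected, gene_id

    def test_raising_thresholds_never_adds_calls(self, small_panel):
        _design, matrix, truth = small_panel
        groups = il_sample_groups_from_meta(matrix)
        parent = matrix.samples_where(genotype="M82")
        gene = sorted(truth.cis_genes)[0]
        loose = {c.il_id for c in detect_eqtls(matrix, gene, parent, groups,
                                               z_min=1.5, min_abs_log2=0.5)}
        default = {c.il_id for c in detect_eqtls(matrix, gene, parent, groups)}
        tight = {c.il_id for c in detect_eqtls(matrix, gene, parent, groups,
                                               z_min=4.0, min_abs_log2=2.0)}
        assert tight <= default <= loose

    def test_il_sample_order_does_not_change_calls(self, small_panel):
        _design, matrix, _truth = small_panel
        groups = il_sample_groups_from_meta(matrix)
        parent = matrix.samples_where(genotype="M82")
        gene = matrix.gene_ids[0]
        baseline = detect_eqtls(matrix, gene, parent, groups)
        shuffled = {il: list(reversed(s)) for il, s in reversed(groups.items())}
        permuted = detect_eqtls(matrix, gene, parent, shuffled)
        assert {(c.il_id, c.log2_ratio_vs_parent) for c in baseline} == {
            (c.il_id, c.log2_ratio_vs_parent) for c in permuted
        }


def call(il_id):
    return EQTLCall("g", il_id, 2.0, 5.0)


class TestSpecificity:
    def test_calls_confined_to_nested_located_ils_are_specific(self):
        assert classify_specificity(
            [call("IL4-1"), call("IL4-1-1")], {"IL4-1", "IL4-1-1"}
        ) == "specific"

    def test_calls_spread_over_many_ils_are_nonspecific(self):
        calls = [call(f"IL{i}") for i in range(10)]
        assert classify_specificity(calls, {"IL1"}) == "nonspecific"

    def test_no_calls_is_none(self):
        assert classify_specificity([], {"IL1"}) == "none"

    def test_max_extra_ils_relaxation(self):
        calls = [call("IL1"), call("IL7")]
        assert classify_specificity(calls, {"IL1"}) == "nonspecific"
        assert classify_specificity(calls, {"IL1"}, max_extra_ils=1) == "specific"


class TestCisTrans:
    def test_call_in_located_il_is_cis(self):
        cls = EQTLClassification("g", [call("IL1")], {"IL1"})
        assert classify_cis_trans(cls) == "cis"

    def test_call_elsewhere_is_trans(self):
        cls = EQTLClassification("g", [call("IL9")], {"IL1"})
        assert classify_cis_trans(cls) == "trans"

    def test_split_calls_are_mixed_and_empty_not_applicable(self):
        mixed = EQTLClassification("g", [call("IL1"), call("IL9")], {"IL1"})
        assert classify_cis_trans(mixed) == "mixed"
        empty = EQTLClassification("g", [], {"IL1"})
        assert classify_cis_trans(empty) == "not_applicable"

    def test_random_fixtures_match_set_comparison(self):
        rng = np.random.default_rng(6)
        ils = [f"IL{i}" for i in range(20)]
        for _ in range(200):
            called = set(rng.choice(ils, size=rng.integers(0, 6), replace=False))
            located = set(rng.choice(ils, size=rng.integers(1, 4), replace=False))
            cls = EQTLClassification("g", [call(i) for i in sorted(called)], located)
            got = classify_cis_trans(cls)
            if not called:
                assert got == "not_applicable"
            elif called <= located:
                assert got == "cis"
            elif not (called & located):
                assert got == "trans"
            else:
                assert got == "mixed"


class TestPlantedRecovery:
    def test_zero_noise_classification_is_exact(self, noiseless_panel):
        design, matrix, truth = noiseless_panel
        cls = classify_panel(
            matrix, truth.annotation, design,
            parent_samples=matrix.samples_where(genotype="M82"),
        )
        for g in truth.cis_genes:
            assert cls[g].specificity == "specific"
            assert cls[g].regulatory_class == "cis"
        for g in truth.trans_targets:
            assert cls[g].regulatory_class != "cis"

    def test_noisy_panel_recovers_most_cis_genes(self, small_panel):
        design, matrix, truth = small_panel
        cls = classify_panel(
            matrix, truth.annotation, design,
            parent_samples=matrix.samples_where(genotype="M82"),
        )
        hits = sum(
            1 for g in truth.cis_genes
            if cls[g].specificity == "specific"
            and cls[g].regulatory_class == "cis"
        )
        assert hits / len(truth.cis_genes) >= 0.9

    def test_trans_effects_fall_in_the_nonspecific_or_trans_bins(self, noiseless_panel):
        design, matrix, truth = noiseless_panel
        cls = classify_panel(
            matrix, truth.annotation, design,
            parent_samples=matrix.samples_where(genotype="M82"),
        )
        detected = [g for g in truth.trans_targets if cls[g].calls]
        assert detected  # trans effect (1.5 log2) clears the 1.0 floor
        for g in detected:
            assert cls[g].specificity == "nonspecific"

    def test_batched_panel_agrees_with_per_gene_path(self, small_panel):
        from ilripe import classify_gene

        design, matrix, truth = small_panel
        groups = il_sample_groups_from_meta(matrix)
        parent = matrix.samples_where(genotype="M82")
        batched = classify_panel(matrix, truth.annotation, design, parent)
        for g in matrix.gene_ids[:40]:
            single = classify_gene(matrix, truth.annotation[g], design,
                                   parent, groups)
            assert {c.il_id for c in single.calls} == {
                c.il_id for c in batched[g].calls
            }
            assert single.specificity == batched[g].specificity
            assert single.regulatory_class == batched[g].regulatory_class
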