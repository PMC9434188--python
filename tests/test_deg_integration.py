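"""DEG calling, BH adjustment, conserved overlaps and 2^-ddCt."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from ilripe import (
    ConfigError,
    Contrast,
    DdctMeasurement,
    call_degs,
    conserved_overlap,
    conserved_with_external,
    ddct,
)
from ilripe.deg_integration import DEGRecord, direction_sets, read_signed_gene_list
from oracles import bh_adjust, welch_p


def two_group_matrix(a_values, b_values, gene_ids=None):
    a_values, b_values = np.asarray(a_values), np.asarray(b_values)
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(a_values.shape[0])]
    values = np.hstack([a_values, b_values])
    samples = [f"a{j}" for j in range(a_values.shape[1])] + [
        f"b{j}" for j in range(b_values.shape[1])
    ]
    m = make_matrix(values, gene_ids, samples)
    contrast = Contrast("test", tuple(samples[: a_values.shape[1]]),
                        tuple(samples[a_values.shape[1]:]))
    return m, contrast


class TestCallDegs:
    def test_identical_groups_are_all_ns(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, size=(50, 3))
        m, c = two_group_matrix(vals, vals)
        records = call_degs(m, c)
        assert all(r.direction == "ns" for r in records)
        assert all(r.log2_fc == 0.0 for r in records)

    def test_fc_floor_binds_despite_tiny_p(self):
        # strong separation but log2FC ~ 0.5: must stay ns
        a = np.tile([10.0, 10.1, 9.9], (1, 1))
        b = np.tile([6.5, 6.6, 6.4], (1, 1))
        m, c = two_group_matrix(a, b)
        (rec,) = call_degs(m, c)
        assert abs(rec.log2_fc) < 1
        assert rec.p_value < 1e-4
        assert rec.direction == "ns"

    def test_planted_fourfold_genes_called_and_match_oracle(self):
        rng = np.random.default_rng(40)
        n, k, reps = 1000, 40, 3
        base = rng.uniform(4, 64, n)
        a = np.tile(base[:, None], (1, reps))
        b = np.tile(base[:, None], (1, reps))
        planted = rng.choice(n, size=k, replace=False)
        a[planted] *= 4.0
        m, c = two_group_matrix(a, b)
        records = call_degs(m, c)
        up = {r.gene_id for r in records if r.direction == "up"}
        assert up == {f"g{i:04d}" for i in planted}
        # oracle equivalence for P and BH-adjusted values
        log2a, log2b = np.log2(a + 1.0), np.log2(b + 1.0)
        p_oracle = [welch_p(list(log2a[i]), list(log2b[i])) for i in range(n)]
        fdr_oracle = bh_adjust(p_oracle)
        for rec, p, q in zip(records, p_oracle, fdr_oracle):
            assert rec.p_value == pytest.approx(p, abs=1e-10)
            assert rec.fdr == pytest.approx(q, abs=1e-10)

    def test_single_replicate_welch_is_config_error(self):
        m, c = two_group_matrix(np.ones((5, 1)), np.ones((5, 3)))
        with pytest.raises(ConfigError, match="fold_change"):
            call_degs(m, c)

    def test_fold_change_mode_calls_on_fc_alone(self):
        m, c = two_group_matrix(np.array([[40.0], [10.0]]),
                                np.array([[10.0], [10.0]]))
        records = call_degs(m, c, test="fold_change")
        assert records[0].direction == "up"
        assert records[1].direction == "ns"
        assert np.isnan(records[0].p_value)

    def test_null_simulation_call_fraction_bounded(self):
        # no planted effects: with the FC floor the call rate must sit
        # far below the nominal 5% — bound it by FDR + binomial slack
        rng = np.random.default_rng(77)
        n_genes, reps, n_sims = 100, 3, 50
        calls = total = 0
        for _ in range(n_sims):
            base = rng.uniform(4, 6, n_genes)  # log2 means
            a = 2 ** (base[:, None] + rng.normal(0, 0.4, (n_genes, reps)))
            b = 2 ** (base[:, None] + rng.normal(0, 0.4, (n_genes, reps)))
            m, c = two_group_matrix(a, b)
            for rec in call_degs(m, c):
                calls += rec.direction != "ns"
                total += 1
        fraction = calls / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert fraction <= 0.05 + 3 * se


class TestBHProperty:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=80))
    def test_adjusted_values_match_from_scratch_bh(self, pvalues):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(pvalues, method="fdr_bh")[1]
        oracle = bh_adjust(pvalues)
        np.testing.assert_allclose(adjusted, oracle, atol=1e-12)
        order = np.argsort(pvalues)
        sorted_adj = np.asarray(oracle)[order]
        assert (np.diff(sorted_adj) >= -1e-15).all()
        assert (sorted_adj <= 1.0 + 1e-15).all()


def rec(gene, contrast, direction):
    return DEGRecord(gene, contrast, 2.0 if direction == "up" else -2.0,
                     1e-6, 1e-5, direction)


class TestConservedOverlap:
    def test_disjoint_direction_sets_yield_empty_membership(self):
        sets = [
            ("A", [rec("g1", "A", "up")]),
            ("B", [rec("g2", "B", "down")]),
        ]
        conserved = conserved_overlap(sets, {"A": "up", "B": "down"})
        assert conserved.members == set()

    def test_planted_core_recovered_exactly(self):
        core = {f"c{i}" for i in range(40)}
        sets = []
        for name, want in [("OE_MG", "up"), ("RNAi_Br", "down"),
                           ("RNAi_Pink", "down")]:
            records = [rec(g, name, want) for g in core]
            records.append(rec(f"extra_{name}", name, want))
            sets.append((name, records))
        conserved = conserved_overlap(
            sets, {"OE_MG": "up", "RNAi_Br": "down", "RNAi_Pink": "down"}
        )
        assert conserved.members == core

    def test_venn_region_counts_partition_the_union(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(60)]
        sets = []
        for name in ("A", "B", "C"):
            chosen = rng.choice(genes, size=25, replace=False)
            sets.append((name, [rec(g, name, "up") for g in chosen]))
        conserved = conserved_overlap(sets, {"A": "up", "B": "up", "C": "up"})
        union = set()
        for _name, records in sets:
            union |= {r.gene_id for r in records}
        assert sum(conserved.venn_counts.values()) == len(union)

    def test_membership_is_subset_of_every_direction_set(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(50)]
        sets = []
        for name in ("A", "B"):
            records = [
                rec(g, name, rng.choice(["up", "down"])) for g in genes
            ]
            sets.append((name, records))
        conserved = conserved_overlap(sets, {"A": "up", "B": "down"})
        for name, records in sets:
            want = conserved.sign_pattern[name]
            dirset = direction_sets(records)[want]
            assert conserved.members <= dirset

    def test_unknown_contrast_in_pattern_is_config_error(self):
        with pytest.raises(ConfigError):
            conserved_overlap([("A", [])], {"A": "up", "Z": "down"})


class TestConservedWithExternal:
    def make_internal(self, members):
        return conserved_overlap(
            [("OE_MG", [rec(g, "OE_MG", "up") for g in members]),
             ("RNAi_Br", [rec(g, "RNAi_Br", "down") for g in members])],
            {"OE_MG": "up", "RNAi_Br": "down"},
        )

    def test_empty_external_set_empties_the_overlap(self):
        internal = self.make_internal({"g1", "g2"})
        merged = conserved_with_external(internal, {"rin": {}})
        assert merged.members == set()

    def test_shared_signed_core_recovered_exactly(self):
        core = {f"c{i}" for i in range(25)}
        internal = self.make_internal(core | {"onlyinternal"})
        rin = {g: "down" for g in core} | {"rinonly": "down", "wrongsign": "up"}
        nor = {g: "down" for g in core} | {"noronly": "down"}
        merged = conserved_with_external(internal, {"rin": rin, "nor": nor})
        assert merged.members == core

    def test_external_order_is_immaterial(self):
        core = {f"c{i}" for i in range(10)}
        internal = self.make_internal(core)
        rin = {g: "down" for g in list(core)[:7]}
        nor = {g: "down" for g in list(core)[3:]}
        a = conserved_with_external(internal, {"rin": rin, "nor": nor})
        b = conserved_with_external(internal, {"nor": nor, "rin": rin})
        assert a.members == b.members

    def test_unsigned_external_list_warns_and_skips_sign_check(self, caplog):
        internal = self.make_internal({"g1", "g2"})
        merged = conserved_with_external(internal, {"rin": {"g1", "g2"}})
        assert merged.members == {"g1", "g2"}
        assert any("unsigned" in r.message for r in caplog.records)

    def test_signed_list_round_trips_from_tsv(self, tmp_path):
        p = tmp_path / "rin.tsv"
        p.write_text("gene_id\tdirection\ng1\tdown\ng2\tup\n")
        assert read_signed_gene_list(p) == {"g1": "down", "g2": "up"}


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 20.0, 20.0, 20.0), 1.0),   # all equal
            ((21.0, 20.0, 20.0, 20.0), 0.5),   # ddCt = 1
            ((20.0, 18.0, 24.0, 18.0), 16.0),  # ddCt = -4
        ],
    )
    def test_closed_forms(self, cts, expected):
        (value,) = ddct([DdctMeasurement(*cts)])
        assert value == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.tuples(*[st.floats(5, 35) for _ in range(4)]),
        st.floats(-10, 10),
    )
    def test_shift_invariance_under_common_ct_offset(self, cts, shift):
        base = DdctMeasurement(*cts)
        shifted = DdctMeasurement(*(c + shift for c in cts))
        assert shifted.relative_expression == pytest.approx(
            base.relative_expression, rel=1e-9
        )

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ConfigError):
            ddct([DdctMeasurement(float("nan"), 20, 20, 20)])
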