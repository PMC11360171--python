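"""Data-cleaning rules: conflict resolution, TAS dedup, tiers, splitting."""

import numpy as np
import pandas as pd
import pytest

from qgexar import ActivityTable, SignatureMatrix
from qgexar.assembly import (
    dedupe_profiles_by_tas,
    filter_gene_tier,
    make_split,
    resolve_activity_conflicts,
)


def activity_frame(rows):
    return pd.DataFrame(rows, columns=["chemical_id", "endpoint", "label", "n_sources"])


def signature(rows, genes=("L:G0001", "B:G0002", "I:G0003"), cell_line="MCF7"):
    """rows = [(chemical_id, tas, values...)]"""
    data = pd.DataFrame(
        [
            {"chemical_id": cid, "cell_line": cell_line, "tas": tas,
             **dict(zip(genes, vals))}
            for cid, tas, *vals in rows
        ]
    )
    return SignatureMatrix(data)


class TestResolveActivityConflicts:
    def test_contradiction_resolves_active(self):
        raw = activity_frame([("c1", "ER", "active", 1), ("c1", "ER", "inactive", 1)])
        out = resolve_activity_conflicts(ActivityTable(raw)).records
        assert len(out) == 1
        assert out.loc[0, "label"] == "active"
        assert out.loc[0, "n_sources"] == 2
        assert bool(out.loc[0, "had_conflict"])

    def test_single_record_passthrough(self):
        raw = activity_frame([("c2", "AR", "inactive", 1)])
        out = resolve_activity_conflicts(ActivityTable(raw)).records
        assert out.loc[0, "label"] == "inactive"
        assert not bool(out.loc[0, "had_conflict"])

    def test_agreeing_duplicates_counted_not_flipped(self):
        raw = activity_frame([("c3", "TR", "inactive", 1), ("c3", "TR", "inactive", 1)])
        out = resolve_activity_conflicts(ActivityTable(raw)).records
        assert len(out) == 1
        assert out.loc[0, "label"] == "inactive"
        assert out.loc[0, "n_sources"] == 2

    def test_endpoints_resolved_independently(self):
        raw = activity_frame(
            [("c1", "ER", "inactive", 1), ("c1", "AR", "active", 1), ("c1", "ER", "active", 1)]
        )
        out = resolve_activity_conflicts(ActivityTable(raw)).records
        by = out.set_index("endpoint")["label"]
        assert by["ER"] == "active" and by["AR"] == "active"
        assert len(out) == 2

    def test_idempotent(self):
        raw = activity_frame(
            [("c1", "ER", "active", 1), ("c1", "ER", "inactive", 1), ("c2", "ER", "inactive", 1)]
        )
        once = resolve_activity_conflicts(ActivityTable(raw))
        twice = resolve_activity_conflicts(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_invalid_label_rejected(self):
        raw = activity_frame([("c1", "ER", "maybe", 1)])
        with pytest.raises(ValueError, match="label"):
            resolve_activity_conflicts(raw)


class TestDedupeProfilesByTas:
    def test_highest_tas_retained(self):
        m = signature([("c1", 0.2, 1.0, 2.0, 3.0), ("c1", 0.9, 4.0, 5.0, 6.0)])
        out = dedupe_profiles_by_tas(m)
        assert out.n_profiles == 1
        assert out.data.loc[0, "tas"] == 0.9
        assert out.data.loc[0, "L:G0001"] == 4.0

    def test_no_duplicates_identity(self):
        m = signature([("c1", 0.5, 1, 2, 3), ("c2", 0.7, 4, 5, 6)])
        pd.testing.assert_frame_equal(dedupe_profiles_by_tas(m).data, m.data)

    def test_tie_keeps_first_in_input_order(self):
        m = signature([("c1", 0.5, 1, 2, 3), ("c1", 0.5, 9, 9, 9)])
        out = dedupe_profiles_by_tas(m)
        assert out.data.loc[0, "L:G0001"] == 1

    def test_missing_tas_on_duplicate_rejected(self):
        m = signature([("c1", np.nan, 1, 2, 3), ("c1", 0.5, 9, 9, 9)])
        with pytest.raises(ValueError, match="TAS"):
            dedupe_profiles_by_tas(m)

    def test_idempotent(self):
        m = signature([("c1", 0.2, 1, 2, 3), ("c1", 0.9, 4, 5, 6), ("c2", 0.3, 7, 8, 9)])
        once = dedupe_profiles_by_tas(m)
        pd.testing.assert_frame_equal(dedupe_profiles_by_tas(once).data, once.data)


class TestFilterGeneTier:
    def test_full_scale_tier_counts(self, rng):
        # 978 landmark + 9196 best inferred + 2154 inferred, as in L1000
        genes = (
            [f"L:G{i:05d}" for i in range(978)]
            + [f"B:G{i:05d}" for i in range(978, 978 + 9196)]
            + [f"I:G{i:05d}" for i in range(10174, 12328)]
        )
        data = pd.DataFrame(
            np.zeros((2, len(genes))), columns=genes
        )
        data.insert(0, "tas", 0.5)
        data.insert(0, "cell_line", "MCF7")
        data.insert(0, "chemical_id", ["c1", "c2"])
        m = SignatureMatrix(data)
        assert len(filter_gene_tier(m, {"landmark"}).gene_columns) == 978
        assert len(filter_gene_tier(m, {"landmark", "best_inferred"}).gene_columns) == 10174
        assert len(filter_gene_tier(m, {"landmark", "best_inferred", "inferred"}).gene_columns) == 12328

    def test_all_tiers_is_identity(self):
        m = signature([("c1", 0.5, 1, 2, 3)])
        out = filter_gene_tier(m, {"landmark", "best_inferred", "inferred"})
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_column_order_preserved(self):
        m = signature([("c1", 0.5, 1, 2, 3, 4)], genes=("L:G1", "B:G2", "L:G3", "I:G4"))
        out = filter_gene_tier(m, {"landmark"})
        assert out.gene_columns == ["L:G1", "L:G3"]

    def test_empty_keep_rejected(self):
        m = signature([("c1", 0.5, 1, 2, 3)])
        with pytest.raises(ValueError, match="tier"):
            filter_gene_tier(m, set())


class TestMakeSplit:
    @staticmethod
    def _cohort(n_a, n_b, n_common, seed=0):
        """Two cell lines with a controlled chemical-id intersection."""
        common = [f"c{i}" for i in range(n_common)]
        only_a = [f"a{i}" for i in range(n_a - n_common)]
        only_b = [f"b{i}" for i in range(n_b - n_common)]
        def mat(ids, cl):
            return signature([(c, 0.5, 0.0, 0.0, 0.0) for c in ids], cell_line=cl)
        matrices = {"MCF7": mat(common + only_a, "MCF7"), "A549": mat(common + only_b, "A549")}
        act = ActivityTable(
            activity_frame([(c, "ER", "inactive", 1) for c in common + only_a + only_b])
        )
        return matrices, act

    def test_er_like_training_counts(self):
        # 1552- and 1262-chemical cell lines sharing 1259; 291 validation
        matrices, act = self._cohort(1552, 1262, 1259)
        split = make_split(matrices, act, n_validation=291, seed=4)
        assert len(split.validation) == 291
        assert len(split.training["MCF7"]) == 1261
        assert len(split.training["A549"]) == 971

    def test_zero_validation(self):
        matrices, act = self._cohort(30, 25, 20)
        split = make_split(matrices, act, n_validation=0, seed=1)
        assert split.validation == []
        assert len(split.training["MCF7"]) == 30

    def test_validation_disjoint_from_all_training(self):
        matrices, act = self._cohort(50, 40, 35)
        split = make_split(matrices, act, n_validation=10, seed=2)
        val = set(split.validation)
        for ids in split.training.values():
            assert not val & set(ids)

    def test_counts_round_trip(self):
        matrices, act = self._cohort(50, 40, 35)
        split = make_split(matrices, act, n_validation=10, seed=2)
        for cl, m in matrices.items():
            assert len(split.training[cl]) + len(split.validation) == m.n_profiles

    def test_reproducible_and_seed_sensitive(self):
        matrices, act = self._cohort(50, 40, 35)
        s1 = make_split(matrices, act, 10, seed=2)
        s2 = make_split(matrices, act, 10, seed=2)
        s3 = make_split(matrices, act, 10, seed=3)
        assert s1.validation == s2.validation
        assert s1.validation != s3.validation

    def test_oversized_validation_rejected(self):
        matrices, act = self._cohort(30, 25, 20)
        with pytest.raises(ValueError, match="exceeds"):
            make_split(matrices, act, n_validation=21, seed=0)
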