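import pandas as pd
import pytest

from ctipairs.errors import DataError
from ctipairs.mechanism import (
    RELATION_WHITELIST,
    assign_dti,
    assign_dti_classes,
    build_expansion_map,
    expand_targets,
    merge_mechanism_pairs,
)


def relations_frame(rows):
    """rows: (tid, target_type, relationship, related_tid, related_type)"""
    return pd.DataFrame(
        [
            {
                "tid": r[0],
                "target_type": r[1],
                "relationship": r[2],
                "related_tid": r[3],
                "related_type": r[4],
            }
            for r in rows
        ]
    )


def pairs_frame(keys, **extra):
    frame = pd.DataFrame(keys, columns=["parent_molregno", "tid"])
    frame["pchembl_value_max_BF"] = extra.get("pchembl", 7.0)
    return frame


class TestExpansion:
    def test_family_superset_of_members(self):
        relations = relations_frame(
            [
                (300, "PROTEIN FAMILY", "SUPERSET OF", 200, "SINGLE PROTEIN"),
                (300, "PROTEIN FAMILY", "SUPERSET OF", 201, "SINGLE PROTEIN"),
            ]
        )
        expansion = build_expansion_map(relations)
        assert expand_targets(300, expansion) == {300, 200, 201}

    def test_no_relations_identity(self):
        assert expand_targets(200, {}) == {200}

    def test_subset_of_not_followed(self):
        relations = relations_frame(
            [(200, "SINGLE PROTEIN", "SUBSET OF", 300, "PROTEIN FAMILY")]
        )
        expansion = build_expansion_map(relations)
        assert expand_targets(200, expansion) == {200}

    def test_whitelist_has_exactly_six_triples(self):
        assert len(RELATION_WHITELIST) == 6
        assert all(related == "SINGLE PROTEIN" for _, _, related in RELATION_WHITELIST)

    @pytest.mark.parametrize(
        "source_type",
        [
            "PROTEIN FAMILY",
            "PROTEIN COMPLEX",
            "PROTEIN COMPLEX GROUP",
            "CHIMERIC PROTEIN",
            "PROTEIN-PROTEIN INTERACTION",
        ],
    )
    def test_superset_sources_admissible(self, source_type):
        relations = relations_frame(
            [(300, source_type, "SUPERSET OF", 200, "SINGLE PROTEIN")]
        )
        assert expand_targets(300, build_expansion_map(relations)) == {300, 200}

    def test_equivalent_single_proteins_admissible(self):
        relations = relations_frame(
            [(200, "SINGLE PROTEIN", "EQUIVALENT TO", 201, "SINGLE PROTEIN")]
        )
        assert expand_targets(200, build_expansion_map(relations)) == {200, 201}

    def test_non_whitelisted_triples_ignored(self):
        relations = relations_frame(
            [
                (300, "PROTEIN FAMILY", "SUPERSET OF", 301, "PROTEIN FAMILY"),
                (300, "PROTEIN FAMILY", "OVERLAPS WITH", 200, "SINGLE PROTEIN"),
                (300, "SINGLE PROTEIN", "SUPERSET OF", 200, "SINGLE PROTEIN"),
            ]
        )
        assert expand_targets(300, build_expansion_map(relations)) == {300}

    def test_expansion_is_single_hop(self):
        relations = relations_frame(
            [
                (300, "PROTEIN FAMILY", "SUPERSET OF", 200, "SINGLE PROTEIN"),
                (200, "SINGLE PROTEIN", "EQUIVALENT TO", 201, "SINGLE PROTEIN"),
            ]
        )
        expansion = build_expansion_map(relations)
        assert expand_targets(300, expansion) == {300, 200}


class TestMechanismMerge:
    def mechanisms(self, rows):
        return pd.DataFrame(
            [
                {"molregno": m, "tid": t, "disease_efficacy": e, "max_phase": None}
                for m, t, e in rows
            ]
        )

    def test_existing_pair_flagged_no_new_row(self):
        pairs = pairs_frame([(100, 200)])
        merged, _ = merge_mechanism_pairs(
            pairs, self.mechanisms([(100, 200, 1)]), {}, {}
        )
        assert len(merged) == 1
        assert bool(merged["in_dm_table"].iloc[0])

    def test_unmeasured_pair_appended_without_pchembl(self):
        pairs = pairs_frame([(100, 200)])
        merged, _ = merge_mechanism_pairs(
            pairs, self.mechanisms([(101, 201, 1)]), {}, {}
        )
        assert len(merged) == 2
        appended = merged[merged["parent_molregno"] == 101].iloc[0]
        assert bool(appended["in_dm_table"])
        assert pd.isna(appended["pchembl_value_max_BF"])

    def test_disease_efficacy_zero_ignored(self):
        pairs = pairs_frame([(100, 200)])
        merged, therapeutic = merge_mechanism_pairs(
            pairs, self.mechanisms([(100, 200, 0)]), {}, {}
        )
        assert not merged["in_dm_table"].any()
        assert therapeutic == set()

    def test_expanded_merge_flags_and_appends(self):
        pairs = pairs_frame([(100, 200)])  # (C, P1) measured
        expansion = {300: {200}}  # F superset-of P1
        merged, therapeutic = merge_mechanism_pairs(
            pairs, self.mechanisms([(100, 300, 1)]), expansion, {}
        )
        assert therapeutic == {200, 300}
        by_key = merged.set_index(["parent_molregno", "tid"])["in_dm_table"]
        assert bool(by_key.loc[(100, 200)])
        assert bool(by_key.loc[(100, 300)])
        assert len(merged) == 2

    def test_mechanism_compound_parent_mapped(self):
        pairs = pairs_frame([(100, 200)])
        merged, _ = merge_mechanism_pairs(
            pairs, self.mechanisms([(1000, 200, 1)]), {}, {1000: 100}
        )
        assert len(merged) == 1
        assert bool(merged["in_dm_table"].iloc[0])


class TestDTIAssignment:
    @pytest.mark.parametrize(
        "in_dm,phase,therapeutic,expected",
        [
            (True, 4, False, "D_DT"),
            (True, 3, False, "C3_DT"),
            (True, 2, False, "C2_DT"),
            (True, 1, False, "C1_DT"),
            (True, 0.5, False, "C0_DT"),
            (True, -1, False, "C0_DT"),
            (True, None, False, "C0_DT"),
            (False, 4, True, "DT"),
            (False, None, False, "NDT"),
        ],
    )
    def test_table_rows_current_release(self, in_dm, phase, therapeutic, expected):
        assert assign_dti(in_dm, phase, therapeutic, release=32) == expected

    def test_unknown_release_uses_current_coding(self):
        assert assign_dti(True, 0.5, False, release=None) == "C0_DT"

    def test_legacy_release_phase_zero(self):
        assert assign_dti(True, 0, False, release=31) == "C0_DT"

    def test_legacy_release_rejects_half_phase(self):
        with pytest.raises(DataError, match="0.5"):
            assign_dti(True, 0.5, False, release=31)

    def test_current_release_rejects_phase_zero(self):
        with pytest.raises(DataError, match="0"):
            assign_dti(True, 0, False, release=32)

    def test_drug_elsewhere_is_dt_not_d_dt(self):
        # phase-4 compound measured on a therapeutic target without a
        # curated mechanism there stays a comparator
        assert assign_dti(False, 4, True, release=32) == "DT"

    def test_ndt_rows_dropped(self):
        pairs = pairs_frame([(100, 200), (101, 201)])
        pairs["in_dm_table"] = [True, False]
        out = assign_dti_classes(pairs, {100: 4.0}, therapeutic_targets=set(), release=32)
        assert len(out) == 1
        assert out["DTI"].iloc[0] == "D_DT"
        assert not (out["DTI"] == "NDT").any()

    def test_partition_single_class_per_pair(self):
        pairs = pairs_frame([(100, 200), (101, 200), (102, 201)])
        pairs["in_dm_table"] = [True, False, False]
        out = assign_dti_classes(
            pairs, {100: 2.0}, therapeutic_targets={200}, release=32
        )
        assert out.set_index("parent_molregno")["DTI"].to_dict() == {
            100: "C2_DT",
            101: "DT",
        }
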