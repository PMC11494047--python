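import pandas as pd
import pytest

from ctipairs.annotate import (
    aromatic_atom_counts,
    attach_structures_and_filter,
    attach_target_classes,
    compute_ligand_efficiencies,
    compute_toolkit_descriptors,
    concat_atc,
)
from ctipairs.fixtures import MIXTURE_SMILES_POOL, SMILES_POOL


def structures_frame(rows):
    return pd.DataFrame(
        [
            {
                "molregno": m,
                "canonical_smiles": s,
                "standard_inchi": f"I{m}",
                "standard_inchi_key": f"K{m}",
            }
            for m, s in rows
        ]
    )


def pairs_frame(parents):
    return pd.DataFrame({"parent_molregno": parents, "tid": [200] * len(parents)})


class TestStructureFilter:
    def test_plain_smiles_retained(self):
        kept, report = attach_structures_and_filter(
            pairs_frame([100]), structures_frame([(100, "CCO")])
        )
        assert len(kept) == 1
        assert report == {"missing_smiles": 0, "mixture_smiles": 0}

    def test_mixture_removed(self):
        kept, report = attach_structures_and_filter(
            pairs_frame([100]), structures_frame([(100, "CC(=O)[O-].[Na+]")])
        )
        assert len(kept) == 0
        assert report["mixture_smiles"] == 1

    def test_three_structureless_compounds_counted(self):
        kept, report = attach_structures_and_filter(
            pairs_frame([100, 101, 102, 103]), structures_frame([(103, "CCO")])
        )
        assert len(kept) == 1
        assert report["missing_smiles"] == 3

    def test_no_retained_smiles_contains_full_stop(self):
        rows = [(100 + i, s) for i, s in enumerate(SMILES_POOL + MIXTURE_SMILES_POOL)]
        kept, _ = attach_structures_and_filter(
            pairs_frame([m for m, _ in rows]), structures_frame(rows)
        )
        assert not kept["canonical_smiles"].str.contains(".", regex=False).any()


class TestLigandEfficiencies:
    def base(self, **overrides):
        row = {
            "pchembl_value_max_BF": 9.0,
            "pchembl_value_max_B": None,
            "heavy_atoms": 30.0,
            "mw_freebase": 450.0,
            "psa": 100.0,
            "alogp": 3.0,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_worked_example(self):
        out = compute_ligand_efficiencies(self.base()).iloc[0]
        assert out["LE_BF"] == pytest.approx(1.37 * 9.0 / 30.0)  # 0.411
        assert out["BEI_BF"] == pytest.approx(20.0)
        assert out["SEI_BF"] == pytest.approx(9.0)
        assert out["LLE_BF"] == pytest.approx(6.0)

    def test_absent_pchembl_gives_absent_metrics(self):
        out = compute_ligand_efficiencies(self.base(pchembl_value_max_BF=None)).iloc[0]
        for metric in ("LE_BF", "BEI_BF", "SEI_BF", "LLE_BF"):
            assert pd.isna(out[metric])

    def test_zero_denominator_gives_absent(self):
        out = compute_ligand_efficiencies(self.base(heavy_atoms=0.0, psa=0.0)).iloc[0]
        assert pd.isna(out["LE_BF"])
        assert pd.isna(out["SEI_BF"])
        assert out["BEI_BF"] == pytest.approx(20.0)

    def test_domains_independent(self):
        out = compute_ligand_efficiencies(self.base(pchembl_value_max_B=6.0)).iloc[0]
        assert out["LLE_B"] == pytest.approx(3.0)
        assert out["LLE_BF"] == pytest.approx(6.0)

    def test_no_partial_rows(self):
        frame = self.base(alogp=None)
        out = compute_ligand_efficiencies(frame).iloc[0]
        assert pd.isna(out["LLE_BF"])
        assert not pd.isna(out["LE_BF"])


class TestAtc:
    def test_sorted_join(self):
        assert concat_atc(["N", "C"]) == "C|N"

    def test_singleton(self):
        assert concat_atc(["L"]) == "L"

    def test_dedupe(self):
        assert concat_atc(["N", "N"]) == "N"

    def test_empty_absent(self):
        assert concat_atc([]) is None


class TestTargetClasses:
    def class_rows(self, rows):
        return pd.DataFrame(rows, columns=["tid", "level1", "level2"])

    def test_single_assignment(self):
        pairs = pairs_frame([100])
        out, report = attach_target_classes(
            pairs, self.class_rows([(200, "Enzyme", "Kinase")])
        )
        assert out["tclass_level1"].iloc[0] == "Enzyme"
        assert out["tclass_level2"].iloc[0] == "Kinase"
        assert len(report) == 0

    def test_multi_level1_concatenated_and_reported(self):
        out, report = attach_target_classes(
            pairs_frame([100]),
            self.class_rows(
                [(200, "Epigenetic regulator", None), (200, "Enzyme", "Kinase")]
            ),
        )
        assert out["tclass_level1"].iloc[0] == "Enzyme|Epigenetic regulator"
        assert list(report["tid"]) == [200]

    def test_unclassified_absent_not_reported(self):
        out, report = attach_target_classes(pairs_frame([100]), self.class_rows([]))
        assert pd.isna(out["tclass_level1"].iloc[0])
        assert pd.isna(out["tclass_level2"].iloc[0])
        assert len(report) == 0

    def test_report_limited_to_dataset_targets(self):
        out, report = attach_target_classes(
            pairs_frame([100]),
            self.class_rows(
                [(999, "Enzyme", None), (999, "Ion channel", None)]
            ),
        )
        assert len(report) == 0


class TestToolkitDescriptors:
    @pytest.mark.parametrize(
        "smiles,total,carbon,nitrogen,hetero",
        [
            ("c1ccccc1", 6, 6, 0, 0),   # benzene
            ("c1ccncc1", 6, 5, 1, 1),   # pyridine
            ("c1ccoc1", 5, 4, 0, 1),    # furan
        ],
    )
    def test_aromatic_worked_examples(self, smiles, total, carbon, nitrogen, hetero):
        values = compute_toolkit_descriptors(smiles)
        assert values["n_aromatic_atoms"] == total
        assert values["n_aromatic_c"] == carbon
        assert values["n_aromatic_n"] == nitrogen
        assert values["n_aromatic_hetero"] == hetero

    @pytest.mark.parametrize("smiles", SMILES_POOL)
    def test_aromatic_identity_holds(self, smiles):
        values = compute_toolkit_descriptors(smiles)
        assert (
            values["n_aromatic_c"] + values["n_aromatic_hetero"]
            == values["n_aromatic_atoms"]
        )
        assert values["n_aromatic_n"] <= values["n_aromatic_hetero"]
        for column, value in values.items():
            if column.startswith("n_"):
                assert value >= 0

    def test_unparseable_smiles_absent(self):
        values = compute_toolkit_descriptors("not_a_smiles((")
        assert all(v is None for v in values.values())

    def test_acyclic_scaffold_empty(self):
        values = compute_toolkit_descriptors("CCCCCC")
        assert values["scaffold_w_stereo"] == ""
        assert values["scaffold_wo_stereo"] == ""

    def test_stereocenter_counted(self):
        values = compute_toolkit_descriptors("C[C@H](N)C(=O)O")
        assert values["n_stereocenters"] == 1

    def test_scaffold_stereo_variants(self):
        values = compute_toolkit_descriptors("CN1CCC[C@H]1c1cccnc1")  # nicotine
        assert "@" in values["scaffold_w_stereo"]
        assert "@" not in values["scaffold_wo_stereo"]

    def test_aromatic_counts_function_direct(self):
        from rdkit import Chem

        counts = aromatic_atom_counts(Chem.MolFromSmiles("c1ccncc1"))
        assert counts == {
            "n_aromatic_atoms": 6,
            "n_aromatic_c": 5,
            "n_aromatic_n": 1,
            "n_aromatic_hetero": 1,
        }
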