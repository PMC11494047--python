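"""Compound and target annotations for assembled pairs.

Adds stored structures and physicochemical properties, ligand-efficiency
metrics derived from the per-domain maximum pChEMBL, ATC level-1 codes,
two-level target classes, and (optionally) RDKit-computed descriptors
including Bemis-Murcko scaffolds and aromatic-atom counts.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import pandas as pd

log = logging.getLogger(__name__)

#: Conversion factor from pChEMBL to binding free energy per heavy atom
#: (kcal/mol at ~300 K): LE = 1.37 * pChEMBL / heavy_atoms.
LE_CONVERSION = 1.37

RDKIT_COUNT_COLUMNS = (
    "n_heteroatoms",
    "n_stereocenters",
    "n_aliphatic_rings",
    "n_aromatic_rings",
    "n_saturated_rings",
    "n_aliphatic_carbocycles",
    "n_aromatic_carbocycles",
    "n_saturated_carbocycles",
    "n_aliphatic_heterocycles",
    "n_aromatic_heterocycles",
    "n_saturated_heterocycles",
    "n_aromatic_atoms",
    "n_aromatic_c",
    "n_aromatic_n",
    "n_aromatic_hetero",
)

RDKIT_COLUMNS = (
    ("fraction_csp3",)
    + RDKIT_COUNT_COLUMNS
    + ("scaffold_w_stereo", "scaffold_wo_stereo")
)


def attach_structures_and_filter(
    pairs: pd.DataFrame, structures: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join stored structures and drop compounds without a usable SMILES.

    Compounds with no SMILES at all and compounds whose SMILES contains a
    full stop (mixtures, salts kept as multi-component records) are removed
    together with all their pairs.  The report counts removed *compounds*
    (distinct parents) per reason.
    """
    structures = structures.rename(columns={"molregno": "parent_molregno"})
    merged = pairs.merge(structures, on="parent_molregno", how="left")
    no_smiles = merged["canonical_smiles"].isna()
    mixture = merged["canonical_smiles"].fillna("").str.contains(".", regex=False)
    report = {
        "missing_smiles": int(merged.loc[no_smiles, "parent_molregno"].nunique()),
        "mixture_smiles": int(merged.loc[mixture, "parent_molregno"].nunique()),
    }
    kept = merged[~(no_smiles | mixture)].reset_index(drop=True)
    return kept, report


def _safe_ratio(numerator: pd.Series, denominator: pd.Series) -> pd.Series:
    denom = denominator.where(denominator > 0)
    return numerator / denom


def compute_ligand_efficiencies(pairs: pd.DataFrame) -> pd.DataFrame:
    """LE/BEI/SEI/LLE per domain from the domain's maximum pChEMBL.

    LE = 1.37 * pChEMBL / heavy atoms, BEI = pChEMBL / MW in kDa,
    SEI = pChEMBL / (PSA / 100 A^2), LLE = pChEMBL - calculated logP.
    Any missing operand or non-positive denominator leaves the metric absent.
    """
    out = pairs.copy()
    for domain in ("BF", "B"):
        p = out[f"pchembl_value_max_{domain}"]
        out[f"LE_{domain}"] = LE_CONVERSION * _safe_ratio(p, out["heavy_atoms"])
        out[f"BEI_{domain}"] = _safe_ratio(p * 1000.0, out["mw_freebase"])
        out[f"SEI_{domain}"] = _safe_ratio(p, out["psa"] / 100.0)
        out[f"LLE_{domain}"] = p - out["alogp"]
    return out


def concat_atc(codes) -> str | None:
    """Distinct level-1 ATC codes, sorted alphabetically, '|'-joined."""
    distinct = sorted({c for c in codes if c is not None and not pd.isna(c)})
    return "|".join(distinct) if distinct else None


def atc_by_compound(atc: pd.DataFrame) -> pd.Series:
    """molregno -> concatenated level-1 descriptor."""
    return atc.groupby("molregno")["level1"].apply(concat_atc)


def attach_target_classes(
    pairs: pd.DataFrame, class_rows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach per-target class labels and report multi-class targets.

    Labels at each level are deduplicated, sorted alphabetically and joined
    with '|'.  Targets present in the dataset with more than one label at
    either level are returned in the report table.
    """

    def join_labels(values) -> str | None:
        labels = sorted({v for v in values if v is not None and not pd.isna(v)})
        return "|".join(labels) if labels else None

    def count_labels(values) -> int:
        return len({v for v in values if v is not None and not pd.isna(v)})

    per_target = class_rows.groupby("tid").agg(
        tclass_level1=("level1", join_labels),
        tclass_level2=("level2", join_labels),
        _n1=("level1", count_labels),
        _n2=("level2", count_labels),
    )
    out = pairs.merge(
        per_target[["tclass_level1", "tclass_level2"]],
        left_on="tid",
        right_index=True,
        how="left",
    )
    in_dataset = per_target.index.isin(set(pairs["tid"].astype(int)))
    multi = per_target[in_dataset & ((per_target["_n1"] > 1) | (per_target["_n2"] > 1))]
    report = (
        multi[["tclass_level1", "tclass_level2"]]
        .reset_index()
        .sort_values("tid", ignore_index=True)
    )
    return out, report


def aromatic_atom_counts(mol) -> dict[str, int]:
    """Total, carbon, nitrogen and hetero aromatic-atom counts.

    Counts atoms flagged aromatic under RDKit's default aromaticity
    perception; hetero = aromatic and not carbon, so carbon + hetero equals
    the total by construction.
    """
    total = carbon = nitrogen = 0
    for atom in mol.GetAtoms():
        if not atom.GetIsAromatic():
            continue
        total += 1
        symbol = atom.GetSymbol()
        if symbol == "C":
            carbon += 1
        elif symbol == "N":
            nitrogen += 1
    return {
        "n_aromatic_atoms": total,
        "n_aromatic_c": carbon,
        "n_aromatic_n": nitrogen,
        "n_aromatic_hetero": total - carbon,
    }


def compute_toolkit_descriptors(canonical_smiles: str) -> dict:
    """RDKit descriptors for one compound, or all-absent when unparseable."""
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors
    from rdkit.Chem.Scaffolds import MurckoScaffold

    absent = {column: None for column in RDKIT_COLUMNS}
    if canonical_smiles is None or pd.isna(canonical_smiles):
        return absent
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        log.warning("unparseable SMILES, descriptors absent: %s", canonical_smiles)
        return absent

    chiral_centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    values = {
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "n_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms(mol),
        "n_stereocenters": len(chiral_centers),
        "n_aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings(mol),
        "n_aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "n_saturated_rings": rdMolDescriptors.CalcNumSaturatedRings(mol),
        "n_aliphatic_carbocycles": rdMolDescriptors.CalcNumAliphaticCarbocycles(mol),
        "n_aromatic_carbocycles": rdMolDescriptors.CalcNumAromaticCarbocycles(mol),
        "n_saturated_carbocycles": rdMolDescriptors.CalcNumSaturatedCarbocycles(mol),
        "n_aliphatic_heterocycles": rdMolDescriptors.CalcNumAliphaticHeterocycles(mol),
        "n_aromatic_heterocycles": rdMolDescriptors.CalcNumAromaticHeterocycles(mol),
        "n_saturated_heterocycles": rdMolDescriptors.CalcNumSaturatedHeterocycles(mol),
    }
    values.update(aromatic_atom_counts(mol))

    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    values["scaffold_w_stereo"] = Chem.MolToSmiles(scaffold)
    scaffold_flat = Chem.Mol(scaffold)
    Chem.RemoveStereochemistry(scaffold_flat)
    values["scaffold_wo_stereo"] = Chem.MolToSmiles(scaffold_flat)
    return values


def attach_toolkit_descriptors(pairs: pd.DataFrame) -> pd.DataFrame:
    """Compute descriptors once per distinct SMILES and broadcast to pairs."""
    unique_smiles = pairs["canonical_smiles"].dropna().unique()
    per_smiles = {s: compute_toolkit_descriptors(s) for s in unique_smiles}
    out = pairs.copy()
    for column in RDKIT_COLUMNS:
        out[column] = [
            per_smiles.get(s, {}).get(column) if not pd.isna(s) else None
            for s in out["canonical_smiles"]
        ]
    return out


def attach_compound_columns(
    pairs: pd.DataFrame,
    properties: pd.DataFrame,
    dictionary: pd.DataFrame,
    atc: pd.DataFrame,
    first_years: Mapping[int, float] | pd.Series,
) -> pd.DataFrame:
    """Merge property-table columns, compound ids, ATC and first-pub year."""
    out = pairs.merge(
        properties.rename(columns={"molregno": "parent_molregno"}),
        on="parent_molregno",
        how="left",
    )
    out = out.merge(
        dictionary.rename(
            columns={"molregno": "parent_molregno", "chembl_id": "parent_chembl_id"}
        )[["parent_molregno", "parent_chembl_id"]],
        on="parent_molregno",
        how="left",
    )
    atc_series = atc_by_compound(atc) if len(atc) else pd.Series(dtype=object)
    out["atc_level1"] = out["parent_molregno"].map(atc_series)
    first = pd.Series(first_years, dtype=float)
    out["first_publication_cpd"] = out["parent_molregno"].map(first)
    return out
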