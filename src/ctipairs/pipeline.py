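"""End-to-end orchestration: store -> annotated, validated pair table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ctipairs import annotate, assembly, cleaning, mechanism, reader, subsets
from ctipairs.reader import PROPERTY_COLUMNS, SourceFilter, StoreHandle

log = logging.getLogger(__name__)

#: Identity and annotation columns in output order (aggregates in between).
_LEADING_COLUMNS = ("parent_molregno", "parent_chembl_id", "tid", "target_chembl_id")


@dataclass(frozen=True)
class PipelineConfig:
    literature_only: bool = True
    calculate_rdkit: bool = False
    compound_threshold: int = subsets.DEFAULT_COMPOUND_THRESHOLD


@dataclass
class PipelineResult:
    dataset: pd.DataFrame
    variants: pd.DataFrame
    stats: pd.DataFrame
    multiclass_report: pd.DataFrame
    removal_report: dict[str, int]
    expected_missing: dict[str, int]
    validation: "cleaning.ValidationReport"
    row_counts: dict[str, int] = field(default_factory=dict)


def _smiles_parse_status(smiles_values) -> dict[str, tuple[bool, bool]]:
    """Distinct SMILES -> (parseable, has_ring); for missing-count expectations."""
    from rdkit import Chem
    from rdkit.rdBase import BlockLogs

    status: dict[str, tuple[bool, bool]] = {}
    with BlockLogs():
        for smiles in smiles_values:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                status[smiles] = (False, False)
            else:
                status[smiles] = (True, mol.GetRingInfo().NumRings() > 0)
    return status


def expected_missing_counts(
    dataset: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    class_rows: pd.DataFrame,
    include_rdkit: bool,
) -> dict[str, int]:
    """Expected per-column missing counts derived from the source tables.

    For each annotation column the number of missing values in the final
    dataset is predicted from the availability of the underlying table rows
    (property columns, structures, ATC, target classes) or from the joint
    availability of operands (ligand-efficiency metrics, RDKit descriptors).
    """
    parents = dataset["parent_molregno"]
    expected: dict[str, int] = {}

    props = tables["properties"].set_index("molregno")
    for column in PROPERTY_COLUMNS:
        expected[column] = int(parents.map(props[column]).isna().sum())

    structures = tables["structures"].set_index("molregno")
    for column in ("standard_inchi", "standard_inchi_key"):
        expected[column] = int(parents.map(structures[column]).isna().sum())
    expected["canonical_smiles"] = 0  # compounds without SMILES are removed

    atc_parents = set(tables["atc"]["molregno"].astype(int))
    expected["atc_level1"] = int((~parents.isin(atc_parents)).sum())

    tids = dataset["tid"]
    l1_targets = set(class_rows.loc[class_rows["level1"].notna(), "tid"].astype(int))
    l2_targets = set(class_rows.loc[class_rows["level2"].notna(), "tid"].astype(int))
    expected["tclass_level1"] = int((~tids.isin(l1_targets)).sum())
    expected["tclass_level2"] = int((~tids.isin(l2_targets)).sum())

    heavy = parents.map(props["heavy_atoms"])
    mw = parents.map(props["mw_freebase"])
    psa = parents.map(props["psa"])
    alogp = parents.map(props["alogp"])
    for domain in ("BF", "B"):
        p = dataset[f"pchembl_value_max_{domain}"]
        expected[f"LE_{domain}"] = int((p.isna() | heavy.isna() | ~(heavy > 0)).sum())
        expected[f"BEI_{domain}"] = int((p.isna() | mw.isna() | ~(mw > 0)).sum())
        expected[f"SEI_{domain}"] = int((p.isna() | psa.isna() | ~(psa > 0)).sum())
        expected[f"LLE_{domain}"] = int((p.isna() | alogp.isna()).sum())

    if include_rdkit:
        status = _smiles_parse_status(dataset["canonical_smiles"].dropna().unique())
        parseable = dataset["canonical_smiles"].map(
            lambda s: status.get(s, (False, False))[0] if pd.notna(s) else False
        )
        has_ring = dataset["canonical_smiles"].map(
            lambda s: status.get(s, (False, False))[1] if pd.notna(s) else False
        )
        n_unparseable = int((~parseable).sum())
        for column in ("fraction_csp3", *annotate.RDKIT_COUNT_COLUMNS):
            expected[column] = n_unparseable
        # acyclic molecules have an empty scaffold, which cleans to missing
        n_acyclic = int((parseable & ~has_ring).sum())
        expected["scaffold_w_stereo"] = n_unparseable + n_acyclic
        expected["scaffold_wo_stereo"] = n_unparseable + n_acyclic

    return expected


def _order_columns(dataset: pd.DataFrame) -> pd.DataFrame:
    ordered = [c for c in _LEADING_COLUMNS if c in dataset.columns]
    ordered += [c for c in dataset.columns if c not in ordered]
    return dataset[ordered]


def run_pipeline(handle: StoreHandle, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full extraction on an open store handle.

    Stages: activity extraction, parent mapping and aggregation, curated
    mechanism merge and DTI assignment, compound/target annotation, cleaning
    and validation, subset flags and statistics.  Returns the cleaned
    dataset plus all reports; nothing is written to disk here.
    """
    row_counts: dict[str, int] = {}

    tables = reader.fetch_compound_tables(handle)
    parent_map = assembly.build_parent_map(tables["hierarchy"])

    records = reader.fetch_activity_records(
        handle, SourceFilter(literature_only=config.literature_only)
    )
    row_counts["activity_records"] = len(records)
    log.info("qualifying activity records: %d", len(records))

    pairs = assembly.aggregate_pairs(records, parent_map)
    variants = assembly.variant_pairs(records, parent_map)
    first_years = assembly.compound_first_years(records, parent_map)
    row_counts["measured_pairs"] = len(pairs)
    log.info("measured compound-target pairs: %d", len(pairs))

    mechanisms = reader.fetch_mechanisms(handle)
    relations = reader.fetch_target_relations(handle)
    expansion = mechanism.build_expansion_map(relations)
    merged, therapeutic_targets = mechanism.merge_mechanism_pairs(
        pairs, mechanisms, expansion, parent_map
    )
    row_counts["pairs_after_mechanism_merge"] = len(merged)

    phase_by_parent = {
        int(r.molregno): (None if pd.isna(r.max_phase) else float(r.max_phase))
        for r in tables["dictionary"].itertuples()
    }
    dataset = mechanism.assign_dti_classes(
        merged, phase_by_parent, therapeutic_targets, release=handle.release
    )
    row_counts["pairs_after_ndt_removal"] = len(dataset)
    log.info("pairs after NDT removal: %d", len(dataset))

    dataset, removal_report = annotate.attach_structures_and_filter(
        dataset, tables["structures"]
    )
    row_counts["pairs_after_structure_filter"] = len(dataset)
    log.info(
        "removed compounds: %d without SMILES, %d mixtures",
        removal_report["missing_smiles"],
        removal_report["mixture_smiles"],
    )

    dataset = annotate.attach_compound_columns(
        dataset, tables["properties"], tables["dictionary"], tables["atc"], first_years
    )
    target_dictionary = reader.fetch_target_dictionary(handle).rename(
        columns={"chembl_id": "target_chembl_id"}
    )
    dataset = dataset.merge(target_dictionary, on="tid", how="left")
    class_rows = reader.fetch_target_classes(handle)
    dataset, multiclass_report = annotate.attach_target_classes(dataset, class_rows)
    dataset = annotate.compute_ligand_efficiencies(dataset)
    if config.calculate_rdkit:
        dataset = annotate.attach_toolkit_descriptors(dataset)

    expected_missing = expected_missing_counts(
        dataset, tables, class_rows, include_rdkit=config.calculate_rdkit
    )

    dataset = cleaning.normalize_and_round(dataset)
    dataset = subsets.compute_filter_columns(dataset, threshold=config.compound_threshold)
    dataset = _order_columns(dataset)

    validation = cleaning.run_basic_checks(dataset, expected_missing)
    if not validation.overall:
        log.error("basic checks failed:\n%s", validation.summary())

    stats = subsets.compute_stats(dataset, variants)
    row_counts["final_pairs"] = len(dataset)

    return PipelineResult(
        dataset=dataset,
        variants=variants,
        stats=stats,
        multiclass_report=multiclass_report,
        removal_report=removal_report,
        expected_missing=expected_missing,
        validation=validation,
        row_counts=row_counts,
    )
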