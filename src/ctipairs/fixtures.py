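"""Miniature ChEMBL-schema stores for testing without downloads.

`build_fixture` renders a :class:`FixtureSpec` into a deterministic SQLite
file covering exactly the tables the pipeline reads.  `edge_case_suite`
returns hand-crafted stores for boundary behaviour.  The matching
brute-force ground truth lives in :mod:`ctipairs.oracle`, which shares no
logic with the pipeline modules.
"""

from __future__ import annotations

import random
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

#: Column order per table; inserts follow these positions.
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "ACTIVITIES": (
        "activity_id",
        "assay_id",
        "molregno",
        "doc_id",
        "pchembl_value",
        "potential_duplicate",
        "data_validity_comment",
        "src_id",
    ),
    "ASSAYS": ("assay_id", "tid", "assay_type", "variant_id"),
    "DOCS": ("doc_id", "year"),
    "MOLECULE_HIERARCHY": ("molregno", "parent_molregno"),
    "MOLECULE_DICTIONARY": ("molregno", "chembl_id", "max_phase"),
    "DRUG_MECHANISM": ("mec_id", "molregno", "tid", "disease_efficacy"),
    "TARGET_RELATIONS": ("tid", "relationship", "related_tid"),
    "TARGET_DICTIONARY": ("tid", "chembl_id", "pref_name", "target_type"),
    "COMPOUND_PROPERTIES": (
        "molregno",
        "mw_freebase",
        "alogp",
        "hba",
        "hbd",
        "psa",
        "rtb",
        "num_ro5_violations",
        "heavy_atoms",
        "qed_weighted",
        "aromatic_rings",
    ),
    "COMPOUND_STRUCTURES": (
        "molregno",
        "canonical_smiles",
        "standard_inchi",
        "standard_inchi_key",
    ),
    "MOLECULE_ATC_CLASSIFICATION": ("molregno", "level5"),
    "PROTEIN_CLASSIFICATION": (
        "protein_class_id",
        "parent_id",
        "pref_name",
        "class_level",
    ),
    "TARGET_COMPONENTS": ("tid", "component_id"),
    "COMPONENT_CLASS": ("component_id", "protein_class_id"),
}

#: Parseable single-component SMILES to draw compound structures from.
SMILES_POOL = (
    "CCO",
    "c1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "C[C@H](N)C(=O)O",
    "CN1CCC[C@H]1c1cccnc1",
    "CC(=O)Nc1ccc(O)cc1",
    "CCCCCC",
    "CC(C)(C)O",
    "O=C(O)c1ccccc1O",
)

#: Multi-component SMILES (contain '.') for the mixture-removal path.
MIXTURE_SMILES_POOL = ("CC(=O)[O-].[Na+]", "Cl.NCCc1ccccc1")

#: Two-level protein classification tree used by all fixtures.
PROTEIN_CLASS_TREE = (
    (1, None, "Protein class", 0),
    (2, 1, "Enzyme", 1),
    (3, 1, "Membrane receptor", 1),
    (4, 1, "Ion channel", 1),
    (5, 1, "Epigenetic regulator", 1),
    (6, 2, "Kinase", 2),
    (7, 2, "Protease", 2),
    (8, 3, "Family A G protein-coupled receptor", 2),
    (9, 4, "Voltage-gated ion channel", 2),
)

_LEAF_CLASS_IDS = (6, 7, 8, 9, 2, 3, 4, 5)

_ATC_LEVEL5_POOL = (
    "N02BE01",
    "C07AB02",
    "L01XE07",
    "A10BA02",
    "J01CA04",
    "N05BA01",
)


class FixtureSpecError(ValueError):
    """The spec asks for an impossible store composition."""


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs controlling the composition of a generated store.

    The same spec (including ``seed``) always renders to an identical store
    file.
    """

    seed: int = 0
    n_parents: int = 12
    n_salts_per_parent: int = 1
    n_targets: int = 6
    n_variant_targets: int = 2
    n_families: int = 2
    family_size: int = 2
    activity_density: float = 0.5
    max_records_per_pair: int = 3
    assay_type_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)  # B, F, A
    pchembl_range: tuple[float, float] = (3.0, 11.0)
    fraction_missing_pchembl: float = 0.1
    fraction_duplicate_flag: float = 0.05
    fraction_validity_comment: float = 0.1
    fraction_nonliterature: float = 0.2
    fraction_missing_year: float = 0.1
    year_range: tuple[int, int] = (1995, 2023)
    n_docs: int = 8
    n_mechanism_rows: int = 6
    fraction_disease_efficacy_zero: float = 0.2
    max_phase_choices: tuple = (4, 3, 2, 1, 0.5, -1, None)
    fraction_missing_structure: float = 0.1
    fraction_mixture_smiles: float = 0.1
    fraction_missing_properties: float = 0.1
    fraction_missing_psa: float = 0.1
    atc_fraction: float = 0.4
    n_atc_max: int = 2
    fraction_unclassified_targets: float = 0.15
    fraction_multiclass_targets: float = 0.15
    release: int = 32

    def validate(self) -> None:
        counts = (
            self.n_parents,
            self.n_salts_per_parent,
            self.n_targets,
            self.n_variant_targets,
            self.n_families,
            self.family_size,
            self.n_mechanism_rows,
            self.n_docs,
        )
        if any(c < 0 for c in counts):
            raise FixtureSpecError("all counts must be >= 0")
        n_mech_slots = self.n_parents * (self.n_targets + self.n_families)
        if self.n_mechanism_rows > n_mech_slots:
            raise FixtureSpecError(
                f"n_mechanism_rows={self.n_mechanism_rows} exceeds the "
                f"{n_mech_slots} distinct (compound, target) slots"
            )
        if self.n_variant_targets > self.n_targets:
            raise FixtureSpecError("n_variant_targets exceeds n_targets")
        if self.family_size > self.n_targets and self.n_families > 0:
            raise FixtureSpecError("family_size exceeds n_targets")


def write_store(path: Path | str, tables: dict[str, list[tuple]]) -> Path:
    """Create a SQLite store with the given rows; absent tables are empty."""
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        for table, columns in TABLE_COLUMNS.items():
            conn.execute(f"CREATE TABLE {table} ({', '.join(columns)})")
            rows = tables.get(table, [])
            if rows:
                placeholders = ", ".join("?" for _ in columns)
                conn.executemany(f"INSERT INTO {table} VALUES ({placeholders})", rows)
        conn.commit()
    finally:
        conn.close()
    return path


def _target_class_rows(
    rng: random.Random, tids: list[int], spec: FixtureSpec
) -> tuple[list[tuple], list[tuple]]:
    components, component_classes = [], []
    for tid in tids:
        component_id = 1000 + tid
        components.append((tid, component_id))
        roll = rng.random()
        if roll < spec.fraction_unclassified_targets:
            continue
        if roll < spec.fraction_unclassified_targets + spec.fraction_multiclass_targets:
            for class_id in rng.sample(_LEAF_CLASS_IDS, 2):
                component_classes.append((component_id, class_id))
        else:
            component_classes.append((component_id, rng.choice(_LEAF_CLASS_IDS)))
    return components, component_classes


def generate_tables(spec: FixtureSpec) -> dict[str, list[tuple]]:
    """Render a spec into table rows (deterministic in the seed)."""
    spec.validate()
    rng = random.Random(spec.seed)

    parents = [100 + i for i in range(spec.n_parents)]
    hierarchy = [(p, p) for p in parents]
    salts: dict[int, int] = {}
    for i, parent in enumerate(parents):
        for k in range(spec.n_salts_per_parent):
            salt = 1000 + i * 10 + k
            salts[salt] = parent
            hierarchy.append((salt, parent))
    molecules = parents + sorted(salts)

    dictionary = []
    for m in molecules:
        phase = rng.choice(spec.max_phase_choices) if m in parents else None
        dictionary.append((m, f"CHEMBL{m}", phase))

    single_tids = [200 + j for j in range(spec.n_targets)]
    family_tids = [300 + f for f in range(spec.n_families)]
    target_dictionary = [
        (tid, f"CHEMBL_T{tid}", f"Protein {tid}", "SINGLE PROTEIN")
        for tid in single_tids
    ]
    target_dictionary += [
        (tid, f"CHEMBL_T{tid}", f"Family {tid}", "PROTEIN FAMILY")
        for tid in family_tids
    ]
    relations = []
    for f, tid in enumerate(family_tids):
        members = single_tids[f :: max(spec.n_families, 1)][: spec.family_size]
        for member in members:
            relations.append((tid, "SUPERSET OF", member))
            # inverse direction is deliberately not whitelisted
            relations.append((member, "SUBSET OF", tid))

    variant_tids = set(single_tids[: spec.n_variant_targets])

    docs = []
    for d in range(spec.n_docs):
        year = (
            None
            if rng.random() < spec.fraction_missing_year
            else rng.randint(*spec.year_range)
        )
        docs.append((600 + d, year))

    assays: list[tuple] = []
    assay_ids: dict[tuple[int, str, int | None], int] = {}

    def assay_for(tid: int, assay_type: str, variant_id: int | None) -> int:
        key = (tid, assay_type, variant_id)
        if key not in assay_ids:
            assay_id = 5000 + len(assay_ids)
            assay_ids[key] = assay_id
            assays.append((assay_id, tid, assay_type, variant_id))
        return assay_ids[key]

    activities = []
    activity_id = 1
    comments = (None, None, None, "Manually validated", "Outside typical range")
    for molregno in molecules:
        for tid in single_tids:
            if rng.random() >= spec.activity_density:
                continue
            for _ in range(rng.randint(1, spec.max_records_per_pair)):
                assay_type = rng.choices(
                    ("B", "F", "A"), weights=spec.assay_type_weights
                )[0]
                variant_id = (
                    500 + tid
                    if tid in variant_tids and rng.random() < 0.3
                    else None
                )
                pchembl = (
                    None
                    if rng.random() < spec.fraction_missing_pchembl
                    else round(rng.uniform(*spec.pchembl_range), 2)
                )
                activities.append(
                    (
                        activity_id,
                        assay_for(tid, assay_type, variant_id),
                        molregno,
                        600 + rng.randrange(spec.n_docs),
                        pchembl,
                        1 if rng.random() < spec.fraction_duplicate_flag else 0,
                        comments[-2:][rng.randrange(2)]
                        if rng.random() < spec.fraction_validity_comment
                        else None,
                        rng.choice((7, 9, 38))
                        if rng.random() < spec.fraction_nonliterature
                        else 1,
                    )
                )
                activity_id += 1

    mech_slots = [(p, t) for p in parents for t in single_tids + family_tids]
    mechanisms = []
    for mec_id, (molregno, tid) in enumerate(
        rng.sample(mech_slots, spec.n_mechanism_rows), start=1
    ):
        efficacy = 0 if rng.random() < spec.fraction_disease_efficacy_zero else 1
        mechanisms.append((mec_id, molregno, tid, efficacy))

    structures = []
    for m in molecules:
        roll = rng.random()
        if roll < spec.fraction_missing_structure:
            continue
        if roll < spec.fraction_missing_structure + spec.fraction_mixture_smiles:
            smiles = rng.choice(MIXTURE_SMILES_POOL)
        else:
            smiles = rng.choice(SMILES_POOL)
        structures.append((m, smiles, f"InChI=1S/fake{m}", f"FAKEKEY{m:010d}"))

    properties = []
    for m in molecules:
        if rng.random() < spec.fraction_missing_properties:
            continue
        psa = (
            None
            if rng.random() < spec.fraction_missing_psa
            else round(rng.uniform(20.0, 140.0), 2)
        )
        properties.append(
            (
                m,
                round(rng.uniform(150.0, 600.0), 2),
                round(rng.uniform(-2.0, 6.0), 2),
                rng.randint(0, 10),
                rng.randint(0, 5),
                psa,
                rng.randint(0, 12),
                rng.randint(0, 2),
                rng.randint(10, 45),
                round(rng.uniform(0.1, 0.95), 3),
                rng.randint(0, 4),
            )
        )

    atc = []
    for m in parents:
        if rng.random() < spec.atc_fraction:
            for code in rng.sample(_ATC_LEVEL5_POOL, rng.randint(1, spec.n_atc_max)):
                atc.append((m, code))

    components, component_classes = _target_class_rows(
        rng, single_tids + family_tids, spec
    )

    return {
        "ACTIVITIES": activities,
        "ASSAYS": assays,
        "DOCS": docs,
        "MOLECULE_HIERARCHY": hierarchy,
        "MOLECULE_DICTIONARY": dictionary,
        "DRUG_MECHANISM": mechanisms,
        "TARGET_RELATIONS": relations,
        "TARGET_DICTIONARY": target_dictionary,
        "COMPOUND_PROPERTIES": properties,
        "COMPOUND_STRUCTURES": structures,
        "MOLECULE_ATC_CLASSIFICATION": atc,
        "PROTEIN_CLASSIFICATION": list(PROTEIN_CLASS_TREE),
        "TARGET_COMPONENTS": components,
        "COMPONENT_CLASS": component_classes,
    }


def build_fixture(spec: FixtureSpec, path: Path | str) -> Path:
    """Write the store described by ``spec`` to ``path``."""
    return write_store(path, generate_tables(spec))


@dataclass(frozen=True)
class EdgeCase:
    """A hand-crafted store plus the facts it is meant to demonstrate."""

    name: str
    tables: dict[str, list[tuple]]
    release: int = 32
    expect: dict = field(default_factory=dict)
    expect_error: type | None = None


def _base_tables() -> dict[str, list[tuple]]:
    return {
        "DOCS": [(600, 2005), (601, 2010), (602, None)],
        "MOLECULE_HIERARCHY": [(100, 100), (101, 101), (1000, 100)],
        "MOLECULE_DICTIONARY": [
            (100, "CHEMBL100", 4),
            (101, "CHEMBL101", None),
            (1000, "CHEMBL1000", None),
        ],
        "TARGET_DICTIONARY": [
            (200, "CHEMBL_T200", "Protein 200", "SINGLE PROTEIN"),
            (201, "CHEMBL_T201", "Protein 201", "SINGLE PROTEIN"),
            (300, "CHEMBL_T300", "Family 300", "PROTEIN FAMILY"),
        ],
        "ASSAYS": [(5000, 200, "B", None), (5001, 201, "F", None)],
        "COMPOUND_STRUCTURES": [
            (100, "c1ccccc1", "InChI=1S/fake100", "FAKEKEY100"),
            (101, "CCO", "InChI=1S/fake101", "FAKEKEY101"),
        ],
        "COMPOUND_PROPERTIES": [
            (100, 300.0, 2.5, 4, 1, 80.0, 3, 0, 22, 0.7, 2),
            (101, 46.07, -0.3, 1, 1, 20.2, 0, 0, 3, 0.4, 0),
        ],
        "PROTEIN_CLASSIFICATION": list(PROTEIN_CLASS_TREE),
        "TARGET_COMPONENTS": [(200, 1200), (201, 1201), (300, 1300)],
        "COMPONENT_CLASS": [(1200, 6), (1201, 8), (1300, 2)],
    }


def edge_case_suite() -> list[EdgeCase]:
    """Stores covering the documented boundary behaviours."""
    cases: list[EdgeCase] = []

    # A curated pair that was never measured enters with all aggregates
    # absent and a C0 class (compound without a clinical phase).
    tables = _base_tables()
    tables["DRUG_MECHANISM"] = [(1, 101, 200, 1)]
    cases.append(
        EdgeCase(
            "mechanism_only_pair",
            tables,
            expect={"pairs": {(101, 200): {"DTI": "C0_DT", "in_dm_table": True}}},
        )
    )

    # A molecule with two distinct parents is a fatal consistency error.
    tables = _base_tables()
    tables["MOLECULE_HIERARCHY"] = [(100, 100), (1000, 100), (1000, 101)]
    tables["ACTIVITIES"] = [(1, 5000, 1000, 600, 7.0, 0, None, 1)]
    from ctipairs.errors import ConsistencyError

    cases.append(
        EdgeCase("multi_parent_error", tables, expect_error=ConsistencyError)
    )

    # A curated compound whose stored SMILES is a mixture is removed.
    tables = _base_tables()
    tables["COMPOUND_STRUCTURES"] = [
        (100, "CC(=O)[O-].[Na+]", "InChI=1S/fake100", "FAKEKEY100"),
        (101, "CCO", "InChI=1S/fake101", "FAKEKEY101"),
    ]
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    tables["DRUG_MECHANISM"] = [(1, 100, 200, 1)]
    cases.append(
        EdgeCase(
            "mixture_smiles_removed",
            tables,
            expect={"removal": {"missing_smiles": 0, "mixture_smiles": 1}},
        )
    )

    # A compound without any structure row is removed and counted.
    tables = _base_tables()
    tables["COMPOUND_STRUCTURES"] = [
        (101, "CCO", "InChI=1S/fake101", "FAKEKEY101"),
    ]
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    tables["DRUG_MECHANISM"] = [(1, 100, 200, 1)]
    cases.append(
        EdgeCase(
            "missing_smiles_removed",
            tables,
            expect={"removal": {"missing_smiles": 1, "mixture_smiles": 0}},
        )
    )

    # Unclassified target: class labels absent, not in the multi-class file.
    tables = _base_tables()
    tables["COMPONENT_CLASS"] = []
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    tables["DRUG_MECHANISM"] = [(1, 101, 200, 1)]
    cases.append(
        EdgeCase(
            "unclassified_target",
            tables,
            expect={"multiclass_tids": set(), "tclass_level1": {200: None}},
        )
    )

    # Two level-1 classes concatenate alphabetically and land in the report.
    tables = _base_tables()
    tables["COMPONENT_CLASS"] = [(1200, 2), (1200, 5)]
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    tables["DRUG_MECHANISM"] = [(1, 101, 200, 1)]
    cases.append(
        EdgeCase(
            "multiclass_target",
            tables,
            expect={
                "multiclass_tids": {200},
                "tclass_level1": {200: "Enzyme|Epigenetic regulator"},
            },
        )
    )

    # Family expansion: a mechanism on the family also covers its members,
    # while the non-whitelisted inverse relation is ignored.
    tables = _base_tables()
    tables["TARGET_RELATIONS"] = [
        (300, "SUPERSET OF", 200),
        (300, "SUPERSET OF", 201),
        (200, "SUBSET OF", 300),
    ]
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    tables["DRUG_MECHANISM"] = [(1, 100, 300, 1)]
    cases.append(
        EdgeCase(
            "relation_expansion",
            tables,
            expect={
                "pairs": {
                    (100, 200): {"DTI": "D_DT", "in_dm_table": True},
                    (100, 300): {"DTI": "D_DT", "in_dm_table": True},
                    (100, 201): {"DTI": "D_DT", "in_dm_table": True},
                }
            },
        )
    )

    # Sub-phase-1 codes of the current coding all map to C0_DT.
    tables = _base_tables()
    tables["MOLECULE_HIERARCHY"] = [(100, 100), (101, 101), (102, 102)]
    tables["MOLECULE_DICTIONARY"] = [
        (100, "CHEMBL100", 0.5),
        (101, "CHEMBL101", -1),
        (102, "CHEMBL102", None),
    ]
    tables["COMPOUND_STRUCTURES"] = [
        (100, "c1ccccc1", "I100", "K100"),
        (101, "CCO", "I101", "K101"),
        (102, "c1ccncc1", "I102", "K102"),
    ]
    tables["DRUG_MECHANISM"] = [(1, 100, 200, 1), (2, 101, 200, 1), (3, 102, 201, 1)]
    cases.append(
        EdgeCase(
            "sub_phase_codes_current",
            tables,
            expect={
                "pairs": {
                    (100, 200): {"DTI": "C0_DT"},
                    (101, 200): {"DTI": "C0_DT"},
                    (102, 201): {"DTI": "C0_DT"},
                }
            },
        )
    )

    # Legacy coding (release 31): phase 0 maps to C0_DT.
    tables = _base_tables()
    tables["MOLECULE_DICTIONARY"] = [
        (100, "CHEMBL100", 0),
        (101, "CHEMBL101", None),
        (1000, "CHEMBL1000", None),
    ]
    tables["DRUG_MECHANISM"] = [(1, 100, 200, 1)]
    cases.append(
        EdgeCase(
            "phase_zero_legacy",
            tables,
            release=31,
            expect={"pairs": {(100, 200): {"DTI": "C0_DT"}}},
        )
    )

    # Empty activity and mechanism tables give an empty final dataset.
    cases.append(
        EdgeCase("empty_tables", _base_tables(), expect={"n_pairs": 0})
    )

    # Measured activity on a non-therapeutic target is NDT and discarded.
    tables = _base_tables()
    tables["ACTIVITIES"] = [(1, 5000, 100, 600, 7.0, 0, None, 1)]
    cases.append(EdgeCase("ndt_discarded", tables, expect={"n_pairs": 0}))

    return cases
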