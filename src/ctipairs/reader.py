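"""Read-only access to a ChEMBL-schema SQLite store.

All queries are plain SQL over the subset of the schema the pipeline needs.
Record-level exclusion filters (assay type, potential duplicates, validity
comments, the unchecked-target sentinel, literature provenance) are applied
here so downstream stages only ever see qualifying activity rows.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ctipairs.errors import SchemaError, StoreError, VersionError

#: Earliest ChEMBL release whose schema carries every table the pipeline reads.
MIN_SUPPORTED_RELEASE = 26

#: Sentinel target id for activities whose target has not been curated yet.
UNCHECKED_TARGET_TID = 22226

#: Source id of the scientific-literature channel in the ChEMBL SOURCE table.
LITERATURE_SRC_ID = 1

REQUIRED_TABLES = (
    "ACTIVITIES",
    "ASSAYS",
    "DOCS",
    "MOLECULE_HIERARCHY",
    "MOLECULE_DICTIONARY",
    "DRUG_MECHANISM",
    "TARGET_RELATIONS",
    "TARGET_DICTIONARY",
    "COMPOUND_PROPERTIES",
    "COMPOUND_STRUCTURES",
    "MOLECULE_ATC_CLASSIFICATION",
    "PROTEIN_CLASSIFICATION",
    "TARGET_COMPONENTS",
    "COMPONENT_CLASS",
)

#: Columns of COMPOUND_PROPERTIES carried into the dataset, in output order.
PROPERTY_COLUMNS = (
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
)


@dataclass(frozen=True)
class SourceFilter:
    """Provenance restriction applied to activity records.

    By default only records from the scientific-literature source channel are
    emitted; ``literature_only=False`` keeps every source.
    """

    literature_only: bool = True


@dataclass
class StoreHandle:
    """An open connection to a schema-checked store.

    ``release`` is the ChEMBL release number when known, else ``None``;
    release-dependent behaviour (clinical-phase codes) assumes the current
    semantics when the release is unknown.
    """

    path: Path
    release: int | None = None
    conn: sqlite3.Connection = field(repr=False, default=None)

    def close(self) -> None:
        if self.conn is not None:
            self.conn.close()
            self.conn = None

    def __enter__(self) -> "StoreHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _check_schema(conn: sqlite3.Connection) -> None:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type IN ('table', 'view')"
    ).fetchall()
    present = {r[0].upper() for r in rows}
    for table in REQUIRED_TABLES:
        if table not in present:
            raise SchemaError(f"store is missing required table {table}")


def open_store(
    version_or_path: int | str | Path | None = None,
    *,
    release: int | None = None,
) -> StoreHandle:
    """Open a store by file path or by ChEMBL release number.

    An integer argument is treated as a release number and resolved through
    the standard ChEMBL distribution mechanism (``chembl_downloader``); any
    other argument is a path to an existing SQLite file.  ``release`` may be
    passed alongside a path when the release of the file is known.  With no
    argument the latest available release is fetched.
    """
    if isinstance(version_or_path, int):
        if release is not None and release != version_or_path:
            raise ValueError("release conflicts with requested version")
        release = version_or_path
        path = _fetch_release(version_or_path)
    elif version_or_path is None:
        path = _fetch_release(None)
    else:
        path = Path(version_or_path)

    if release is not None and release < MIN_SUPPORTED_RELEASE:
        raise VersionError(
            f"ChEMBL release {release} is not supported; "
            f"{MIN_SUPPORTED_RELEASE} is the earliest usable release"
        )
    if not path.is_file():
        raise StoreError(f"store file not found: {path}")
    conn = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
    try:
        _check_schema(conn)
    except sqlite3.DatabaseError as exc:
        conn.close()
        raise StoreError(f"not a readable SQLite database: {path}") from exc
    except SchemaError:
        conn.close()
        raise
    return StoreHandle(path=path, release=release, conn=conn)


def _fetch_release(release: int | None) -> Path:
    if release is not None and release < MIN_SUPPORTED_RELEASE:
        raise VersionError(
            f"ChEMBL release {release} is not supported; "
            f"{MIN_SUPPORTED_RELEASE} is the earliest usable release"
        )
    try:
        import chembl_downloader
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise StoreError(
            "no store path given and chembl_downloader is not installed; "
            "pass a path to a ChEMBL SQLite file instead"
        ) from exc
    version = str(release) if release is not None else None
    return Path(chembl_downloader.download_extract_sqlite(version=version))


def _read_sql(handle: StoreHandle, sql: str, params: tuple = ()) -> pd.DataFrame:
    return pd.read_sql_query(sql, handle.conn, params=params)


def fetch_activity_records(
    handle: StoreHandle, source_filter: SourceFilter = SourceFilter()
) -> pd.DataFrame:
    """Qualifying activity records, one row per measurement.

    Emitted rows satisfy every exclusion rule: a present, positive pChEMBL
    value, assay type B or F, potential-duplicate flag 0, data-validity
    comment absent or ``'Manually validated'`` and a curated target.  With
    ``literature_only`` only rows from the literature source channel pass.

    Columns: ``molregno, tid, variant_id, assay_type, pchembl_value, year,
    src_id``.  Row order is unspecified.
    """
    sql = """
        SELECT a.molregno        AS molregno,
               s.tid             AS tid,
               s.variant_id      AS variant_id,
               s.assay_type      AS assay_type,
               a.pchembl_value   AS pchembl_value,
               d.year            AS year,
               a.src_id          AS src_id
        FROM ACTIVITIES a
        JOIN ASSAYS s ON s.assay_id = a.assay_id
        LEFT JOIN DOCS d ON d.doc_id = a.doc_id
        WHERE a.pchembl_value IS NOT NULL
          AND a.pchembl_value > 0
          AND s.assay_type IN ('B', 'F')
          AND a.potential_duplicate = 0
          AND (a.data_validity_comment IS NULL
               OR a.data_validity_comment = 'Manually validated')
          AND s.tid <> ?
    """
    params: list = [UNCHECKED_TARGET_TID]
    if source_filter.literature_only:
        sql += " AND a.src_id = ?"
        params.append(LITERATURE_SRC_ID)
    return _read_sql(handle, sql, tuple(params))


def fetch_mechanisms(handle: StoreHandle) -> pd.DataFrame:
    """Curated mechanism rows joined with the compound's clinical phase.

    Columns: ``molregno, tid, disease_efficacy, max_phase``.  No filtering;
    the disease-efficacy restriction is applied downstream.
    """
    return _read_sql(
        handle,
        """
        SELECT dm.molregno        AS molregno,
               dm.tid             AS tid,
               dm.disease_efficacy AS disease_efficacy,
               md.max_phase       AS max_phase
        FROM DRUG_MECHANISM dm
        LEFT JOIN MOLECULE_DICTIONARY md ON md.molregno = dm.molregno
        """,
    )


def fetch_target_relations(handle: StoreHandle) -> pd.DataFrame:
    """Target-relation rows with the types of both endpoints attached.

    Columns: ``tid, relationship, related_tid, target_type, related_type``.
    """
    return _read_sql(
        handle,
        """
        SELECT tr.tid            AS tid,
               tr.relationship   AS relationship,
               tr.related_tid    AS related_tid,
               td1.target_type   AS target_type,
               td2.target_type   AS related_type
        FROM TARGET_RELATIONS tr
        LEFT JOIN TARGET_DICTIONARY td1 ON td1.tid = tr.tid
        LEFT JOIN TARGET_DICTIONARY td2 ON td2.tid = tr.related_tid
        """,
    )


def fetch_compound_tables(handle: StoreHandle) -> dict[str, pd.DataFrame]:
    """Verbatim compound-side tables keyed by a short name.

    Returns ``hierarchy`` (molregno, parent_molregno), ``dictionary``
    (molregno, chembl_id, max_phase), ``properties`` (molregno + the
    carried property columns), ``structures`` (molregno, canonical_smiles,
    standard_inchi, standard_inchi_key) and ``atc`` (molregno, level1
    derived from the stored level-5 code).
    """
    props = ", ".join(PROPERTY_COLUMNS)
    return {
        "hierarchy": _read_sql(
            handle, "SELECT molregno, parent_molregno FROM MOLECULE_HIERARCHY"
        ),
        "dictionary": _read_sql(
            handle, "SELECT molregno, chembl_id, max_phase FROM MOLECULE_DICTIONARY"
        ),
        "properties": _read_sql(
            handle, f"SELECT molregno, {props} FROM COMPOUND_PROPERTIES"
        ),
        "structures": _read_sql(
            handle,
            "SELECT molregno, canonical_smiles, standard_inchi, standard_inchi_key"
            " FROM COMPOUND_STRUCTURES",
        ),
        "atc": _read_sql(
            handle,
            "SELECT molregno, SUBSTR(level5, 1, 1) AS level1"
            " FROM MOLECULE_ATC_CLASSIFICATION",
        ),
    }


def fetch_target_dictionary(handle: StoreHandle) -> pd.DataFrame:
    """Target identity columns: ``tid, chembl_id, pref_name, target_type``."""
    return _read_sql(
        handle,
        "SELECT tid, chembl_id, pref_name, target_type FROM TARGET_DICTIONARY",
    )


def fetch_target_classes(handle: StoreHandle) -> pd.DataFrame:
    """Level-1/level-2 protein-class labels per target.

    Resolves each target's protein classes through TARGET_COMPONENTS and
    COMPONENT_CLASS and walks the PROTEIN_CLASSIFICATION tree upwards to the
    class-level-1 and class-level-2 ancestors.  Returns one row per distinct
    (tid, level1, level2) combination; ``level2`` may be null when the
    assigned class sits at level 1.
    """
    classes = _read_sql(
        handle,
        "SELECT protein_class_id, parent_id, pref_name, class_level"
        " FROM PROTEIN_CLASSIFICATION",
    )
    nodes = {
        int(r.protein_class_id): (
            None if pd.isna(r.parent_id) else int(r.parent_id),
            r.pref_name,
            int(r.class_level),
        )
        for r in classes.itertuples()
    }

    def ancestor_at(class_id: int, level: int) -> str | None:
        seen = set()
        current: int | None = class_id
        while current is not None and current not in seen:
            seen.add(current)
            parent, name, class_level = nodes[current]
            if class_level == level:
                return name
            current = parent
        return None

    assigned = _read_sql(
        handle,
        """
        SELECT DISTINCT tc.tid AS tid, cc.protein_class_id AS protein_class_id
        FROM TARGET_COMPONENTS tc
        JOIN COMPONENT_CLASS cc ON cc.component_id = tc.component_id
        """,
    )
    rows = []
    for r in assigned.itertuples():
        class_id = int(r.protein_class_id)
        if class_id not in nodes:
            continue
        rows.append(
            {
                "tid": int(r.tid),
                "level1": ancestor_at(class_id, 1),
                "level2": ancestor_at(class_id, 2),
            }
        )
    out = pd.DataFrame(rows, columns=["tid", "level1", "level2"])
    return out.drop_duplicates(ignore_index=True)
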