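"""Missing-value normalisation, rounding, consistency checks and file I/O.

The assembled dataset is brought onto nullable pandas dtypes with a single
missing-value sentinel, floats are rounded to four decimal places (clinical
phase excepted), and a battery of basic checks is run before and after
writing.  Written files are verified by reading them back and comparing
value-for-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ctipairs.annotate import RDKIT_COUNT_COLUMNS
from ctipairs.mechanism import DTI_CLASSES

#: Written in place of missing values; recognised again on read-back.
MISSING_SENTINEL = "None"

ROUND_DECIMALS = 4

#: Columns exempt from rounding (phase codes like 0.5 must survive intact).
UNROUNDED_COLUMNS = frozenset({"max_phase"})

INT_COLUMNS = frozenset(
    {
        "parent_molregno",
        "tid",
        "first_publication_cpd_target_pair_BF",
        "first_publication_cpd_target_pair_w_pchembl_BF",
        "first_publication_cpd_target_pair_B",
        "first_publication_cpd_target_pair_w_pchembl_B",
        "first_publication_cpd",
        "hba",
        "hbd",
        "rtb",
        "num_ro5_violations",
        "heavy_atoms",
        "aromatic_rings",
    }
    | set(RDKIT_COUNT_COLUMNS)
)

BOOL_COLUMNS = frozenset(
    {
        "in_dm_table",
        "BF_100",
        "BF_100_c_dt_d_dt",
        "BF_100_d_dt",
        "BF_100_c_dt",
        "B_100",
        "B_100_c_dt_d_dt",
        "B_100_d_dt",
        "B_100_c_dt",
    }
)


def normalize_and_round(dataset: pd.DataFrame) -> pd.DataFrame:
    """Canonical dtypes, one missing sentinel, 4-dp round-half-even floats.

    Integer-valued columns move to nullable ``Int64``, booleans to nullable
    ``boolean``, remaining numerics to ``Float64`` rounded to four decimals
    (except the clinical phase), text to ``string`` with empty strings
    converted to missing.  The operation is idempotent.
    """
    out = dataset.copy()
    for column in out.columns:
        series = out[column]
        if column in BOOL_COLUMNS:
            out[column] = series.astype("boolean")
        elif column in INT_COLUMNS:
            out[column] = pd.to_numeric(series).astype("Float64").astype("Int64")
        elif pd.api.types.is_numeric_dtype(series) and not (
            pd.api.types.is_bool_dtype(series)
        ):
            converted = series.astype("Float64")
            if column not in UNROUNDED_COLUMNS:
                converted = converted.round(ROUND_DECIMALS)
            out[column] = converted
        else:
            text = series.astype("string")
            out[column] = text.mask(text == "", pd.NA)
    return out


@dataclass
class Check:
    name: str
    expected: object
    observed: object
    passed: bool


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return all(check.passed for check in self.checks)

    def add(self, name: str, expected, observed) -> None:
        self.checks.append(Check(name, expected, observed, expected == observed))

    def failures(self) -> list[Check]:
        return [check for check in self.checks if not check.passed]

    def summary(self) -> str:
        lines = []
        for check in self.checks:
            status = "PASS" if check.passed else "FAIL"
            lines.append(
                f"{status} {check.name}: expected={check.expected!r} "
                f"observed={check.observed!r}"
            )
        lines.append(f"overall: {'PASS' if self.overall else 'FAIL'}")
        return "\n".join(lines)


def run_basic_checks(
    dataset: pd.DataFrame,
    expected_missing: dict[str, int] | None = None,
) -> ValidationReport:
    """Consistency checks over the cleaned dataset.

    Verifies the uniform missing sentinel, absence of mixed-type (object)
    columns, that every pair without a pChEMBL value is curated
    (``in_dm_table``), per-column missing counts against expectations
    computed from the source tables, and that no NDT row survived.
    """
    report = ValidationReport()

    string_columns = [c for c in dataset.columns if dataset[c].dtype == "string"]
    empty_strings = int(
        sum((dataset[c] == "").sum() for c in string_columns)
    )
    report.add("uniform_missing_values", 0, empty_strings)

    object_columns = [c for c in dataset.columns if dataset[c].dtype == object]
    report.add("no_mixed_type_columns", [], object_columns)

    if "pchembl_value_max_BF" in dataset.columns and "in_dm_table" in dataset.columns:
        missing_pchembl = dataset["pchembl_value_max_BF"].isna()
        unexplained = int((missing_pchembl & ~dataset["in_dm_table"].fillna(False)).sum())
        report.add("pchembl_missing_implies_mechanism", 0, unexplained)

    if "DTI" in dataset.columns:
        report.add("no_ndt_rows", 0, int((dataset["DTI"] == "NDT").sum()))
        invalid = int((~dataset["DTI"].isin(DTI_CLASSES[:-1])).sum())
        report.add("dti_classes_valid", 0, invalid)

    for column, expected in (expected_missing or {}).items():
        observed = int(dataset[column].isna().sum()) if column in dataset.columns else None
        report.add(f"missing_count:{column}", int(expected), observed)

    return report


def write_dataset(dataset: pd.DataFrame, path: Path | str, delimiter: str = ";") -> Path:
    """Write a delimited text file with the canonical missing sentinel."""
    path = Path(path)
    dataset.to_csv(path, sep=delimiter, index=False, na_rep=MISSING_SENTINEL)
    return path


def read_dataset(
    path: Path | str, delimiter: str = ";", like: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a written dataset back, restoring dtypes from ``like``."""
    raw = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        na_values=[MISSING_SENTINEL],
        keep_default_na=False,
    )
    if like is None:
        return raw
    out = pd.DataFrame(index=raw.index)
    for column in raw.columns:
        series = raw[column]
        dtype = like[column].dtype if column in like.columns else None
        if dtype is not None and pd.api.types.is_bool_dtype(dtype):
            out[column] = series.map({"True": True, "False": False}).astype("boolean")
        elif dtype is not None and pd.api.types.is_integer_dtype(dtype):
            out[column] = pd.to_numeric(series).astype("Float64").astype("Int64")
        elif dtype is not None and pd.api.types.is_float_dtype(dtype):
            out[column] = pd.to_numeric(series).astype("Float64")
        else:
            out[column] = series.astype("string")
    return out


def verify_roundtrip(
    dataset: pd.DataFrame, written_file: Path | str, delimiter: str = ";"
) -> tuple[bool, str]:
    """True iff the file reproduces the in-memory dataset value-for-value."""
    try:
        read_back = read_dataset(written_file, delimiter=delimiter, like=dataset)
    except Exception as exc:  # parse or cast failure counts as mismatch
        return False, f"read-back failed: {exc}"
    if list(read_back.columns) != list(dataset.columns):
        return False, (
            f"column mismatch: wrote {list(dataset.columns)}, "
            f"read {list(read_back.columns)}"
        )
    if len(read_back) != len(dataset):
        return False, f"row count mismatch: wrote {len(dataset)}, read {len(read_back)}"
    expected = dataset.reset_index(drop=True)
    for column in expected.columns:
        left = expected[column]
        right = read_back[column]
        mismatch = ~((left.isna() & right.isna()) | (left == right)).fillna(False)
        if mismatch.any():
            row = int(mismatch.idxmax())
            return False, (
                f"first differing cell: column {column!r} row {row}: "
                f"wrote {left.iloc[row]!r}, read {right.iloc[row]!r}"
            )
    return True, "ok"
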