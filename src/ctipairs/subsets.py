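"""Subset filter columns, per-dataset statistics and file output.

Subsets restrict the dataset to targets with enough measured compounds
(default at least 100 with a pChEMBL value in the assay domain) and,
optionally, at least one drug and/or clinical-candidate interaction on the
target.  Flags are carried as boolean columns on the full dataset; subset
files are exactly the rows where a flag is true.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from ctipairs.cleaning import verify_roundtrip, write_dataset
from ctipairs.mechanism import CANDIDATE_CLASSES

log = logging.getLogger(__name__)

#: Minimum number of distinct compounds with a pChEMBL value per target.
DEFAULT_COMPOUND_THRESHOLD = 100

#: Flag menu per assay domain, in output order.
FLAG_SUFFIXES = ("100", "100_c_dt_d_dt", "100_d_dt", "100_c_dt")

STAT_GROUPS = ("total", "comparator", "drugs", "candidates")

STAT_COLUMNS = (
    "n_pairs",
    "n_pairs_incl_variants",
    "n_compounds",
    "n_targets",
    "n_targets_incl_variants",
)


def flag_columns(domains: tuple[str, ...] = ("BF", "B")) -> list[str]:
    return [f"{d}_{suffix}" for d in domains for suffix in FLAG_SUFFIXES]


def compute_filter_columns(
    dataset: pd.DataFrame,
    threshold: int = DEFAULT_COMPOUND_THRESHOLD,
    domains: tuple[str, ...] = ("BF", "B"),
) -> pd.DataFrame:
    """Attach the eight boolean subset flags.

    ``<d>_100`` is true for every pair of a target with at least
    ``threshold`` distinct compounds carrying a pChEMBL value in domain
    ``d``; ``_d_dt`` additionally requires a drug interaction (D_DT) on the
    target, ``_c_dt`` a clinical-candidate interaction (C*_DT), and
    ``_c_dt_d_dt`` at least one of either.
    """
    out = dataset.copy()
    drug_targets = set(out.loc[out["DTI"] == "D_DT", "tid"])
    candidate_targets = set(out.loc[out["DTI"].isin(CANDIDATE_CLASSES), "tid"])
    for domain in domains:
        with_pchembl = out[out[f"pchembl_value_max_{domain}"].notna()]
        counts = with_pchembl.groupby("tid")["parent_molregno"].nunique()
        qualifying = set(counts[counts >= threshold].index)
        base = out["tid"].isin(qualifying)
        out[f"{domain}_100"] = base.astype("boolean")
        out[f"{domain}_100_c_dt_d_dt"] = (
            base & out["tid"].isin(drug_targets | candidate_targets)
        ).astype("boolean")
        out[f"{domain}_100_d_dt"] = (base & out["tid"].isin(drug_targets)).astype(
            "boolean"
        )
        out[f"{domain}_100_c_dt"] = (base & out["tid"].isin(candidate_targets)).astype(
            "boolean"
        )
    return out


def _group_masks(dataset: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "total": pd.Series(True, index=dataset.index),
        "comparator": dataset["DTI"] == "DT",
        "drugs": dataset["DTI"] == "D_DT",
        "candidates": dataset["DTI"].isin(CANDIDATE_CLASSES),
    }


def compute_stats(dataset: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Pair/compound/target tallies for the dataset and its DTI groups.

    ``variants`` holds the distinct (parent, target, variant) keys observed
    in the activity data; pairs without any variant-resolved record count as
    a single plain-target key.
    """
    variant_keys = variants.copy()
    variant_keys["variant_id"] = variant_keys["variant_id"].astype("Float64")
    rows = []
    for group, mask in _group_masks(dataset).items():
        members = dataset.loc[mask, ["parent_molregno", "tid"]].astype("int64")
        merged = members.drop_duplicates().merge(
            variant_keys, on=["parent_molregno", "tid"], how="left"
        )
        rows.append(
            {
                "group": group,
                "n_pairs": len(members),
                "n_pairs_incl_variants": len(
                    merged.drop_duplicates(
                        subset=["parent_molregno", "tid", "variant_id"]
                    )
                ),
                "n_compounds": members["parent_molregno"].nunique(),
                "n_targets": members["tid"].nunique(),
                "n_targets_incl_variants": len(
                    merged.drop_duplicates(subset=["tid", "variant_id"])
                ),
            }
        )
    return pd.DataFrame(rows, columns=["group", *STAT_COLUMNS])


def output_prefix(release: int | None, literature_only: bool) -> str:
    sources = "literature_only" if literature_only else "all_sources"
    return f"ChEMBL{release if release is not None else 'NA'}_CTI_{sources}"


def write_outputs(
    dataset: pd.DataFrame,
    variants: pd.DataFrame,
    output_dir: Path | str,
    release: int | None,
    literature_only: bool = True,
    delimiter: str = ";",
    write_bf_subsets: bool = False,
    write_b_subsets: bool = False,
    spreadsheet: bool = False,
    multiclass_report: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the full dataset, requested subsets and their stats files.

    Every delimited file is verified by round-trip read-back; a failed
    verification is a fatal I/O error.  The optional spreadsheet is written
    on a best-effort basis ("may fail if the output is too large") and never
    blocks the delimited output.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    prefix = output_prefix(release, literature_only)
    written: dict[str, Path] = {}

    def write_and_verify(name: str, frame: pd.DataFrame) -> None:
        path = output_dir / f"{prefix}_{name}.csv"
        write_dataset(frame, path, delimiter)
        ok, message = verify_roundtrip(frame, path, delimiter)
        if not ok:
            raise IOError(f"round-trip verification failed for {path}: {message}")
        written[name] = path

    def write_with_stats(name: str, frame: pd.DataFrame) -> None:
        write_and_verify(name, frame)
        stats = compute_stats(frame, variants)
        write_and_verify(f"{name}_stats", stats)

    write_with_stats("full_dataset", dataset)

    domains = [d for d, chosen in (("BF", write_bf_subsets), ("B", write_b_subsets)) if chosen]
    for flag in flag_columns(tuple(domains)):
        subset = dataset[dataset[flag].fillna(False).astype(bool)].reset_index(drop=True)
        write_with_stats(flag, subset)

    if multiclass_report is not None:
        write_and_verify("targets_w_more_than_one_tclass", multiclass_report)

    if spreadsheet:
        try:
            xlsx = output_dir / f"{prefix}.xlsx"
            with pd.ExcelWriter(xlsx) as writer:
                dataset.to_excel(writer, sheet_name="full_dataset", index=False)
            written["spreadsheet"] = xlsx
        except Exception as exc:
            log.warning("spreadsheet output failed, delimited files kept: %s", exc)

    return written
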