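"""Parent mapping and per-pair aggregation of activity records.

Activities are regrouped under the parent compound of the molecule hierarchy
(salt forms collapse onto their parent) and summarised per (parent, target)
pair: mean/median/maximum pChEMBL and first-publication years, once over
binding and functional assays combined (``_BF``) and once over binding assays
alone (``_B``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ctipairs.errors import ConsistencyError

#: Aggregate columns produced per assay domain.
DOMAINS = ("BF", "B")

AGGREGATE_COLUMNS = tuple(
    f"{stem}_{domain}"
    for domain in DOMAINS
    for stem in (
        "pchembl_value_mean",
        "pchembl_value_median",
        "pchembl_value_max",
        "first_publication_cpd_target_pair",
        "first_publication_cpd_target_pair_w_pchembl",
    )
)


def build_parent_map(hierarchy: pd.DataFrame) -> dict[int, int]:
    """Molregno -> parent molregno from MOLECULE_HIERARCHY rows.

    Raises :class:`ConsistencyError` if any molecule carries two distinct
    parents.  Molecules absent from the map are their own parent.
    """
    parent_map: dict[int, int] = {}
    for row in hierarchy.itertuples():
        if pd.isna(row.parent_molregno):
            continue
        molregno = int(row.molregno)
        parent = int(row.parent_molregno)
        if molregno in parent_map and parent_map[molregno] != parent:
            raise ConsistencyError(
                f"molecule {molregno} has two distinct parents: "
                f"{parent_map[molregno]} and {parent}"
            )
        parent_map[molregno] = parent
    return parent_map


def map_to_parent(molregno: int, parent_map: dict[int, int]) -> int:
    """Parent of ``molregno``; identity when the hierarchy has no entry."""
    return parent_map.get(molregno, molregno)


def _domain_aggregates(records: pd.DataFrame, domain: str) -> pd.DataFrame:
    grouped = records.groupby(["parent_molregno", "tid"], sort=False)
    out = grouped["pchembl_value"].agg(["mean", "median", "max"])
    out.columns = [f"pchembl_value_{stat}_{domain}" for stat in ("mean", "median", "max")]
    years = grouped["year"].min()
    out[f"first_publication_cpd_target_pair_{domain}"] = years
    with_pchembl = records[records["pchembl_value"].notna()]
    out[f"first_publication_cpd_target_pair_w_pchembl_{domain}"] = (
        with_pchembl.groupby(["parent_molregno", "tid"], sort=False)["year"].min()
    )
    return out


def aggregate_pairs(records: pd.DataFrame, parent_map: dict[int, int]) -> pd.DataFrame:
    """One row per (parent, target) pair with ``_BF`` and ``_B`` aggregates.

    ``records`` must already satisfy the reader's filters.  The ``_BF``
    statistics run over binding and functional records combined; ``_B`` over
    binding records only, and are absent for pairs without a binding record.
    Year minima skip records without a document year.
    """
    records = records.copy()
    records["parent_molregno"] = records["molregno"].map(
        lambda m: map_to_parent(int(m), parent_map)
    )
    bf = _domain_aggregates(records, "BF")
    b = _domain_aggregates(records[records["assay_type"] == "B"], "B")
    pairs = bf.join(b, how="left").reset_index()
    pairs["parent_molregno"] = pairs["parent_molregno"].astype(np.int64)
    pairs["tid"] = pairs["tid"].astype(np.int64)
    return pairs


def variant_pairs(records: pd.DataFrame, parent_map: dict[int, int]) -> pd.DataFrame:
    """Distinct (parent, target, variant) keys for the variant-level tallies.

    A record without a variant annotation contributes the plain target as its
    own variant key (variant null).
    """
    keys = records[["molregno", "tid", "variant_id"]].copy()
    keys["parent_molregno"] = keys["molregno"].map(
        lambda m: map_to_parent(int(m), parent_map)
    )
    return (
        keys[["parent_molregno", "tid", "variant_id"]]
        .drop_duplicates(ignore_index=True)
    )


def compound_first_years(
    records: pd.DataFrame, parent_map: dict[int, int]
) -> pd.Series:
    """First publication year per parent compound over all its records."""
    rec = records.copy()
    rec["parent_molregno"] = rec["molregno"].map(
        lambda m: map_to_parent(int(m), parent_map)
    )
    return rec.groupby("parent_molregno")["year"].min()
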