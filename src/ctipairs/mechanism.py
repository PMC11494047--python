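"""Curated-mechanism integration and drug-target interaction (DTI) classes.

Mechanism rows with a positive disease-efficacy flag mark known therapeutic
interactions.  Their targets are expanded through a whitelist of target
relations (single hop), merged into the measured pairs, and every pair is
then labelled with a DTI class derived from the compound's maximum clinical
phase.  Pairs that are neither curated nor hit a therapeutic target (NDT)
are discarded.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from ctipairs.assembly import map_to_parent
from ctipairs.errors import DataError

#: Admissible (source target type, relationship, related target type)
#: triples for target expansion.
RELATION_WHITELIST = frozenset(
    {
        ("PROTEIN FAMILY", "SUPERSET OF", "SINGLE PROTEIN"),
        ("PROTEIN COMPLEX", "SUPERSET OF", "SINGLE PROTEIN"),
        ("PROTEIN COMPLEX GROUP", "SUPERSET OF", "SINGLE PROTEIN"),
        ("SINGLE PROTEIN", "EQUIVALENT TO", "SINGLE PROTEIN"),
        ("CHIMERIC PROTEIN", "SUPERSET OF", "SINGLE PROTEIN"),
        ("PROTEIN-PROTEIN INTERACTION", "SUPERSET OF", "SINGLE PROTEIN"),
    }
)

DTI_CLASSES = ("D_DT", "C3_DT", "C2_DT", "C1_DT", "C0_DT", "DT", "NDT")
CANDIDATE_CLASSES = ("C3_DT", "C2_DT", "C1_DT", "C0_DT")

#: Release after which the clinical-phase coding changed (0 replaced by
#: 0.5 / -1 / NULL for sub-phase-1 compounds).
PHASE_CODING_CHANGE_RELEASE = 32


def _norm(label) -> str | None:
    return None if label is None or pd.isna(label) else str(label).strip().upper()


def build_expansion_map(relations: pd.DataFrame) -> dict[int, set[int]]:
    """tid -> related tids reachable by one whitelisted relation."""
    expansion: dict[int, set[int]] = {}
    for row in relations.itertuples():
        triple = (
            _norm(row.target_type),
            _norm(row.relationship),
            _norm(row.related_type),
        )
        if triple in RELATION_WHITELIST:
            expansion.setdefault(int(row.tid), set()).add(int(row.related_tid))
    return expansion


def expand_targets(tid: int, expansion: Mapping[int, set[int]]) -> set[int]:
    """Original target plus single-hop whitelisted relatives."""
    return {tid} | set(expansion.get(tid, ()))


def merge_mechanism_pairs(
    pairs: pd.DataFrame,
    mechanisms: pd.DataFrame,
    expansion: Mapping[int, set[int]],
    parent_map: Mapping[int, int],
) -> tuple[pd.DataFrame, set[int]]:
    """Flag curated pairs and append the unmeasured ones.

    Only mechanism rows with ``disease_efficacy == 1`` count.  Each curated
    (compound, target) pair is parent-mapped and target-expanded; existing
    pairs get ``in_dm_table = True``, missing ones are appended with all
    aggregate fields absent.  Returns the merged pair table and the set of
    therapeutic targets (all expanded mechanism targets).
    """
    relevant = mechanisms[mechanisms["disease_efficacy"] == 1]
    mech_pairs: set[tuple[int, int]] = set()
    therapeutic_targets: set[int] = set()
    for row in relevant.itertuples():
        if pd.isna(row.molregno) or pd.isna(row.tid):
            continue
        parent = map_to_parent(int(row.molregno), parent_map)
        for tid in expand_targets(int(row.tid), expansion):
            mech_pairs.add((parent, tid))
            therapeutic_targets.add(tid)

    merged = pairs.copy()
    existing = set(
        zip(merged["parent_molregno"].astype(int), merged["tid"].astype(int))
    )
    merged["in_dm_table"] = [
        key in mech_pairs for key in zip(merged["parent_molregno"], merged["tid"])
    ]
    new_keys = sorted(mech_pairs - existing)
    if new_keys:
        appended = pd.DataFrame(new_keys, columns=["parent_molregno", "tid"])
        appended["in_dm_table"] = True
        merged = pd.concat([merged, appended], ignore_index=True)
        merged["parent_molregno"] = merged["parent_molregno"].astype(np.int64)
        merged["tid"] = merged["tid"].astype(np.int64)
    return merged, therapeutic_targets


def _sub_phase_codes(release: int | None) -> set:
    # Unknown release assumes the current coding.
    if release is not None and release < PHASE_CODING_CHANGE_RELEASE:
        return {0.0, None}
    return {0.5, -1.0, None}


def assign_dti(
    in_dm_table: bool,
    max_phase,
    target_is_therapeutic: bool,
    release: int | None = None,
) -> str:
    """DTI class for a single pair.

    Curated pairs are graded by the compound's maximum clinical phase
    (4 -> D_DT, 3/2/1 -> C3/C2/C1_DT, below phase 1 -> C0_DT, with the
    sub-phase-1 codes depending on the release).  Non-curated pairs are DT
    on therapeutic targets and NDT otherwise.
    """
    if not in_dm_table:
        return "DT" if target_is_therapeutic else "NDT"
    phase = None if max_phase is None or pd.isna(max_phase) else float(max_phase)
    if phase in (4.0, 3.0, 2.0, 1.0):
        return {4.0: "D_DT", 3.0: "C3_DT", 2.0: "C2_DT", 1.0: "C1_DT"}[phase]
    if phase in _sub_phase_codes(release):
        return "C0_DT"
    raise DataError(f"unknown max_phase code: {max_phase!r}")


def assign_dti_classes(
    pairs: pd.DataFrame,
    max_phase_by_parent: Mapping[int, float],
    therapeutic_targets: Iterable[int],
    release: int | None = None,
) -> pd.DataFrame:
    """Attach ``max_phase`` and ``DTI`` columns and drop NDT pairs."""
    therapeutic = set(therapeutic_targets)
    out = pairs.copy()
    out["max_phase"] = [
        max_phase_by_parent.get(int(parent)) for parent in out["parent_molregno"]
    ]
    out["DTI"] = [
        assign_dti(bool(in_dm), phase, int(tid) in therapeutic, release)
        for in_dm, phase, tid in zip(out["in_dm_table"], out["max_phase"], out["tid"])
    ]
    return out[out["DTI"] != "NDT"].reset_index(drop=True)
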