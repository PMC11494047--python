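"""Brute-force ground truth for fixture stores.

Recomputes the expected pipeline output from raw table rows with plain
nested loops and the :mod:`statistics` module.  Deliberately shares no code
with the pipeline modules: this is the independent reference the pipeline
is tested against.
"""

from __future__ import annotations

import sqlite3
import statistics
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class FixtureTruth:
    """Expected outputs for one store, keyed by (parent, tid)."""

    pairs: dict[tuple[int, int], dict] = field(default_factory=dict)
    removal: dict[str, int] = field(default_factory=dict)
    flags: dict[tuple[int, int], dict[str, bool]] = field(default_factory=dict)
    stats: dict[str, dict[str, int]] = field(default_factory=dict)
    multiclass_tids: set[int] = field(default_factory=set)
    compound_first_year: dict[int, int] = field(default_factory=dict)


def _rows(conn: sqlite3.Connection, table: str) -> list[dict]:
    cursor = conn.execute(f"SELECT * FROM {table}")
    columns = [d[0].lower() for d in cursor.description]
    return [dict(zip(columns, row)) for row in cursor.fetchall()]


_WHITELIST = {
    ("PROTEIN FAMILY", "SUPERSET OF", "SINGLE PROTEIN"),
    ("PROTEIN COMPLEX", "SUPERSET OF", "SINGLE PROTEIN"),
    ("PROTEIN COMPLEX GROUP", "SUPERSET OF", "SINGLE PROTEIN"),
    ("SINGLE PROTEIN", "EQUIVALENT TO", "SINGLE PROTEIN"),
    ("CHIMERIC PROTEIN", "SUPERSET OF", "SINGLE PROTEIN"),
    ("PROTEIN-PROTEIN INTERACTION", "SUPERSET OF", "SINGLE PROTEIN"),
}


def compute_truth(
    store_path: Path | str,
    literature_only: bool = True,
    release: int | None = 32,
    threshold: int = 100,
) -> FixtureTruth:
    """Naively recompute the expected dataset for a store."""
    conn = sqlite3.connect(f"file:{Path(store_path)}?mode=ro", uri=True)
    try:
        activities = _rows(conn, "ACTIVITIES")
        assays = {a["assay_id"]: a for a in _rows(conn, "ASSAYS")}
        docs = {d["doc_id"]: d for d in _rows(conn, "DOCS")}
        hierarchy = _rows(conn, "MOLECULE_HIERARCHY")
        dictionary = {m["molregno"]: m for m in _rows(conn, "MOLECULE_DICTIONARY")}
        mechanisms = _rows(conn, "DRUG_MECHANISM")
        relations = _rows(conn, "TARGET_RELATIONS")
        targets = {t["tid"]: t for t in _rows(conn, "TARGET_DICTIONARY")}
        structures = {s["molregno"]: s for s in _rows(conn, "COMPOUND_STRUCTURES")}
        components = _rows(conn, "TARGET_COMPONENTS")
        component_classes = _rows(conn, "COMPONENT_CLASS")
        class_nodes = {
            c["protein_class_id"]: c for c in _rows(conn, "PROTEIN_CLASSIFICATION")
        }
    finally:
        conn.close()

    parent_of: dict[int, int] = {}
    for row in hierarchy:
        if row["parent_molregno"] is not None:
            parent_of[row["molregno"]] = row["parent_molregno"]

    # -- qualifying activity records ------------------------------------
    qualifying = []
    for act in activities:
        assay = assays.get(act["assay_id"])
        if assay is None:
            continue
        if assay["assay_type"] not in ("B", "F"):
            continue
        if act["pchembl_value"] is None or act["pchembl_value"] <= 0:
            continue
        if act["potential_duplicate"] != 0:
            continue
        comment = act["data_validity_comment"]
        if comment is not None and comment != "Manually validated":
            continue
        if assay["tid"] == 22226:
            continue
        if literature_only and act["src_id"] != 1:
            continue
        doc = docs.get(act["doc_id"])
        qualifying.append(
            {
                "parent": parent_of.get(act["molregno"], act["molregno"]),
                "tid": assay["tid"],
                "variant_id": assay["variant_id"],
                "assay_type": assay["assay_type"],
                "pchembl": act["pchembl_value"],
                "year": doc["year"] if doc else None,
            }
        )

    # -- per-pair aggregates --------------------------------------------
    truth = FixtureTruth()
    pair_keys = sorted({(q["parent"], q["tid"]) for q in qualifying})
    for parent, tid in pair_keys:
        entry: dict = {"in_dm_table": False}
        for domain, types in (("BF", ("B", "F")), ("B", ("B",))):
            recs = [
                q
                for q in qualifying
                if q["parent"] == parent and q["tid"] == tid and q["assay_type"] in types
            ]
            values = [q["pchembl"] for q in recs]
            years = [q["year"] for q in recs if q["year"] is not None]
            years_w = [
                q["year"]
                for q in recs
                if q["year"] is not None and q["pchembl"] is not None
            ]
            entry[f"pchembl_value_mean_{domain}"] = (
                statistics.mean(values) if values else None
            )
            entry[f"pchembl_value_median_{domain}"] = (
                statistics.median(values) if values else None
            )
            entry[f"pchembl_value_max_{domain}"] = max(values) if values else None
            entry[f"first_publication_cpd_target_pair_{domain}"] = (
                min(years) if years else None
            )
            entry[f"first_publication_cpd_target_pair_w_pchembl_{domain}"] = (
                min(years_w) if years_w else None
            )
        truth.pairs[(parent, tid)] = entry

    for q in qualifying:
        if q["year"] is None:
            continue
        current = truth.compound_first_year.get(q["parent"])
        if current is None or q["year"] < current:
            truth.compound_first_year[q["parent"]] = q["year"]

    # -- mechanism merge and DTI ----------------------------------------
    def expanded(tid: int) -> set[int]:
        out = {tid}
        for rel in relations:
            if rel["tid"] != tid:
                continue
            src = targets.get(rel["tid"], {}).get("target_type")
            dst = targets.get(rel["related_tid"], {}).get("target_type")
            rel_label = rel["relationship"]
            norm = tuple(
                x.strip().upper() if isinstance(x, str) else None
                for x in (src, rel_label, dst)
            )
            if norm in _WHITELIST:
                out.add(rel["related_tid"])
        return out

    therapeutic: set[int] = set()
    mech_pairs: set[tuple[int, int]] = set()
    for mech in mechanisms:
        if mech["disease_efficacy"] != 1:
            continue
        if mech["molregno"] is None or mech["tid"] is None:
            continue
        parent = parent_of.get(mech["molregno"], mech["molregno"])
        for tid in expanded(mech["tid"]):
            mech_pairs.add((parent, tid))
            therapeutic.add(tid)

    for key in mech_pairs:
        if key in truth.pairs:
            truth.pairs[key]["in_dm_table"] = True
        else:
            entry = {"in_dm_table": True}
            for domain in ("BF", "B"):
                for stem in (
                    "pchembl_value_mean",
                    "pchembl_value_median",
                    "pchembl_value_max",
                    "first_publication_cpd_target_pair",
                    "first_publication_cpd_target_pair_w_pchembl",
                ):
                    entry[f"{stem}_{domain}"] = None
            truth.pairs[key] = entry

    legacy = release is not None and release < 32
    sub_phase = {0.0, None} if legacy else {0.5, -1.0, None}
    for (parent, tid), entry in list(truth.pairs.items()):
        phase = dictionary.get(parent, {}).get("max_phase")
        phase = float(phase) if phase is not None else None
        entry["max_phase"] = phase
        if entry["in_dm_table"]:
            if phase == 4.0:
                dti = "D_DT"
            elif phase in (3.0, 2.0, 1.0):
                dti = f"C{int(phase)}_DT"
            elif phase in sub_phase:
                dti = "C0_DT"
            else:
                dti = "INVALID"
        else:
            dti = "DT" if tid in therapeutic else "NDT"
        entry["DTI"] = dti
        if dti == "NDT":
            del truth.pairs[(parent, tid)]

    # -- structure-based compound removal -------------------------------
    removed_missing: set[int] = set()
    removed_mixture: set[int] = set()
    for parent, tid in list(truth.pairs):
        structure = structures.get(parent)
        smiles = structure["canonical_smiles"] if structure else None
        if smiles is None:
            removed_missing.add(parent)
            del truth.pairs[(parent, tid)]
        elif "." in smiles:
            removed_mixture.add(parent)
            del truth.pairs[(parent, tid)]
    truth.removal = {
        "missing_smiles": len(removed_missing),
        "mixture_smiles": len(removed_mixture),
    }

    # -- subset flags ----------------------------------------------------
    drug_targets = {tid for (_, tid), e in truth.pairs.items() if e["DTI"] == "D_DT"}
    candidate_targets = {
        tid
        for (_, tid), e in truth.pairs.items()
        if e["DTI"] in ("C3_DT", "C2_DT", "C1_DT", "C0_DT")
    }
    for domain in ("BF", "B"):
        per_target: dict[int, set[int]] = {}
        for (parent, tid), entry in truth.pairs.items():
            if entry[f"pchembl_value_max_{domain}"] is not None:
                per_target.setdefault(tid, set()).add(parent)
        qualifying_tids = {
            tid for tid, parents in per_target.items() if len(parents) >= threshold
        }
        for key in truth.pairs:
            tid = key[1]
            flags = truth.flags.setdefault(key, {})
            base = tid in qualifying_tids
            flags[f"{domain}_100"] = base
            flags[f"{domain}_100_c_dt_d_dt"] = base and (
                tid in drug_targets or tid in candidate_targets
            )
            flags[f"{domain}_100_d_dt"] = base and tid in drug_targets
            flags[f"{domain}_100_c_dt"] = base and tid in candidate_targets
    for key in truth.pairs:
        truth.flags.setdefault(key, {})

    # -- statistics ------------------------------------------------------
    variant_keys: dict[tuple[int, int], set] = {}
    for q in qualifying:
        variant_keys.setdefault((q["parent"], q["tid"]), set()).add(q["variant_id"])
    groups = {
        "total": lambda dti: True,
        "comparator": lambda dti: dti == "DT",
        "drugs": lambda dti: dti == "D_DT",
        "candidates": lambda dti: dti in ("C3_DT", "C2_DT", "C1_DT", "C0_DT"),
    }
    for group, member in groups.items():
        keys = [key for key, e in truth.pairs.items() if member(e["DTI"])]
        pair_variants = set()
        target_variants = set()
        for parent, tid in keys:
            for variant in variant_keys.get((parent, tid), {None}):
                pair_variants.add((parent, tid, variant))
                target_variants.add((tid, variant))
        truth.stats[group] = {
            "n_pairs": len(keys),
            "n_pairs_incl_variants": len(pair_variants),
            "n_compounds": len({parent for parent, _ in keys}),
            "n_targets": len({tid for _, tid in keys}),
            "n_targets_incl_variants": len(target_variants),
        }

    # -- multi-class targets among dataset targets ----------------------
    def ancestor(class_id, level):
        seen = set()
        while class_id is not None and class_id in class_nodes and class_id not in seen:
            seen.add(class_id)
            node = class_nodes[class_id]
            if node["class_level"] == level:
                return node["pref_name"]
            class_id = node["parent_id"]
        return None

    class_ids_by_tid: dict[int, set[int]] = {}
    component_to_classes: dict[int, set[int]] = {}
    for row in component_classes:
        component_to_classes.setdefault(row["component_id"], set()).add(
            row["protein_class_id"]
        )
    for row in components:
        for class_id in component_to_classes.get(row["component_id"], ()):
            class_ids_by_tid.setdefault(row["tid"], set()).add(class_id)
    dataset_tids = {tid for _, tid in truth.pairs}
    for tid in dataset_tids:
        l1 = {
            name
            for class_id in class_ids_by_tid.get(tid, ())
            if (name := ancestor(class_id, 1)) is not None
        }
        l2 = {
            name
            for class_id in class_ids_by_tid.get(tid, ())
            if (name := ancestor(class_id, 2)) is not None
        }
        if len(l1) > 1 or len(l2) > 1:
            truth.multiclass_tids.add(tid)

    return truth
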