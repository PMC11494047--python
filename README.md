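# ctipairs

Reproducible extraction of an annotated compound–target pairs dataset from a
ChEMBL-schema SQLite store (ChEMBL release 26 or later).

The pipeline:

1. **Activity extraction** — pChEMBL-bearing activities from binding (B) and
   functional (F) assays, excluding potential duplicates, rows with validity
   comments (other than "Manually validated"), the unchecked-target sentinel
   (TID 22226) and, by default, non-literature sources.
2. **Parent mapping & aggregation** — every molecule is collapsed onto its
   parent compound (salt information dropped); per (parent, target) pair the
   pChEMBL values are aggregated into mean/median/max and first-publication
   years, once over B+F assays (`_BF`) and once over B assays only (`_B`).
3. **Mechanism merge & DTI classes** — curated mechanism rows
   (disease-efficacy = 1) are target-expanded through a six-triple relation
   whitelist (single hop) and merged in; each pair gets a drug–target
   interaction class (`D_DT`, `C3_DT`…`C0_DT`, `DT`), with `NDT` pairs
   discarded. Sub-phase-1 clinical codes are handled per release (`0` up to
   release 31; `0.5`/`-1`/NULL from release 32).
4. **Annotation** — structures (compounds without a SMILES or with a `.` in
   the SMILES are removed and counted), stored physicochemical properties,
   ligand-efficiency metrics (LE = 1.37·pChEMBL/HA, BEI = pChEMBL/MW[kDa],
   SEI = pChEMBL/(PSA/100), LLE = pChEMBL − logP), level-1 ATC codes,
   two-level target classes (multi-label targets reported to a side file),
   and optional RDKit descriptors including Bemis–Murcko scaffolds and
   aromatic-atom counts.
5. **Cleaning & checks** — nullable dtypes, a single missing sentinel,
   4-decimal round-half-even rounding (max_phase exempt), and basic
   consistency checks including expected-missing-count accounting.
6. **Subsets & stats** — boolean filter columns (`BF_100`,
   `BF_100_c_dt_d_dt`, …), per-group statistics (total / comparator /
   drugs / candidates, with and without variant-resolved targets), and
   round-trip-verified delimited output files named
   `ChEMBL<NN>_CTI_<sources>_<subset>.csv`.

A fixture module (`ctipairs.fixtures`) generates miniature deterministic
ChEMBL-schema stores, and `ctipairs.oracle` recomputes the expected output
with independent brute-force loops; the test suite asserts exact agreement
on an edge-case suite plus 20 random seeds.

## CLI

```sh
ctipairs --sqlite /path/to/chembl_32.db -v 32 --output out/ --rdkit --BF --B
```

Options mirror the published parameter contract: `--chembl/-v` (release
number; downloaded via `chembl_downloader` when no `--sqlite/-s` path is
given), `--output/-o` (required), `--delimiter/-d` (default `;`),
`--all_sources`, `--rdkit`, `--excel`, `--BF`, `--B`, `--debug`. The full
dataset is always written; a `run_manifest.json` records release, source
mode, per-stage row counts and check results. The exit status is non-zero
if any validation check fails.

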