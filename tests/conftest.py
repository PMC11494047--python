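import math

import pandas as pd
import pytest

from ctipairs import open_store, run_pipeline, PipelineConfig
from ctipairs.fixtures import FixtureSpec, build_fixture, generate_tables, write_store
from ctipairs.oracle import compute_truth
from ctipairs.subsets import flag_columns

#: Compound-per-target threshold used for fixture-scale runs (the production
#: default of 100 would never trigger on miniature stores).
FIXTURE_THRESHOLD = 3

AGGREGATE_FIELDS = tuple(
    f"{stem}_{domain}"
    for domain in ("BF", "B")
    for stem in (
        "pchembl_value_mean",
        "pchembl_value_median",
        "pchembl_value_max",
        "first_publication_cpd_target_pair",
        "first_publication_cpd_target_pair_w_pchembl",
    )
)


@pytest.fixture
def make_store(tmp_path):
    """Callable building a store file from raw tables or a FixtureSpec."""

    counter = [0]

    def build(tables=None, spec=None):
        counter[0] += 1
        path = tmp_path / f"store_{counter[0]}.db"
        if spec is not None:
            build_fixture(spec, path)
        else:
            write_store(path, tables or {})
        return path

    return build


@pytest.fixture
def run_store(make_store):
    """Callable running the full pipeline on tables or a spec."""

    def run(
        tables=None,
        spec=None,
        release=32,
        threshold=FIXTURE_THRESHOLD,
        rdkit=False,
        literature_only=True,
    ):
        path = make_store(tables=tables, spec=spec)
        config = PipelineConfig(
            literature_only=literature_only,
            calculate_rdkit=rdkit,
            compound_threshold=threshold,
        )
        with open_store(path, release=release) as handle:
            result = run_pipeline(handle, config)
        return result, path

    return run


def _values_match(expected, observed) -> bool:
    if expected is None:
        return pd.isna(observed)
    if pd.isna(observed):
        return False
    if isinstance(expected, float) or isinstance(observed, float):
        return math.isclose(float(expected), float(observed), abs_tol=1e-9)
    return expected == observed


def assert_matches_truth(result, truth, threshold=FIXTURE_THRESHOLD):
    """Pipeline output must equal the brute-force truth, key by key."""
    dataset = result.dataset
    pipeline_keys = set(
        zip(dataset["parent_molregno"].astype(int), dataset["tid"].astype(int))
    )
    assert pipeline_keys == set(truth.pairs), "pair key sets differ"

    indexed = dataset.set_index(["parent_molregno", "tid"])
    for key, expected in truth.pairs.items():
        row = indexed.loc[key]
        for column in AGGREGATE_FIELDS:
            value = expected[column]
            rounded = None if value is None else round(float(value), 4)
            assert _values_match(rounded, row[column]), (
                f"pair {key} column {column}: expected {rounded}, got {row[column]}"
            )
        assert bool(row["in_dm_table"]) == expected["in_dm_table"], key
        assert _values_match(expected["max_phase"], row["max_phase"]), key
        assert row["DTI"] == expected["DTI"], key
        for flag in flag_columns():
            assert bool(row[flag]) == truth.flags[key][flag], (key, flag)

    assert result.removal_report == truth.removal

    stats = result.stats.set_index("group")
    for group, expected_stats in truth.stats.items():
        for metric, value in expected_stats.items():
            assert int(stats.loc[group, metric]) == value, (group, metric)

    report_tids = set(result.multiclass_report["tid"].astype(int))
    assert report_tids == truth.multiclass_tids


@pytest.fixture
def truth_checker():
    def check(result, store_path, release=32, threshold=FIXTURE_THRESHOLD,
              literature_only=True):
        truth = compute_truth(
            store_path,
            literature_only=literature_only,
            release=release,
            threshold=threshold,
        )
        assert_matches_truth(result, truth, threshold=threshold)
        return truth

    return check


@pytest.fixture
def random_spec():
    def make(seed, **overrides):
        return FixtureSpec(seed=seed, **overrides)

    return make


__all__ = [
    "FIXTURE_THRESHOLD",
    "AGGREGATE_FIELDS",
    "assert_matches_truth",
    "generate_tables",
]
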