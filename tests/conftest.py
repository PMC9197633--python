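import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from updrs_abbrev import AssessmentTable, ItemSet, SimConfig, build_registry, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_table(registry):
    """A 500-record synthetic cohort shared by oracle-equivalence tests."""
    return generate(SimConfig(n_records=500, seed=11), registry)


def make_table(registry, ratings: dict[str, list[int]], n: int | None = None):
    """Build an AssessmentTable from explicit per-field rating columns.

    Fields not listed default to zero; lengths must agree.
    """
    lengths = {len(v) for v in ratings.values()}
    if n is None:
        (n,) = lengths or {1}
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "visit_id": "v1",
    })
    for rf in registry.rating_fields:
        df[rf] = np.asarray(ratings.get(rf, [0] * n), dtype=float)
    return AssessmentTable(df=df, registry=registry, provenance="fixture")


@pytest.fixture
def table_factory(registry):
    def _make(ratings, n=None):
        return make_table(registry, ratings, n)
    return _make


#: planted-recovery study conditions: a 20-item single-rating pool spanning
#: parts 1 and 2, four planted items given a loading boost that makes their
#: subset-sum R-squared maximal in the population.
PLANTED_SUBSET = ("1.2", "1.9", "2.3", "2.8")
PLANTED_POOL = tuple(f"1.{i}" for i in range(1, 11)) + tuple(
    f"2.{i}" for i in range(1, 11)
)


def planted_config(seed: int, n_records: int = 2000) -> SimConfig:
    return SimConfig(
        n_records=n_records,
        seed=seed,
        loading_range=(0.2, 0.45),
        planted_subset=ItemSet(PLANTED_SUBSET),
        planted_boost=0.55,
    )


@pytest.fixture
def linear_exact_table(registry):
    """Totals lie exactly on y = 2x + 7 where x is item 1.1's rating.

    1.1 carries x in {0..4}; 1.2 mirrors it and 1.3 + 1.4 contribute the
    constant 7, so total = 2x + 7 without leaving the 0-4 rating range.
    """
    x = [0, 1, 2, 3, 4, 0, 2, 4]
    return make_table(registry, {
        "1.1": x,
        "1.2": x,
        "1.3": [4] * len(x),
        "1.4": [3] * len(x),
    }), ItemSet(["1.1"])
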