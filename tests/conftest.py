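"""Shared fixtures: compact synthetic cohorts and a fitted embedding.

Cohort sizes here are deliberately small so the whole suite runs on one CPU
in minutes; the generator's structure (latent progress factor, site factor,
arrest dynamics) is identical at every scale.
"""

import numpy as np
import pytest

import mklabour as m

SMALL = dict(n_static_cont=5, n_static_cat=2, n_dynamic=6)


@pytest.fixture(scope="session")
def small_config():
    return m.SimConfig(n_subjects=80, seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_records(small_config):
    return m.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tables(small_records):
    return m.cohort_to_tables(small_records)


@pytest.fixture(scope="session")
def small_schema(small_config):
    return m.schema_for_config(small_config)


@pytest.fixture(scope="session")
def prepared(small_tables, small_schema):
    """(cohort, train_ids, test_ids, report) for the small cohort."""
    return m.prepare_cohort(small_tables, small_schema, fraction=0.75, seed=11)


@pytest.fixture(scope="session")
def fitted(prepared):
    """Embedding fitted on the small cohort's training partition."""
    cohort, train_ids, _, _ = prepared
    with np.errstate(all="ignore"):
        return m.fit_embedding(cohort, train_ids, n_dims=3, max_alternations=10)


@pytest.fixture(scope="session")
def mid_pipeline():
    """A 250-subject cohort with fitted embedding and trajectory index."""
    cfg = m.SimConfig(n_subjects=250, seed=29, **SMALL)
    tables = m.cohort_to_tables(m.simulate_cohort(cfg))
    schema = m.schema_for_config(cfg)
    cohort, train_ids, test_ids, _ = m.prepare_cohort(tables, schema, fraction=0.8, seed=29)
    results = m.fit_embedding(cohort, train_ids, n_dims=3, max_alternations=10)
    index = m.TrajectoryIndex.from_cohort(results, cohort, train_ids)
    return cohort, train_ids, test_ids, results, index
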