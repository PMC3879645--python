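"""Shared fixtures: synthetic cohorts at two sizes and one full pipeline run.

Everything is generated at test time from seeds; the default cohort matches
the study design (the packaged participant table + 10 blood anchors, contamination on
the five lowest-scoring cases).
"""

import pytest

from dsmeth import pipeline, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.simulate_default_cohort(seed=0)


@pytest.fixture(scope="session")
def default_result(default_cohort):
    c = default_cohort
    return pipeline.run_pipeline(c.beta, c.qc, c.annotation, c.sheet)


@pytest.fixture(scope="session")
def small_cohort():
    """3,000-probe cohort for cheaper per-module checks."""
    return synthetic.simulate_default_cohort(seed=11, n_probes=3000)


@pytest.fixture(scope="session")
def table1():
    return synthetic.fixture_table1()
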