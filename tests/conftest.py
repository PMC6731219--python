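import pytest

import retrocall as rc


@pytest.fixture(scope="session")
def small_config():
    return rc.SyntheticConfig(n_tumors=10, seed=1, germline_panel_size=20)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return rc.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    return rc.call_insertions(
        small_cohort.tumor_pairs, small_cohort.normal_pairs,
        small_cohort.panel_calls, small_cohort.annotation.decoy_contigs)
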