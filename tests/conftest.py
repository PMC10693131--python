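import logging

import pytest

from asthmacast.synthetic import default_truth, make_weekly_table

logging.getLogger("asthmacast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def weekly_table():
    """Five simulated years under the default study conditions (shared across
    tests; treat as read-only)."""
    table, truth = make_weekly_table(range(2015, 2020), default_truth(), seed=7)
    return table, truth


@pytest.fixture(scope="session")
def short_table():
    """Three simulated years — the minimum for one walk-forward fold."""
    table, truth = make_weekly_table(range(2015, 2018), default_truth(), seed=7)
    return table, truth
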