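import numpy as np
import pytest

import hazglm as hg
from hazglm.synthetic import Scenario, simulate_tte

# reference individual-level sample: (time years, event)
SAMPLE_RECORDS = [
    (0.0219, 0),
    (0.1973, 1),
    (1.9562, 1),
    (1.9644, 0),
    (6.7288, 1),
    (7.2849, 0),
]

# worked-example life-table rows: (month start, n, events, censorings, at_risk, hazard 3dp)
WORKED_LIFETABLE = [
    (0, 686, 0, 7, 682.5, 0.0),
    (1, 679, 0, 3, 677.5, 0.0),
    (2, 676, 1, 4, 674.0, 0.001),
    (22, 477, 5, 3, 475.5, 0.011),
    (23, 469, 7, 4, 467.0, 0.015),
    (24, 458, 8, 12, 452.0, 0.018),
    (87, 1, 0, 1, 0.5, 0.0),
]


@pytest.fixture
def sample_records():
    return [hg.SubjectRecord(t, e) for t, e in SAMPLE_RECORDS]


@pytest.fixture(scope="session")
def gbsg_records():
    return hg.gbsg_like(seed=0)


@pytest.fixture(scope="session")
def gbsg_lifetable(gbsg_records):
    return hg.build_lifetable(gbsg_records)


@pytest.fixture(scope="session")
def constant_lifetable():
    """Life table from a large constant-hazard cohort (rate 0.2 / year)."""
    recs = simulate_tte(Scenario("constant", {"rate": 0.2}, n=4000, admin_censor=6.0), seed=3)
    return hg.build_lifetable(recs)
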