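import numpy as np
import pytest

from flucto.evaluation import EvalConfig, loso_evaluation
from flucto.synthetic_data import CohortSpec, generate_cohort

#: The 24 published per-subject change distributions with the severity call
#: and percentages the decision rule printed for them (None = N/A).  The
#: last four subjects never reached the ON state (ground truth INC).
TABLE3_ROWS = [
    # (subject, (d0, d1, d2, d3), S, (p0, p1, p2, p3))
    (1, (5, 0, 2, 8), 3, (None, 0, 20, 80)),
    (2, (4, 4, 2, 0), 1, (None, 67, 33, 0)),
    (3, (14, 1, 0, 0), 0, (100, None, None, None)),
    (4, (4, 0, 4, 2), 2, (None, 0, 67, 33)),
    (5, (3, 2, 5, 0), 2, (None, 29, 71, 0)),
    (6, (2, 6, 2, 0), 1, (None, 75, 25, 0)),
    (7, (4, 0, 2, 4), 3, (None, 0, 33, 67)),
    (8, (3, 7, 0, 0), 1, (None, 100, 0, 0)),
    (9, (2, 1, 0, 3), 3, (None, 25, 0, 75)),
    (10, (6, 1, 2, 1), 2, (None, 25, 50, 25)),
    (11, (4, 0, 6, 0), 2, (None, 0, 100, 0)),
    (12, (2, 2, 2, 4), 3, (None, 25, 25, 50)),
    (13, (369, 28, 15, 84), 3, (None, 22, 12, 66)),
    (14, (378, 101, 17, 0), 1, (None, 86, 14, 0)),
    (15, (347, 3, 1, 0), 0, (100, None, None, None)),
    (16, (593, 1, 1, 0), 0, (100, None, None, None)),
    (17, (408, 20, 38, 95), 3, (None, 13, 25, 62)),
    (18, (258, 27, 66, 0), 2, (None, 29, 71, 0)),
    (19, (395, 89, 44, 0), 1, (None, 67, 33, 0)),
    (20, (351, 10, 31, 73), 3, (None, 9, 27, 64)),
    (21, (214, 51, 8, 3), "INC", (None, None, None, None)),
    (22, (13, 2, 0, 0), 0, (100, None, None, None)),
    (23, (8, 0, 2, 0), "INC", (None, None, None, None)),
    (24, (7, 2, 1, 0), 1, (None, 67, 33, 0)),
]


@pytest.fixture(scope="session")
def table3_rows():
    return TABLE3_ROWS


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort: one subject per class, short rounds."""
    spec = CohortSpec(
        n_per_class=(1, 1, 1, 1),
        rounds_range=(3, 3),
        rounds_weights=None,
        timeline_rounds_range=(4, 4),
        round_duration_s=40.0,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_loso(tiny_cohort):
    return loso_evaluation(tiny_cohort, EvalConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
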