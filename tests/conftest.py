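import numpy as np
import pandas as pd
import pytest

import retrocal as rc


@pytest.fixture(scope="session")
def table1():
    return rc.table1_fixture()


def make_two_condition_study(
    diffs,
    bases=None,
    standard_scores=(1.0, 0.0),
    study_id="study",
    date="2020-01",
    method="M",
):
    """Build a balanced two-condition StudyData from per-subject condition
    differences (high-standard minus low-standard) and optional baselines."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    bases = np.zeros(n) if bases is None else np.asarray(bases, dtype=float)
    hi, lo = standard_scores
    rows = []
    for j in range(n):
        rows.append(dict(subject=f"s{j}", condition="hi", standard_score=hi,
                         method=method, measured_score=bases[j] + diffs[j]))
        rows.append(dict(subject=f"s{j}", condition="lo", standard_score=lo,
                         method=method, measured_score=bases[j]))
    return rc.StudyData(study_id, date, pd.DataFrame(rows))


@pytest.fixture
def tiny_study():
    """Three subjects, two conditions, within-subject differences 1, 2, 3
    against standard scores 1 and 0 — the hand-checkable paired design."""
    return make_two_condition_study([1.0, 2.0, 3.0], bases=[10.0, 20.0, 30.0])
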