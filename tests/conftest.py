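import numpy as np
import pandas as pd
import pytest

from cueuse import preprocessing, synthetic_data


@pytest.fixture(scope="session")
def tiny_cohort() -> pd.DataFrame:
    """Small mixed cohort (6 trackers / 2 followers) with full schedules."""
    spec = synthetic_data.CohortSpec(n_trackers=6, n_followers=2, seed=11)
    return synthetic_data.simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_prep(tiny_cohort):
    return preprocessing.preprocess(tiny_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_summaries(responses: dict, subjects=None) -> pd.DataFrame:
    """Build a 12-cell summary table from a {(p, config): value} pattern.

    ``responses`` may give scalars (same for all subjects) or callables
    ``f(subject) -> value``.
    """
    from cueuse.encoding_models import SPATIAL_PROBS, VALUE_LABELS

    subjects = subjects if subjects is not None else range(4)
    rows = []
    for s in subjects:
        for p in SPATIAL_PROBS:
            for v in VALUE_LABELS:
                val = responses[(p, v)]
                rt = val(s) if callable(val) else val
                rows.append(
                    dict(subject=s, p_tgt=p, value_config=v, median_rt=rt,
                         accuracy=0.8, inverse_efficiency=rt / 0.8)
                )
    return pd.DataFrame(rows)
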