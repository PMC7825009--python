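import numpy as np
import pandas as pd
import pytest

import metpath as mp


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 features, fully observed."""
    values = pd.DataFrame(
        [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
        index=["s1", "s2", "s3"],
        columns=["Glucose", "Lactate"],
    )
    return mp.MetaboliteMatrix(values)


@pytest.fixture(scope="session")
def class_dataset():
    """Case/control dataset with two dysregulated pathways."""
    spec = mp.SynthSpec(
        n_controls=40,
        n_cases=40,
        n_metabolites=60,
        pathways=mp.default_pathways(10, 6, 60),
        effect_pathways={"PW00": 2.0, "PW01": 2.0},
        seed=7,
    )
    matrix, db, labels = mp.gen_classification_dataset(spec)
    return matrix, db, labels


@pytest.fixture(scope="session")
def surv_dataset():
    """Pathway-level survival dataset: 2 of 30 pathways carry hazard."""
    spec = mp.SynthSpec(
        n_controls=100,
        n_cases=100,
        n_metabolites=120,
        pathways=mp.default_pathways(30, 4, 120),
        survival=mp.SurvivalSpec(
            beta={"PW00": 1.0, "PW01": 1.0}, baseline_rate=0.1, censoring_fraction=0.2
        ),
        seed=11,
    )
    return mp.gen_survival_dataset(spec)


def make_surv(times, events):
    times = np.asarray(times, dtype=float)
    return mp.SurvivalData([f"s{i}" for i in range(len(times))], times, np.asarray(events))
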