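import numpy as np
import pandas as pd
import pytest

import stresstraj as st

TOY_EFFECTS = {("reg01", b): 0.3 for b in range(6, 11)}


@pytest.fixture(scope="session")
def toy_atlas():
    return st.RoiAtlas.toy(4)


@pytest.fixture(scope="session")
def compact_design():
    return st.TaskDesign.compact()


@pytest.fixture(scope="session")
def toy_cohort(toy_atlas, compact_design):
    """Small full-pipeline cohort: 14 subjects, 4 ROIs, compact design."""
    spec = st.CohortSpec(n_female=8, n_male=6, seed=7,
                         effect_activation=TOY_EFFECTS)
    return st.simulate_cohort(spec, design=compact_design, atlas=toy_atlas)


@pytest.fixture(scope="session")
def toy_concats(toy_cohort):
    return st.preprocess_and_concatenate(toy_cohort.timeseries)


@pytest.fixture(scope="session")
def toy_edges(toy_cohort, toy_concats):
    return st.fit_all_edges(toy_concats, toy_cohort.atlas,
                            toy_cohort.design)


def make_prediction_data(n=120, p=24, seed=0, signal_col=None, signal_r=0.0):
    """Feature matrix + participants table with an optional planted feature."""
    rng = np.random.default_rng(seed)
    y = rng.normal(24.0, 4.0, n)
    X = rng.standard_normal((n, p))
    if signal_col is not None:
        z = (y - y.mean()) / y.std()
        X[:, signal_col] = (signal_r * z
                            + np.sqrt(max(1 - signal_r ** 2, 0.0))
                            * rng.standard_normal(n))
    ids = [f"s{i:03d}" for i in range(n)]
    fm = st.FeatureMatrix(pd.DataFrame(
        X, index=ids, columns=[f"act|reg{j:02d}|block01" for j in range(p)]))
    part = pd.DataFrame({
        "participant_id": ids, "bmi": y,
        "sex": np.where(rng.random(n) < 0.6, "female", "male"),
        "age": rng.normal(35, 10, n),
        "diagnosis": rng.random(n) < 0.4,
        "pretask_responder": rng.random(n) < 0.16,
        "log_mean_fd": rng.normal(-1.6, 0.3, n),
        "medication": rng.random(n) < 0.05,
    })
    return fm, part
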