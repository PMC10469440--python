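import numpy as np
import pandas as pd
import pytest

from metaboicc import FeatureSpec, StudyDesign, simulate_study
from metaboicc.model import MCMCSettings
from metaboicc.tables import FeatureTable


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(deterministic_repeats=True)


@pytest.fixture(scope="session")
def small_study():
    """A small but structured simulated study: 2 centers, replicates, no censoring."""
    design = StudyDesign(center_sizes=(20, 20), repeat_fraction=1.0)
    spec = FeatureSpec(
        n_features=3,
        sigma2_within=0.5,
        sigma2_subject=0.5,
        sigma2_center=0.1,
        detection_rate=1.0,
    )
    return simulate_study(design, spec, seed=42)


@pytest.fixture
def fast_mcmc():
    return MCMCSettings(iterations=600, chains=2, seed=0)


def make_table(values: np.ndarray, feature_ids=None, sample_ids=None, **feat_cols):
    """Helper: wrap a 2-D array (samples x features) into a FeatureTable."""
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    feature_ids = feature_ids or [f"F{j + 1:03d}" for j in range(f)]
    sample_ids = sample_ids or [f"s{i + 1:03d}" for i in range(n)]
    feats = None
    if feat_cols:
        feats = pd.DataFrame(feat_cols, index=pd.Index(feature_ids, name="feature_id"))
    return FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids), feats)
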