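import numpy as np
import pandas as pd
import pytest

import msprog as mp
from msprog.pipeline import registry_tables


@pytest.fixture(scope="session")
def small_config():
    return mp.SimConfig(n_patients=600, seed=7)


@pytest.fixture(scope="session")
def small_registry(small_config):
    return mp.simulate_registry(small_config)


@pytest.fixture(scope="session")
def small_tables(small_registry):
    return registry_tables(small_registry)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    """Case-found, exclusion-filtered cohort with features and labels."""
    import msprog.cohort_features as cf

    cases = cf.find_cases(
        small_tables["prescriptions"], small_tables["admissions"], small_tables["outpatients"]
    )
    included, report = cf.apply_exclusions(cases, small_tables["demographics"])
    features = cf.build_features(included, small_tables)
    labels = cf.label_cohort(features, small_tables["clinical_edss"])
    return {"included": included, "report": report, "features": features, "labels": labels}


def gaussian_classes(n: int, separation: float, seed: int = 0, mix=(0.09, 0.62, 0.29)):
    """Three Gaussian clouds in 5 dimensions, ``separation`` sds apart along
    a shared axis; separation 0 makes the classes indistinguishable."""
    rng = np.random.default_rng(seed)
    y = rng.choice(3, size=n, p=mix)
    X = rng.standard_normal((n, 5))
    X[:, 0] += separation * y
    X[:, 1] -= 0.5 * separation * y
    feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    labels = pd.Series(np.array(["C1", "C2", "C3"])[y])
    return feats, labels
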