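import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import acpdesign as a

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# The shortest of the experimentally active designed peptides: high
# hydrophobic moment, 180-degree hydrophobic face, eight positive charges.
AMPHIARC2 = "KIFKKFKTIIKKVWRIFGRF"


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic labeled dataset (fast; for unit tests)."""
    return a.make_fixture(a.FixtureSpec(n_pos=60, n_neg=60, seed=7))


@pytest.fixture(scope="session")
def small_results(small_dataset):
    """Classifier fitted without feature elimination (fast path)."""
    clf = a.AcpClassifier(
        small_dataset, select_features=False, cv_folds=5, seed=7
    )
    return clf.fit()


def toy_dataset(X: np.ndarray, y, names=None) -> a.LabeledDataset:
    """LabeledDataset wrapper around a plain feature matrix (no peptides)."""
    X = np.asarray(X, float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return a.LabeledDataset(
        peptides=[a.Peptide(f"p{i}", "A") for i in range(len(X))],
        labels=np.asarray(y, int),
        X=pd.DataFrame(X, columns=names),
    )
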