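import numpy as np
import pytest

from drugfuse import AssociationMatrix, BinaryProfileMatrix, SimilarityMatrix


def make_sim(values, label="sim"):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"d{i}" for i in range(values.shape[0]))
    return SimilarityMatrix(ids, values, label)


def random_sim(rng, n, label="sim"):
    """Random symmetric similarity in [0,1] with unit diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return make_sim(m, label)


def make_assoc(values, drug_ids=None):
    values = np.asarray(values)
    if drug_ids is None:
        drug_ids = tuple(f"d{i}" for i in range(values.shape[0]))
    diseases = tuple(f"x{j}" for j in range(values.shape[1]))
    return AssociationMatrix(drug_ids, diseases, values)


def make_profiles(values, space_label="other"):
    values = np.asarray(values)
    ids = tuple(f"d{i}" for i in range(values.shape[0]))
    feats = tuple(f"f{j}" for j in range(values.shape[1]))
    return BinaryProfileMatrix(ids, feats, values, space_label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
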