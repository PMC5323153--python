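import numpy as np
import pytest

from mdinfer import AssociationMatrix, SimilarityMatrix, normalize


def write_tsv(path, rows):
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t".join(str(f) for f in row) + "\n")
    return path


def random_similarity(rng, n, ids=None):
    """Random symmetric nonnegative similarity with unit diagonal."""
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids or [f"x{i}" for i in range(n)], values)


def random_instance(rng, nm, nd, density=0.4):
    """Random (normalized SM, normalized SD, A) triple with nonzero A."""
    smn = normalize(random_similarity(rng, nm, [f"m{i}" for i in range(nm)]))
    sdn = normalize(random_similarity(rng, nd, [f"d{j}" for j in range(nd)]))
    values = (rng.random((nm, nd)) < density).astype(float)
    if values.sum() == 0:
        values[rng.integers(nm), rng.integers(nd)] = 1.0
    assoc = AssociationMatrix(
        [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)], values
    )
    return smn, sdn, assoc


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_assoc():
    """2x2 matrix with known pairs (m1,d1), (m2,d2), (m1,d2)."""
    return AssociationMatrix(
        ["m1", "m2"], ["d1", "d2"], np.array([[1.0, 1.0], [0.0, 1.0]])
    )
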