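import numpy as np
import pytest


def horn_quaternion_rmsd(A, B):
    """Closed-form optimal-superposition RMSD via the Horn quaternion method.

    Independent of the package's SVD-based implementation; used as an oracle.
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    S = A.T @ B
    K = np.empty((4, 4))
    K[0, 0] = S[0, 0] + S[1, 1] + S[2, 2]
    K[0, 1] = K[1, 0] = S[1, 2] - S[2, 1]
    K[0, 2] = K[2, 0] = S[2, 0] - S[0, 2]
    K[0, 3] = K[3, 0] = S[0, 1] - S[1, 0]
    K[1, 1] = S[0, 0] - S[1, 1] - S[2, 2]
    K[1, 2] = K[2, 1] = S[0, 1] + S[1, 0]
    K[1, 3] = K[3, 1] = S[0, 2] + S[2, 0]
    K[2, 2] = -S[0, 0] + S[1, 1] - S[2, 2]
    K[2, 3] = K[3, 2] = S[1, 2] + S[2, 1]
    K[3, 3] = -S[0, 0] - S[1, 1] + S[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    sq = max(((A**2).sum() + (B**2).sum() - 2.0 * lam) / len(A), 0.0)
    return np.sqrt(sq)

from ssangles.model import TrainingSchedule, train_bundle
from ssangles.synthetic_data import GeneratorConfig, simulate_records


@pytest.fixture(scope="session")
def small_splits():
    """A small default-condition dataset shared by read-only tests."""
    cfg = GeneratorConfig(n_proteins=14, length_range=(30, 45), seed=101)
    return simulate_records(cfg, (0.6, 0.2, 0.2))


@pytest.fixture(scope="session")
def micro_bundle(small_splits):
    """A briefly-trained 12-model bundle (routing/IO behaviour, not accuracy)."""
    sched = TrainingSchedule(seed=7, max_epochs=2)
    return train_bundle(small_splits["train"], small_splits["val"], sched=sched)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
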