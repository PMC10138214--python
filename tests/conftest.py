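import numpy as np
import pytest

from cpsmerge.alignment import AlignedEnsemble, align_ensemble
from cpsmerge.partitions import Partition


def make_partition(labels):
    return Partition(np.asarray(labels))


def make_aligned_ensemble(reference_labels, partition_labels):
    """OT-align a list of raw label vectors to a reference label vector."""
    ref = make_partition(reference_labels)
    raws = [make_partition(lbl) for lbl in partition_labels]
    return align_ensemble(raws, ref)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_coupling_ipf(rng, r, c, n_iter=300):
    """A random feasible transport plan via iterative proportional fitting."""
    W = rng.uniform(0.1, 1.0, size=(len(r), len(c)))
    for _ in range(n_iter):
        W *= (r / W.sum(axis=1))[:, None]
        W *= (c / W.sum(axis=0))[None, :]
    return W
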