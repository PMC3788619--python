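import numpy as np
import pytest

from phosphorewire.annotation import AMINO_ACIDS
from phosphorewire.io_formats import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_protein(pid="P1", sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV",
                 disorder=None, gene=None):
    return ProteinRecord(pid, gene or pid, sequence, disorder)


def random_peptides(rng, n, length=15):
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(aa[rng.integers(0, 20, size=length)]) for _ in range(n)]


def random_pwm(rng):
    """A random valid PWM with Dirichlet columns."""
    from phosphorewire.kinase_models import KinasePwm, information_weights

    probs = rng.dirichlet(np.full(20, 0.5), size=15).T
    return KinasePwm("RND", probs, information_weights(probs), [], 0, 0)


@pytest.fixture
def protein_factory():
    return make_protein
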