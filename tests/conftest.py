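import numpy as np
import pytest

from episyn import InteractionModel, random_model, sample_independent


@pytest.fixture
def null_model():
    """d=3 model with no effects: Pr(Y=1|x) = 1/2 everywhere."""
    return InteractionModel(d=3, beta={}, p=[0.3, 0.5, 0.7])


@pytest.fixture
def pair_model():
    """d=3 model with a single pair interaction beta_{1,2}=1 (0-based (0,1))."""
    return InteractionModel(d=3, beta={(0, 1): 1.0}, p=[0.4, 0.6, 0.5])


@pytest.fixture
def xor_table():
    """Exact joint of (X1, X2, Y) with Y ~ X1*X2 deterministically.

    A huge interaction coefficient drives the sigmoid to 0/1, so the
    population table is the XOR triple with uniform marginals.
    """
    m = InteractionModel(d=2, beta={(0, 1): 60.0})
    return m.exact_joint((0, 1), include_outcome=True)


@pytest.fixture
def small_dataset():
    m = random_model(6, 2, 2, seed=101)
    return sample_independent(m, 400, seed=102)
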