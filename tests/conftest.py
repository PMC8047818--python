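import pytest

from paleoclock import Alignment, SubstitutionModel


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            ("seq1", "ARND-CQE"),
            ("seq2", "ARNE-CQE"),
            ("seq3", "ARKD--QE"),
        ]
    )


@pytest.fixture
def poisson_model():
    return SubstitutionModel("POISSON", n_categories=1)


@pytest.fixture
def lg_model():
    return SubstitutionModel("LG", gamma_shape=1.0, n_categories=4)
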