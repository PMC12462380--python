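import numpy as np
import pytest

from aasubst import RateModel, parse_paml, random_model

TOY3_TEXT = """\
1.0
2.0 3.0

0.5 0.3 0.2
"""

TOY3_ALPHABET = ("A", "R", "N")


@pytest.fixture
def toy3() -> RateModel:
    """3-state model with rates (1, 2, 3) and skewed frequencies."""
    return parse_paml(TOY3_TEXT, alphabet=TOY3_ALPHABET, name="toy3")


@pytest.fixture
def toy3_equal() -> RateModel:
    """3-state equal-rates model with uniform frequencies."""
    return RateModel.equal_rates(TOY3_ALPHABET, name="toy3eq")


@pytest.fixture
def equal_rates20() -> RateModel:
    return RateModel.equal_rates()


def rand_models(n_models: int, seed: int = 0, n: int = 20) -> list[RateModel]:
    """Deterministic batch of random reversible models."""
    alphabet = tuple("ARNDCQEGHILKMFPSTWYV"[:n])
    return [
        random_model(alphabet=alphabet, seed=seed * 1000 + i, name=f"m{i}")
        for i in range(n_models)
    ]
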