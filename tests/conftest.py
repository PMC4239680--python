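import random

import pytest

from orderalign.model import CostScheme, GeneOrder


def go(text: str, id: str = "") -> GeneOrder:
    """Compact gene order: one character per gene, '-' negates the next."""
    return GeneOrder.from_string(text, id)


@pytest.fixture
def unit_costs() -> CostScheme:
    return CostScheme.unit()


@pytest.fixture
def singleloss_costs() -> CostScheme:
    return CostScheme.dup_singleloss()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240101)
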