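import numpy as np
import pytest

from orgedit.error_model import MismatchRateTable
from orgedit.formats_io import PileupColumn


@pytest.fixture
def uniform_rates():
    """Position-uniform rates with every substitution at 1e-3."""
    eps = 1e-3
    return MismatchRateTable.uniform(
        {(r, o): eps for r in "ACGT" for o in "ACGT" if r != o}
    )


@pytest.fixture
def symmetric_ct_rates():
    """Only the C<->T channel is noisy: P(T|C) = P(C|T) = 1e-3."""
    return MismatchRateTable.uniform({("C", "T"): 1e-3, ("T", "C"): 1e-3})


def make_column(counts: dict, read_position: int = 1,
                template_id: str = "tpl", position: int = 1,
                ref_base: str = "C") -> PileupColumn:
    """Collapsed pileup column with all observations at one read position."""
    col = PileupColumn(template_id, position, ref_base)
    for base, n in counts.items():
        if n:
            col.add(read_position, base, n)
    return col


@pytest.fixture
def rng():
    return np.random.default_rng(20130620)
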