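"""Shared fixtures: small synthetic families and toy inputs, all generated
at test time."""

from __future__ import annotations

import pytest

from cytb561.seqio import AlignmentBlock
from cytb561.simulate import (
    cg1275_nemy_spec,
    cg8399_like_spec,
    default_insect_spec,
    simulate_family,
)


@pytest.fixture(scope="session")
def insect_family():
    """The default synthetic insect family (44 sequences, 4 groups)."""
    records, truth = simulate_family(default_insect_spec(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def cybdom_family():
    """The synthetic CYBDOM family (10 sequences, TM1-TM4 register)."""
    records, truth = simulate_family(cg8399_like_spec(seed=7))
    return records, truth


@pytest.fixture(scope="session")
def light_family():
    """CG1275/Nemy family with loop-resident features only."""
    records, truth = simulate_family(cg1275_nemy_spec(seed=5))
    return records, truth


@pytest.fixture()
def toy_alignment() -> AlignmentBlock:
    return AlignmentBlock(
        ids=("a", "b", "c"),
        rows=("MKH-LV", "MKHALV", "MRH-LV"),
    )
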