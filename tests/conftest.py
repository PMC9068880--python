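import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from hcrprobe import (
    Amplifier,
    DesignParameters,
    HybridizationConditions,
    generate_fixture,
)


@pytest.fixture
def conditions():
    return HybridizationConditions()


@pytest.fixture
def params():
    return DesignParameters()


@pytest.fixture
def placeholder_amp():
    """Synthetic split arms: no published amplifier sequence is load-bearing."""
    return Amplifier(
        name="TEST",
        initiator_up="GGTTGGTTGGTTGGTTGG",
        initiator_down="CCAACCAACCAACCAACC",
        arm_spacer_up="AA",
        arm_spacer_down="AA",
    )


@pytest.fixture
def small_fixture():
    """2-kb transcript with CDS [100, 1300) and a single-copy genome."""
    return generate_fixture(seed=11, length=2000, gc=0.5, cds=(100, 1300))
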