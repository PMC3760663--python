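import numpy as np
import pytest

from irisplex import (
    GenotypeRecord,
    ParameterSet,
    default_panel,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def demo_params(panel):
    """A hand-written, moderately discriminating parameter set (reference:
    brown) used throughout the tests; not the published coefficients."""
    return ParameterSet(
        reference_category="brown",
        alpha={"blue": 3.2, "intermediate": 1.1},
        beta={
            "blue": np.array([-3.6, 1.1, -0.9, 0.4, -0.5, 0.6]),
            "intermediate": np.array([-1.4, 0.7, -0.4, 0.2, -0.1, 0.5]),
        },
        panel=panel,
        provenance="test fixture",
    )


@pytest.fixture()
def random_records(panel):
    rng = np.random.default_rng(20130804)

    def make(n):
        return [
            GenotypeRecord(f"R{i:04d}", rng.integers(0, 3, size=len(panel)).astype(float), panel)
            for i in range(n)
        ]

    return make
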