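import numpy as np
import pytest

import isoniche as iso


@pytest.fixture(scope="session")
def h2_dataset():
    """Default nitrogen-expansion scenario dataset plus its truth manifest."""
    spec = iso.ScenarioSpec.from_hypothesis("H2", seed=11)
    records, manifest = iso.generate_isotope_dataset(spec)
    return spec, records, manifest


@pytest.fixture(scope="session")
def h3_dataset():
    """Null scenario (identical areas) dataset plus manifest."""
    spec = iso.ScenarioSpec.from_hypothesis("H3", seed=7)
    records, manifest = iso.generate_isotope_dataset(spec)
    return spec, records, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_records():
    """Three fish of one species at one site, hand-set values."""
    mk = lambda i, c, n: iso.IsotopeRecord(
        fish_id=f"F{i}", species="china", site="S1", area="MPA",
        status="protected", length_cm=30.0, d13c=c, d15n=n)
    return [mk(1, -18.0, 12.0), mk(2, -16.0, 15.0), mk(3, -17.0, 13.0)]
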