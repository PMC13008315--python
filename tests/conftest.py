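import pytest

from bbb_ivive.synthetic import AssayDesign, TransportTruth


@pytest.fixture
def default_design() -> AssayDesign:
    return AssayDesign()


@pytest.fixture
def sink_design() -> AssayDesign:
    """Large-volume variant of the standard schedule under which sink
    conditions hold across the whole tested permeability range."""
    return AssayDesign(donor_volume=100.0, receiver_volume=100.0)


@pytest.fixture
def noiseless_truth() -> TransportTruth:
    return TransportTruth("cmpd", 5e-6, 5e-6, noise_cv=0.0, seed=7)
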