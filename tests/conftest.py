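import numpy as np
import pytest

from rrpkinetics import pipeline, synthetic
from rrpkinetics.types import MiniKernel, RateTriple, SucroseProtocol

# Table-layout reference triples (k1 vesicles/s, k_minus1 1/s, kf 1/s)
WT = RateTriple(385.6, 0.0903, 0.000844)
V48F = RateTriple(79.87, 0.0605, 0.0164)
WT2 = RateTriple(457.4, 0.1114, 0.000398)  # parallel control of D166Y
D166Y = RateTriple(37.68, 0.0294, 0.03522)
SYT1_WT = RateTriple(1227.0, 0.140, 0.000235)
SYT1_KO = RateTriple(646.0, 0.114, 0.00286)


@pytest.fixture(scope="session")
def wt_rates():
    return WT


@pytest.fixture(scope="session")
def kernel():
    return MiniKernel()


@pytest.fixture(scope="session")
def protocol():
    return SucroseProtocol(
        onset_time=1.0, duration=5.0, n_suc=5000.0,
        baseline_shift=-20.0, exchange_time=0.05,
    )


@pytest.fixture(scope="session")
def wt_sucrose_trace(wt_rates, protocol, kernel):
    """One rendered sucrose application of a wildtype-like cell."""
    events = synthetic.simulate_pool(
        wt_rates, protocol=protocol, t_end=protocol.end_time + 0.1,
        initial_pool="steady", seed=42,
    )
    return synthetic.render_trace(
        events, kernel, protocol=protocol, seed=43
    )


@pytest.fixture(scope="session")
def wt_cell(wt_rates, protocol):
    """Full synthetic cell (spontaneous + sucrose), analysis-ready."""
    return pipeline.simulate_cell(
        wt_rates, seed=7, protocol=protocol, spont_duration=60.0,
        condition="WT", cell_id="WT_fixture",
    )
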