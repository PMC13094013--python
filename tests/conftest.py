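import numpy as np
import pytest

import chp_elastic as ce


@pytest.fixture(scope="session")
def small_label_map():
    """Hand-built 8x8x4 head: gray rim, white core, CSF block with a ChP strip."""
    labels = np.zeros((8, 8, 4), dtype=np.int16)
    labels[1:7, 1:7, :] = ce.LABELS["gray"]
    labels[2:6, 2:6, 1:3] = ce.LABELS["white"]
    labels[3:5, 2:5, 1:3] = ce.LABELS["csf"]
    labels[3:5, 5, 1:3] = ce.LABELS["chp"]  # strip on the ventricle wall
    return labels


@pytest.fixture(scope="session")
def small_spec(small_label_map):
    return ce.PhantomSpec(small_label_map, noise_sigma=0.002, seed=42)


@pytest.fixture(scope="session")
def small_acq():
    return ce.AcquisitionParams(tr=2000.0, te_list=(60.0,), flip_angle=80.0, n_volumes=100)


@pytest.fixture(scope="session")
def hyper_trace():
    return ce.simulate_etco2_hypercapnia(duration=220.0, delay=4.0, seed=5)


@pytest.fixture(scope="session")
def small_phantom(small_spec, small_acq, hyper_trace):
    """(series, truth) for the small hypercapnia phantom at TE 60 ms."""
    return ce.build_phantom(small_spec, hyper_trace, small_acq)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size default phantom under the hypercapnia protocol."""
    trace = ce.simulate_etco2_hypercapnia(delay=6.0, seed=1)
    spec = ce.default_phantom_spec(seed=1)
    series, truth = ce.build_phantom(spec, trace, ce.hypercapnia_acquisition())
    return series, truth, trace
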