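import numpy as np
import pytest

from shgkin import (
    BiExpParams,
    CorrectionModel,
    FieldTrace,
    biexp_field,
    generate_trace,
    get_preset,
    process_trace,
)


@pytest.fixture(scope="session")
def dopg_guv():
    return get_preset("dopg_guv")


@pytest.fixture(scope="session")
def dopg_suv():
    return get_preset("dopg_suv")


@pytest.fixture()
def biexp_params():
    """Reference decay parameters used throughout the fitting tests."""
    return BiExpParams(A0=1.0, B1=2.0, tau1=30.0, B2=1.5, tau2=600.0, t0=0.0)


@pytest.fixture()
def noiseless_field_trace(biexp_params):
    """Exact bi-exponential field on a 1 s grid, 3600 s plus a long anchor."""
    t = np.append(np.arange(0.0, 3600.0, 1.0), 43200.0)
    f = biexp_field(biexp_params, t)
    return FieldTrace(time=t, field=f, temperature=306.15, t_peak=0.0)


def corrected_field(preset, T, seed, noise=True):
    """Full instrument-inversion chain on one synthetic trace."""
    trace = generate_trace(preset, T, seed, noise=noise)
    model = CorrectionModel(
        extinction_factor=preset.extinction_factor, hrs_level=preset.hrs_level
    )
    return process_trace(trace, model)
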