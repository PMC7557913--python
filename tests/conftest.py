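import numpy as np
import pytest

from sckinetics import (
    HydrationTrajectory,
    ImpedanceSpectrum,
    NoiseModel,
    ResponseSeries,
    franz_cell_design,
    ne_design,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def franz_zero_noise():
    """One noiseless 4E replicate at the default trajectory (k = 0.005 s⁻¹)."""
    return simulate_experiment(
        franz_cell_design(), HydrationTrajectory(), n_replicates=1, noise=NoiseModel.silent()
    )


@pytest.fixture(scope="session")
def ne_zero_noise():
    """One noiseless NE replicate over the 12-point 16 min schedule."""
    return simulate_experiment(
        ne_design(), HydrationTrajectory(), n_replicates=1, noise=NoiseModel.silent()
    )


@pytest.fixture
def flat_spectrum():
    """A purely resistive 10 kΩ spectrum on the NE grid."""
    freqs = np.geomspace(1e3, 2.5e6, 35)
    return ImpedanceSpectrum(
        frequencies_hz=freqs,
        z_re_ohm=np.full(35, 10e3),
        z_im_ohm=np.zeros(35),
        time_s=0.0,
        method_tag="NE",
        replicate_id="r1",
        site_id="s1",
    )


def exact_first_order_series(k, times, eir_initial=100.0, eir_final=400.0, kind="conductance"):
    """Model-true response: EIR(t) = EIR_f + (EIR_i − EIR_f) e^(−kt)."""
    times = np.asarray(times, dtype=float)
    values = eir_final + (eir_initial - eir_final) * np.exp(-k * times)
    return ResponseSeries(
        time_s=times,
        values=values,
        parameter_kind=kind,
        method_tag="HP",
        replicate_id="r1",
        site_id="s1",
    )


@pytest.fixture
def make_first_order_series():
    return exact_first_order_series
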