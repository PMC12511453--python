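"""Shared fixtures: expensive solves and simulations computed once."""

import numpy as np
import pytest

from tiskit import (
    AxonParams,
    ExtracellularDrive,
    WaveformSpec,
    find_threshold,
)
from tiskit.volume_conductor import (
    ElectrodePatch,
    ElectrodeSetup,
    TissueLayer,
    TissueModel,
    activating_amplitude,
    default_crossed_pairs,
    graded_edges,
    solve_pair,
    _iso,
)

HALFSPACE_SIGMA = 0.3
HALFSPACE_I_MA = 5.0
HALFSPACE_SRC_X = -20.0
HALFSPACE_SNK_X = +20.0


@pytest.fixture(scope="session")
def axon_params():
    return AxonParams()


@pytest.fixture(scope="session")
def sine_1k_threshold(axon_params):
    """Unmodulated 1 kHz sine threshold (mA) at the default 2 s window."""
    spec = WaveformSpec(kind="sine", carrier_frequency=1000.0,
                        per_channel_amplitude=0.1)
    return find_threshold(axon_params, ExtracellularDrive(waveform=spec),
                          rel_tol=0.02)


@pytest.fixture(scope="session")
def tis_1k_threshold(axon_params):
    """Per-channel TIS (delta f = 5 Hz) threshold at 1 kHz, 2 s window."""
    spec = WaveformSpec(kind="tis_pair", carrier_frequency=1000.0,
                        modulation_frequency=5.0, per_channel_amplitude=0.1)
    return find_threshold(axon_params, ExtracellularDrive(waveform=spec),
                          rel_tol=0.02)


def _homogeneous_tissue(sigma=HALFSPACE_SIGMA):
    """Large uniform block with a locally refined grid near the electrodes."""
    xe = graded_edges(200.0, 35.0, 2.5, 20.0)
    ye = graded_edges(200.0, 12.5, 2.5, 20.0)
    z = list(np.arange(0, 35.0 + 1e-9, 2.5))
    h = 2.5
    while z[-1] < 200.0:
        h = min(h * 1.3, 25.0)
        z.append(min(z[-1] + h, 200.0))
    return TissueModel(
        extent_x_mm=400.0, extent_y_mm=400.0, extent_z_mm=200.0,
        layers=(
            TissueLayer("a", 10.0, _iso(sigma), _iso(0.0)),
            TissueLayer("b", 10.0, _iso(sigma), _iso(0.0)),
            TissueLayer("bulk", np.inf, _iso(sigma), _iso(0.0)),
        ),
        frequency_hz=2500.0, nerve_depth_mm=25.0,
        x_edges_override_mm=tuple(xe), y_edges_override_mm=tuple(ye),
        z_edges_override_mm=tuple(z),
    )


@pytest.fixture(scope="session")
def halfspace_solution():
    """Uniform-medium solve of a small-patch pair, for analytic oracles."""
    tissue = _homogeneous_tissue()
    setup = ElectrodeSetup(
        patches=(
            ElectrodePatch(HALFSPACE_SRC_X, 0.0, 5.0, pair=1, polarity=+1),
            ElectrodePatch(HALFSPACE_SNK_X, 0.0, 5.0, pair=1, polarity=-1),
        ),
        current_1_ma=HALFSPACE_I_MA, current_2_ma=HALFSPACE_I_MA,
    )
    return solve_pair(tissue, setup, pair=1)


@pytest.fixture(scope="session")
def forearm_fields():
    """Per-mA activating maps of the tight crossed montage over the nerve."""
    tissue = TissueModel()
    setup = ElectrodeSetup(
        patches=default_crossed_pairs(16.0, 10.0, 12.0),
        current_1_ma=1.0, current_2_ma=1.0,
    )
    s1 = solve_pair(tissue, setup, pair=1)
    s2 = solve_pair(tissue, setup, pair=2)
    x, y, a1 = activating_amplitude(s1)
    _, _, a2 = activating_amplitude(s2)
    return {"x": x, "y": y, "a1": a1, "a2": a2, "s1": s1, "s2": s2}
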