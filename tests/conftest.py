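import numpy as np
import pytest

from dbflip.bifurcation import equilibrium_branch, find_hopf
from dbflip.presets import get_preset


@pytest.fixture(scope="session")
def fig8_branch():
    cp = get_preset("fig8_3state")
    return equilibrium_branch(cp.params, np.arange(-80.0, -10.0, 0.05),
                              s=cp.s)


@pytest.fixture(scope="session")
def fig9_branch():
    cp = get_preset("fig9_4state")
    return equilibrium_branch(cp.params, np.arange(-80.0, -10.0, 0.05),
                              s=cp.s)


@pytest.fixture(scope="session")
def fig8_hopfs(fig8_branch):
    return find_hopf(fig8_branch)


@pytest.fixture(scope="session")
def fig9_hopfs(fig9_branch):
    return find_hopf(fig9_branch)


@pytest.fixture(scope="session")
def fig8_windows(fig8_hopfs):
    """Simulation-oracle oscillation windows around the 3-state Hopf pair."""
    from dbflip.bifurcation import oscillation_windows
    cp = get_preset("fig8_3state")
    u1, u2 = fig8_hopfs[0].u, fig8_hopfs[1].u
    grid = np.linspace(u1 - 0.3, u2 + 0.3, 41)
    return grid, oscillation_windows(cp.params, grid, s=cp.s)


@pytest.fixture(scope="session")
def flipper_clean_traces():
    """Noise-free step family spanning the flip structure of the 4-state
    cell at s/G_in = 4 (spiking, full DB, resurgence, final DB)."""
    from dataclasses import replace
    from dbflip.presets import generate_recording_set
    cp = replace(get_preset("flipper_like"), noise_sd=0.0,
                 u_grid=(100.0, 242.0, 316.0, 389.0, 463.0, 550.0))
    return generate_recording_set(cp, seed=0)


@pytest.fixture(scope="session")
def lfc_clean_traces():
    """Noise-free recording set of the LFC archetype (shared across tests)."""
    from dataclasses import replace
    from dbflip.presets import generate_recording_set
    cp = get_preset("lfc_like")
    return generate_recording_set(replace(cp, noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def hfc_clean_traces():
    from dataclasses import replace
    from dbflip.presets import generate_recording_set
    cp = get_preset("hfc_like")
    return generate_recording_set(replace(cp, noise_sd=0.0), seed=0)
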