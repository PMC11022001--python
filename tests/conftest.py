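import warnings

import numpy as np
import pytest

import aneumech as am

FLOWS = (150.0, 170.0, 190.0)


@pytest.fixture(scope="session")
def waveform_spec():
    return am.WaveformSpec()


@pytest.fixture(scope="session")
def stimulus_spec():
    return am.StimulusSpec(flow_rate=170.0)


@pytest.fixture(scope="session")
def loads(waveform_spec):
    return {fl: am.build_load_program(waveform_spec, am.StimulusSpec(flow_rate=fl)) for fl in FLOWS}


@pytest.fixture(scope="session")
def runner(loads):
    """Reference-anchored forward runner over the three stimulus flows."""
    return am.SacForwardRunner(loads=loads, r0_mm=2.0, thickness_um=430.0)


@pytest.fixture(scope="session")
def acquisition_times(waveform_spec, stimulus_spec):
    """(t1, t2) with a 0.03 s baseline offset."""
    return am.default_acquisition_times(waveform_spec, stimulus_spec, 0.03)


@pytest.fixture(scope="session")
def default_grid():
    return am.design_grid()


@pytest.fixture(scope="session")
def phantom_pair(waveform_spec, stimulus_spec, loads):
    """Noise-free phantom C1/C2 masks plus ground truth (session-cached)."""
    spec = am.PhantomSpec()
    t1, t2 = am.default_acquisition_times(waveform_spec, stimulus_spec, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return am.generate_phantom_pair(spec, loads[170.0], t1=t1, t2=t2)


@pytest.fixture()
def sphere_mask():
    """Voxelized sphere of radius 2 mm at the imaging resolution."""
    # bounds on voxel-size multiples so the equatorial plane z=0 falls on a
    # voxel boundary (region splits are then symmetric)
    return am.voxelize(
        lambda x, y, z: x**2 + y**2 + z**2 <= 4.0, (-2.5, -2.5, -2.5), (2.5, 2.5, 2.5), 0.25
    )


def membrane_oracle(r0_mm, thickness_um, material, pressure_pa, n=4_000_001, lam_max=1.6):
    """Independent brute-force membrane solve: dense stretch grid minimizing
    the Laplace residual |P(lam) - P| on the ascending branch."""
    lam = np.linspace(1.0, lam_max, n)
    i1 = 2.0 * lam**2 + lam**-4
    sigma = 2.0 * (lam**2 - lam**-4) * 0.5 * material.a * np.exp(0.5 * material.b * (i1 - 3.0))
    p = 2.0 * sigma * 1e3 * (thickness_um / 1000.0 * lam**-2) / (r0_mm * lam)
    i = int(np.argmin(np.abs(p - pressure_pa)))
    return lam[i]
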