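from dataclasses import replace

import pytest

from lutadose.phantom import AcquisitionSpec, AdministrationRecord, simulate_study
from lutadose.presets import (
    default_calibration,
    paper_like_phantom,
    simulate_preset_study,
)
from lutadose.scenarios import run_all


@pytest.fixture(scope="session")
def no_physics_study():
    """Null configuration: no attenuation, blur, noise or projection overlap."""
    return simulate_preset_study("no_physics", seed=1)


@pytest.fixture(scope="session")
def paper_study():
    """Bundled demonstration phantom with attenuation, blur and overlap."""
    return simulate_preset_study("paper_like", seed=0)


@pytest.fixture(scope="session")
def attenuated_study():
    """Attenuation on, but no blur and no background: isolates the effect of
    uncorrected photon attenuation (and projection overlap) on the planar path."""
    spec = replace(paper_like_phantom(), background_uptake_fraction=0.0)
    acq = AcquisitionSpec(planar_psf_fwhm_mm=0.0, spect_psf_fwhm_mm=0.0)
    return simulate_study(
        spec, acq, AdministrationRecord(), default_calibration("paper_like")
    )


@pytest.fixture(scope="session")
def no_physics_results(no_physics_study):
    return run_all(no_physics_study)


@pytest.fixture(scope="session")
def paper_results(paper_study):
    return run_all(paper_study)
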