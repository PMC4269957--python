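import pytest

from impactkit.kinematics import derive_kinematics, filter_track, summarize_peaks
from impactkit.synthio import MOUSE_IMPACT_PEAKS, gen_impact_trajectory


@pytest.fixture(scope="session")
def mouse_track():
    """Noiseless synthetic impact constrained to the measured mouse peaks."""
    return gen_impact_trajectory(MOUSE_IMPACT_PEAKS)


@pytest.fixture(scope="session")
def mouse_pipeline_peaks(mouse_track):
    """Peak table from the standard 400-Hz filter + differentiation pipeline."""
    filtered = filter_track(mouse_track)
    return summarize_peaks([derive_kinematics(filtered)])
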