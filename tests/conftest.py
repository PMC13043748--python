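import numpy as np
import pytest

from omdiff import synthetic as syn


@pytest.fixture(scope="session")
def default_frap():
    """One simulated FRAP experiment at the standard study condition."""
    seq, truth = syn.simulate_frap_sequence(syn.FrapSimParams(seed=3))
    return seq, truth


@pytest.fixture(scope="session")
def free_tracks_200():
    """200 freely diffusing tracks at the SPT imaging condition."""
    return [
        syn.simulate_track(syn.TrajectoryParams(d_um2_s=0.055, n_frames=45, seed=s))
        for s in range(200)
    ]


@pytest.fixture(scope="session")
def confined_tracks_200():
    """200 corral-confined tracks; disc chosen so the true plateau is 0.012 µm²."""
    d_geo = 2.0 * np.sqrt(0.012)
    return [
        syn.simulate_track(
            syn.TrajectoryParams(
                d_um2_s=0.018, corral_diameter_um=d_geo, n_frames=45, seed=10_000 + s
            )
        )
        for s in range(200)
    ]
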