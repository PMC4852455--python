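import numpy as np
import pytest

import hyphaq as hq


@pytest.fixture(scope="session")
def wt_params():
    return hq.STRAIN_DEFAULTS["WT"]


@pytest.fixture(scope="session")
def wt_zero_cohort(wt_params):
    """Noise-free, zero-variance wild-type cohort (exact-recovery mode)."""
    return hq.simulate_cohort({"WT": wt_params.zero_variance()}, 3, seed=11)


@pytest.fixture(scope="session")
def wt_noisy_cohort(wt_params):
    """Seeded wild-type cohort at the published parameter values."""
    return hq.simulate_cohort({"WT": wt_params}, 10, seed=7)


def linear_plateau_trace(rate_um_per_h=7.6, t_cess=300.0, n_frames=30,
                         dt=15.0, hypha_id="h0", strain="WT"):
    """Hand-built noise-free linear-then-plateau trace."""
    frames = []
    for k in range(n_frames):
        t = k * dt
        frames.append(hq.FrameRecord(
            frame_index=k, time_min=t,
            length_um=rate_um_per_h * min(t, t_cess) / 60.0))
    return hq.HyphaTrace(hypha_id=hypha_id, strain=strain, frames=frames)


@pytest.fixture
def simple_trace():
    return linear_plateau_trace()
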