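import numpy as np
import pytest
from hypothesis import settings

from undulokin import SyntheticSpec, generate_trial, tracking_io

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free synthetic trial with known ground truth, views merged."""
    spec = SyntheticSpec(tbf=2.5, tip_amplitude_pp=0.16, wavelength=0.6,
                         body_angle=30.0, aa_chord_pitch=11.0,
                         noise_sd=0.0, duration=1.0, seed=0)
    seq, tracks, meta = generate_trial(spec, speed_bl=1.5)
    tracking_io.merge_views(tracks, meta.body_length)
    return spec, seq, tracks, meta


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial with realistic digitizing noise (0.002 BL per coordinate)."""
    spec = SyntheticSpec(tbf=2.2, tip_amplitude_pp=0.16, wavelength=0.6,
                         body_angle=30.0, aa_chord_pitch=11.0,
                         noise_sd=0.002, duration=1.2, seed=3)
    seq, tracks, meta = generate_trial(spec, speed_bl=1.0)
    tracking_io.merge_views(tracks, meta.body_length)
    return spec, seq, tracks, meta


@pytest.fixture(scope="session")
def study_table():
    """A trial table with the reference design layout (51 rows) and a
    seeded response column; stats tests overwrite ``y`` as needed."""
    import pandas as pd

    rng = np.random.default_rng(7)
    speeds = [0.5, 0.75, 1, 1.25, 1.5, 1.75, 2, 3, 4, 5, 6]
    rows = [{"individual_id": f"i{i}", "speed_bl": s, "y": rng.normal()}
            for i in range(5) for s in speeds
            if not (i == 4 and s in (0.5, 0.75, 1.75, 6))]
    return pd.DataFrame(rows)
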