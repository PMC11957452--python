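import numpy as np
import pytest

import belumask as bm

FS = 288_000


@pytest.fixture(scope="session")
def fs() -> int:
    return FS


@pytest.fixture(scope="session")
def white_clip() -> bm.CalibratedClip:
    """5 s of 1000-µPa-RMS white noise at 288 kHz."""
    rng = np.random.default_rng(101)
    return bm.CalibratedClip(rng.normal(0.0, 1000.0, FS * 5), FS)


@pytest.fixture(scope="session")
def quiet_scene() -> bm.SyntheticScene:
    """A sparse, vessel-free scene: every call well above the ambient bed."""
    spec = bm.EventSpec(
        event_id="quiet01",
        seed=2017,
        treatment_durations_s={t: 24.0 for t in ("before", "during", "after")},
        expected_counts={
            (t, c): n
            for t in ("before", "during", "after")
            for c, n in (("HFBP_M", 1.5), ("HFBP_B", 1.5), ("CC", 1.0))
        },
        event_random_intercept_sd=0.0,
    )
    return bm.render_event(spec, vessel_rolloff_hz=None, min_call_separation_s=0.8)


def masking_chain(scene: bm.SyntheticScene, uncertainty_db: float = 3.0):
    """Quiet snippets -> SSDL -> 1/3-octave -> excess -> masking frequency."""
    from belumask.pipeline import masking_for_scene

    return masking_for_scene(scene, uncertainty_db)
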