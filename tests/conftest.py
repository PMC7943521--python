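import pytest

import slmspeech as slm


@pytest.fixture
def stroke():
    """A representative single stroke."""
    return slm.LognormalStroke(D=5.0, t0=0.05, mu=-1.6, sigma=0.15,
                               theta_s=0.3, theta_e=0.8)


@pytest.fixture
def two_stroke_plan():
    return slm.ActionPlan(
        [
            slm.LognormalStroke(D=4, t0=0.10, mu=-1.6, sigma=0.20,
                                theta_s=0.5, theta_e=0.9),
            slm.LognormalStroke(D=3, t0=0.28, mu=-1.5, sigma=0.15,
                                theta_s=-0.4, theta_e=-0.2),
        ]
    )


@pytest.fixture
def sound_map():
    return slm.SoundMap.hexagonal()


@pytest.fixture
def map_params():
    """The default acoustic-to-kinematic map (alpha=0.3, k=0.04 mm/Hz)."""
    return slm.KinematicMapParams()


@pytest.fixture
def anchors_english_male():
    return slm.VOWEL_ANCHOR_SETS["english_male"]
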