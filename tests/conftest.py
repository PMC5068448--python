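import pytest

from gelquant import builtin_ladder, score_gel
from gelquant.synthetic import SyntheticGelSpec, default_lane_boxes, render_gel


@pytest.fixture(scope="session")
def ladder():
    return builtin_ladder("hindiii")


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticGelSpec(seed=7)


@pytest.fixture(scope="session")
def default_render(default_spec):
    """One rendered study-condition gel plus its ground truth."""
    return render_gel(default_spec)


@pytest.fixture(scope="session")
def default_boxes(default_spec):
    return default_lane_boxes(default_spec)


@pytest.fixture(scope="session")
def scored_default(default_render, default_boxes, ladder):
    gel, _ = default_render
    return score_gel(gel, default_boxes, ladder, 9416)


@pytest.fixture(scope="session")
def noiseless_spec():
    """A corruption-free gel: no noise, background, vignette or skew."""
    return SyntheticGelSpec(
        seed=11, noise_sigma=0.0, background_const=0.0, vignette_amplitude=0.0, skew_deg=0.0
    )


@pytest.fixture(scope="session")
def noiseless_render(noiseless_spec):
    return render_gel(noiseless_spec)
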