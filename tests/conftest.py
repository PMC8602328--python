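import hypothesis
import pytest

from linmotif import EngineConfig, build_background, synthgen

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def bias_demo():
    """The 39-sequence positional-bias demonstration set and its background."""
    fg, bg_windows = synthgen.generate_bias_demo(seed=11)
    return fg, bg_windows


@pytest.fixture(scope="session")
def bias_demo_bg(bias_demo):
    _, bg_windows = bias_demo
    return build_background(bg_windows, bg_windows.width)


@pytest.fixture
def default_config():
    return EngineConfig()
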