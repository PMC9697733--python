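"""Shared phantom fixtures; expensive renders are built once per session."""

import pytest

from hrdot import phantom, pipeline


@pytest.fixture(scope="session")
def pair0():
    """Default phantom (12 capillaries of which 2 non-perfused, 4 INL granules,
    2 ONL granules, 3 superficial vessels), seed 0."""
    return phantom.generate_pair(phantom.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless0():
    """Same scene as pair0 with speckle and motion noise disabled."""
    return phantom.generate_pair(phantom.noiseless(phantom.PhantomConfig(seed=0)))


@pytest.fixture(scope="session")
def inl_result0(pair0):
    """(classified elements, alignment transform) of the default pipeline on pair0."""
    return pipeline.run_inl_pipeline(pair0)


@pytest.fixture(scope="session")
def suppressed0(pair0):
    from hrdot import detection

    return detection.suppress_background(pair0.structural)
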