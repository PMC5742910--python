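"""Shared fixtures: palettes, tiny images, and a default synthetic cohort."""

import numpy as np
import pytest
from hypothesis import settings

import benmap as bm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def palette() -> bm.ColorPalette:
    return bm.DEFAULT_PALETTE


@pytest.fixture
def make_image():
    """Factory for a ComponentImage from a nested list of RGB triples."""

    def _make(rows, **kw) -> bm.ComponentImage:
        return bm.ComponentImage(np.asarray(rows, dtype=np.uint8), **kw)

    return _make


@pytest.fixture(scope="session")
def default_cohort() -> bm.Cohort:
    """Study-default synthetic cohort (25 ADHD / 19 control, 2 maps each)."""
    return bm.generate_cohort(bm.CohortGenConfig(seed=11))


@pytest.fixture(scope="session")
def default_results(default_cohort) -> bm.BrainEntropyResults:
    """Fitted analysis of the default cohort."""
    return bm.BrainEntropyModel.from_cohort(default_cohort).fit()
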