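"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from histocyto.synthetic import ImageSpec, TabularSpec, make_feature_dataset, make_image


@pytest.fixture(scope="session")
def standard_table():
    """The standard tabular benchmark: 4 informative + 40 noise features,
    effect size 2, n = 1000."""
    return make_feature_dataset(TabularSpec(seed=1))


@pytest.fixture(scope="session")
def default_image():
    """One default synthetic image (20 nuclei, 25% EC) with ground truth."""
    return make_image(ImageSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
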