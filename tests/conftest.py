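import numpy as np
import pytest

from ctcflow import Box, FlowSpec, PlacementRecipe, Source, place_random


@pytest.fixture
def flow2d():
    return FlowSpec.no_flow()


@pytest.fixture
def flow3d():
    return FlowSpec.constant(1.0)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def small_sources_2d():
    """Ten seeded random near-wall sources for 2D tests."""
    recipe = PlacementRecipe(count=10, box=Box(x=(0, 100), y=(0, 20)), seed=42)
    return place_random(recipe)


@pytest.fixture
def small_sources_3d():
    recipe = PlacementRecipe(count=10, box=Box(x=(0, 100), y=(0, 100), z=(0, 30)),
                             seed=42)
    return place_random(recipe)


@pytest.fixture
def single_source_2d():
    return Source(x0=50.0, y0=30.0, strength=1.0, alpha=1.5)
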