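import dataclasses

import numpy as np
import pytest

from nicheresilience import (
    FOREST,
    GRASSLAND,
    SAVANNA,
    GridTransform,
    StateGrid,
    build_occurrence_table,
    classify_tree_cover,
    default_config,
    generate_landscape,
    reclassify_with_consensus,
)


@pytest.fixture(scope="session")
def small_cfg():
    return default_config(grid_height=60, grid_width=60, seed=3)


@pytest.fixture(scope="session")
def landscape(small_cfg):
    return generate_landscape(small_cfg)


@pytest.fixture(scope="session")
def occurrence_table(landscape):
    states = classify_tree_cover(landscape.corrupted_cover, landscape.climate.transform)
    states = reclassify_with_consensus(states, landscape.consensus)
    return build_occurrence_table(states, landscape.climate, n_points=1200, seed=11)


@pytest.fixture
def balanced_states():
    """A grid occupied one-third by each state, in contiguous stripes."""
    arr = np.empty((60, 60), dtype=np.uint8)
    arr[:20] = GRASSLAND
    arr[20:40] = SAVANNA
    arr[40:] = FOREST
    return StateGrid(arr, GridTransform())
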