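import numpy as np
import pandas as pd
import pytest

import gliascreen as gs
from gliascreen.features import feature_columns


@pytest.fixture(scope="session")
def field_and_truth():
    """One default-noise rendered field with ground truth."""
    stack, truth = gs.render_field(gs.SceneSpec(seed=7))
    return stack, truth


@pytest.fixture(scope="session")
def segmented_field(field_and_truth):
    stack, truth = field_and_truth
    mask = gs.segment_nuclei(stack["hoechst"])
    return stack, truth, mask


@pytest.fixture(scope="session")
def labeled_pool():
    """Feature table + ground-truth class labels pooled over several fields."""
    rng = np.random.default_rng(123)
    frames, labels = [], []
    for _ in range(8):
        stack, truth = gs.render_field(gs.SceneSpec(seed=int(rng.integers(2 ** 31))))
        mask = gs.segment_nuclei(stack["hoechst"])
        ft = gs.measure_objects(stack, mask)
        cls = gs.label_objects_from_truth(mask, truth)
        keep = np.array([c is not None for c in cls])
        frames.append(ft[keep])
        labels.append(cls[keep])
    pool = pd.concat(frames, ignore_index=True)
    return pool, np.concatenate(labels)


@pytest.fixture(scope="session")
def small_screen():
    """Scaled-down screen preserving the triplicate-per-repeat structure."""
    design = gs.ScreenDesign(
        n_repeats=4, plates_per_repeat=3, plate_rows=8, plate_cols=8,
        compounds=gs.default_compounds(20), seed=11,
        controls={"DMSO": (gs.ARCHETYPES["null"], 6),
                  "BAY61": (gs.ARCHETYPES["positive_control"], 6)})
    obs, truth = gs.simulate_screen(design)
    return design, obs, truth


@pytest.fixture(scope="session")
def feature_cols():
    return feature_columns
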