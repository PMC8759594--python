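import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from chromodisp import CategoryCutoffs, SyntheticSceneParams, generate_fish_scene
from chromodisp.morphometry import (
    PipelineConfig,
    ProjectedImage,
    skeleton_dot_length_pipeline,
    total_skeleton_length,
)


@pytest.fixture(scope="session")
def hetero_cutoffs():
    return CategoryCutoffs.heterochromatin()


@pytest.fixture(scope="session")
def eu_cutoffs():
    return CategoryCutoffs.euchromatin()


def focus_lengths_at_spread(spread_um: float, n_foci: int, seed0: int = 1000) -> np.ndarray:
    """Per-focus skeleton dot lengths from single-focus scenes at one spread.

    One scene per focus (the per-crop measurement convention: all fragments
    of a focus sum into one length).
    """
    lengths = []
    for s in range(n_foci):
        scene = generate_fish_scene(
            SyntheticSceneParams(
                n_nuclei=1, foci_per_nucleus=1, focus_spread_um=spread_um,
                seed=seed0 + s,
            )
        )
        measurements = skeleton_dot_length_pipeline(
            ProjectedImage(scene.image, scene.pixel_size_um)
        )
        lengths.append(total_skeleton_length(measurements))
    return np.asarray(lengths)


@pytest.fixture(scope="session")
def small_mask_fixture_set():
    """>= 200 binary masks (<= 32x32): paths, diagonals, Y-junctions,
    squares/rectangles and random blobs, for oracle-equivalence checks."""
    rng = np.random.default_rng(7)
    masks = []
    # straight paths, all four orientations
    for length in range(1, 13):
        m = np.zeros((15, 15), bool)
        m[7, 1 : 1 + length] = True
        masks.append(m)
        masks.append(m.T.copy())
        d = np.zeros((15, 15), bool)
        for i in range(length):
            d[1 + i, 1 + i] = True
        masks.append(d)
        masks.append(d[:, ::-1].copy())
    # Y-junctions with varying arm lengths
    for arm in range(2, 7):
        m = np.zeros((17, 17), bool)
        m[8, 8 - arm : 9] = True
        for i in range(1, arm + 1):
            m[8 - i, 8 + i] = True
            m[8 + i, 8 + i] = True
        masks.append(m)
    # filled squares and rectangles
    for a in range(2, 9):
        for b in range(2, 9):
            m = np.zeros((12, 12), bool)
            m[2 : 2 + a, 2 : 2 + b] = True
            masks.append(m)
    # random blobs
    from scipy import ndimage

    while len(masks) < 210:
        m = rng.random((rng.integers(8, 33), rng.integers(8, 33))) < 0.35
        m = ndimage.binary_closing(m)
        masks.append(m)
    return masks
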