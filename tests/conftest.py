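"""Shared fixtures: rendered synthetic slides are expensive, so the pooled
slide set used by imaging and acceptance tests is built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialcorr.imaging import process_slide
from trialcorr.synthetic import SlideSpec, generate_slide_image


@pytest.fixture(scope="session")
def default_slide():
    """One default-parameter mixed slide: (image, truth)."""
    spec = SlideSpec(width=512, height=512, n_cells=120, seed=11)
    return generate_slide_image(spec)


@pytest.fixture(scope="session")
def pooled_slides():
    """Several mixed slides pooled to ~1,200 cells: list of (image, truth)."""
    out = []
    for seed in range(20, 26):
        spec = SlideSpec(width=640, height=640, n_cells=200, seed=seed)
        out.append(generate_slide_image(spec))
    return out


def match_called_to_truth(called: pd.DataFrame, truth: pd.DataFrame):
    """Pair each called cell with its nearest ground-truth nucleus."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth[["x", "y"]].to_numpy())
    dist, idx = tree.query(called[["x", "y"]].to_numpy())
    return dist, truth.iloc[idx].reset_index(drop=True)


@pytest.fixture(scope="session")
def pooled_calls(pooled_slides):
    """Called cells matched to truth across the pooled slides."""
    pairs = []
    for image, truth in pooled_slides:
        called = process_slide(image)
        dist, matched = match_called_to_truth(called, truth)
        pairs.append((called.reset_index(drop=True), matched, dist))
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
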