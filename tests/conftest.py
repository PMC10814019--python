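import itertools

import numpy as np
import pandas as pd
import pytest

from choromvq.morpho.skeleton import BranchPoint, Skeleton


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating all group splits."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def synthetic_junction_skeleton(d_parent, d_daughter1, d_daughter2):
    """Hand-built branch point at (50, 50): parent from above, daughters at
    +/-45 degrees below, constant diameter per segment."""
    j = (50, 50)
    parent = np.array([(50 - k, 50) for k in range(12, 0, -1)] + [j])
    d1 = np.array([j] + [(50 + k, 50 - k) for k in range(1, 13)])
    d2 = np.array([j] + [(50 + k, 50 + k) for k in range(1, 13)])
    paths = [parent, d1, d2]
    dias = [
        np.full(len(parent), d_parent),
        np.full(len(d1), d_daughter1),
        np.full(len(d2), d_daughter2),
    ]
    mask = np.zeros((100, 100), dtype=bool)
    for p in paths:
        mask[p[:, 0], p[:, 1]] = True
    return Skeleton(
        segments=paths,
        segment_diameters_um=dias,
        branch_points=[BranchPoint(centroid=(50.0, 50.0), pixels=[j], segments=[0, 1, 2])],
        pixel_pitch_um=1.0,
        skeleton_mask=mask,
        mask=mask,
    )


@pytest.fixture
def band_mask():
    """Horizontal band, 8 px tall, in a 64x64 grid (a straight drawn vessel)."""
    m = np.zeros((64, 64), dtype=bool)
    m[28:36, 4:60] = True
    return m


@pytest.fixture
def y_mask():
    """Symmetric Y: thick vertical trunk, two thinner daughters leaving at
    +/-45 degrees (the trunk's larger diameter marks it as the parent)."""
    m = np.zeros((96, 96), dtype=bool)
    cx = 48
    for r in range(50, 90):  # trunk going down
        m[r, cx - 4 : cx + 5] = True
    for k in range(0, 40):  # daughters going up-left / up-right
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                m[50 - k + dr, cx - k + dc] = True
                m[50 - k + dr, cx + k + dc] = True
    return m


@pytest.fixture
def x_mask():
    """Two crossing diagonal bands (an X); clustering should give one junction."""
    m = np.zeros((96, 96), dtype=bool)
    for k in range(8, 88):
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                m[k + dr, k + dc] = True
                m[k + dr, 95 - k + dc] = True
    return m


@pytest.fixture
def half_annulus_mask():
    """Half-circle vessel band of centerline radius 40 px."""
    r, w = 40, 4
    H, W = r + w + 6, 2 * (r + w + 6)
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = r + w + 2, W // 2
    d = np.hypot(yy - cy, xx - cx)
    return (np.abs(d - r) <= w) & (yy <= cy)
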