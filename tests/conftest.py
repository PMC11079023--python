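"""Shared synthetic-scene fixtures.

Session-scoped: the generator scenes are the expensive part of the suite,
and several modules (and the acceptance tests) measure different things on
the same scenes.
"""
from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from gasig.synthgen import SyntheticSAMSpec, generate_sam_stack, generate_timelapse


@pytest.fixture(scope="session")
def dome50():
    """Noiseless 50-cell dome: the reference scene for quantification."""
    spec = SyntheticSAMSpec(n_cells_l1=50, noise_sigma=0.0, seed=1)
    stack, gt = generate_sam_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def dome50_noisy():
    """Same dome with mild detector noise (SNR ~ 50 on the reference gain)."""
    spec = SyntheticSAMSpec(n_cells_l1=50, noise_sigma=2.0, seed=1)
    stack, gt = generate_sam_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def seg_scene():
    """50-cell dome sampled at confocal-like 0.3 µm in-plane pitch, for
    voxel-level segmentation scoring."""
    spec = SyntheticSAMSpec(
        dome_radius_um=40.0,
        voxel_spacing_um=(1.0, 0.3, 0.3),
        n_cells_l1=50,
        cz_radius_um=10.0,
        noise_sigma=2.0,
        seed=1,
    )
    stack, gt = generate_sam_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def growth_series():
    """Two-frame time-lapse sized so every region holds >= 30 cells."""
    spec = SyntheticSAMSpec(
        dome_radius_um=45.0,
        cz_radius_um=14.0,
        n_cells_l1=300,
        primordia=((20.0, 29.0, 3), (157.5, 30.0, 4), (275.0, 28.0, 3)),
        seed=11,
        noise_sigma=2.0,
    )
    return spec, generate_timelapse(spec, n_frames=2)


@pytest.fixture(scope="session")
def division_series():
    """Four-frame time-lapse with a high division fraction, accumulating
    >= 200 division events across intervals."""
    spec = SyntheticSAMSpec(
        n_cells_l1=200,
        dome_radius_um=40.0,
        cz_radius_um=10.0,
        division_fraction=0.3,
        seed=21,
    )
    return spec, generate_timelapse(spec, n_frames=4)


@pytest.fixture(scope="session")
def drift_series():
    """Zero-growth, division-free pair related by pure rigid drift + noise."""
    spec = SyntheticSAMSpec(
        n_cells_l1=80,
        seed=5,
        growth_field={"CZ": 0.0, "IPR": 0.0, "P": 0.0},
        division_fraction=0.0,
    )
    return spec, generate_timelapse(spec, n_frames=2)


def best_match_agreement(truth: np.ndarray, pred: np.ndarray) -> float:
    """Voxel agreement under the best bipartite matching of label sets,
    evaluated over the ground-truth foreground."""
    fg = truth > 0
    width = int(pred.max()) + 1
    pairs = truth[fg].astype(np.int64) * width + pred[fg].astype(np.int64)
    uniq, counts = np.unique(pairs, return_counts=True)
    ta, tb = uniq // width, uniq % width
    ua, ub = np.unique(ta), np.unique(tb)
    ia = {v: i for i, v in enumerate(ua)}
    ib = {v: i for i, v in enumerate(ub)}
    m = np.zeros((len(ua), len(ub)))
    for x, y, c in zip(ta, tb, counts):
        m[ia[x], ib[y]] += c
    ri, ci = linear_sum_assignment(-m)
    return float(m[ri, ci].sum() / fg.sum())
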