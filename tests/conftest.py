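"""Shared fixtures: hand-built tiny datasets and generator shortcuts."""

import numpy as np
import pytest
from hypothesis import settings

from spinisi import DendriteSegment, SpineDataset, SpineTrajectory

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

BG = 100.0
SHAFT_NET = 1000.0


def make_trajectory(spine_id, position, present, sizes):
    """Trajectory with noiseless intensities encoding the given sizes.

    ``present`` and ``sizes`` are per-session sequences; sizes at absent
    sessions are ignored.
    """
    present = np.asarray(present, dtype=bool)
    sizes = np.asarray(sizes, dtype=float)
    spine = np.full(present.shape, np.nan)
    shaft = np.full(present.shape, np.nan)
    bg = np.full(present.shape, np.nan)
    idx = np.flatnonzero(present)
    spine[idx] = BG + sizes[idx] * SHAFT_NET
    shaft[idx] = BG + SHAFT_NET
    bg[idx] = BG
    return SpineTrajectory(
        id=spine_id,
        position=float(position),
        present=present,
        spine_intensity=spine,
        shaft_intensity=shaft,
        background_intensity=bg,
    )


def make_dataset(spine_specs, sessions=(-1, 0, 1, 2), baseline=(-1, 0),
                 length=30.0):
    """One-dendrite dataset from (position, present, sizes) tuples."""
    spines = [
        make_trajectory(i, pos, present, sizes)
        for i, (pos, present, sizes) in enumerate(spine_specs)
    ]
    return SpineDataset(
        dendrites=[DendriteSegment(id=0, length=length, spines=spines)],
        sessions=sessions,
        baseline_sessions=baseline,
    )


@pytest.fixture
def simple_dataset():
    """Three persistent spines over four sessions, no turnover."""
    n = 4
    return make_dataset(
        [
            (2.0, [True] * n, [1.0, 1.0, 1.5, 1.5]),
            (4.0, [True] * n, [1.0, 1.0, 0.5, 0.5]),
            (6.5, [True] * n, [2.0, 2.0, 2.0, 2.0]),
        ]
    )
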