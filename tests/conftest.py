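"""Shared builders for synthetic pose fixtures.

All fixtures are constructed programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from mousetrek.pose_io import KEYPOINTS, PoseTrack
from mousetrek.simulate import TEMPLATE

PX_PER_MM = 2.7


def cm_to_px(cm: np.ndarray) -> np.ndarray:
    return np.asarray(cm, dtype=float) * 10.0 * PX_PER_MM


def make_track(
    positions_cm,
    fps: float = 30.0,
    likelihood: float = 1.0,
    px_per_mm: float = PX_PER_MM,
    animal_id: str = "animal0",
) -> PoseTrack:
    """PoseTrack whose rigid template rides along the given centroid path.

    The template is zero-mean, so the 7-point center of mass equals the input
    path exactly (in cm), which makes kinematic expectations closed-form.
    """
    pos = np.atleast_2d(np.asarray(positions_cm, dtype=float))
    n = len(pos)
    xy_cm = TEMPLATE[None, :, :] + pos[:, None, :]
    lik = np.full((n, len(KEYPOINTS)), likelihood)
    return PoseTrack(
        animal_id=animal_id,
        xy=cm_to_px(xy_cm),
        likelihood=lik,
        fps=fps,
        px_per_mm=px_per_mm,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
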