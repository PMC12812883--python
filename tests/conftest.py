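import math

import numpy as np
import pytest

from hydrolipid.lipids import SegmentationParams


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams(pixel_size_um=0.1)


def feret_oracle(mask: np.ndarray, angle_step_deg: float = 0.1) -> tuple[float, float]:
    """Independent Feret reference: brute force over all boundary-pixel
    corner pairs for the maximum, a fine rotation sweep of projected
    extents for the minimum (pixel units)."""
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    d2 = ((corners[:, None, :] - corners[None, :, :]) ** 2).sum(-1)
    fmax = math.sqrt(float(d2.max()))
    theta = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = corners @ dirs.T
    fmin = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return fmax, fmin
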