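"""Cell-concentration estimation from millifluidic time-lapse stacks.

Swimming cells imaged in a chamber of known volume appear as bright
spots after background subtraction.  Because the chamber walls are
stationary while cells move between frames, the per-pixel median over
the stack is a robust background; each background-subtracted frame is
thresholded and its connected components counted.  The mean per-frame
count divided by the chamber volume (µL), times 1000 and times any
dilution factor, gives the concentration in cells mL⁻¹.  Frames are
treated as independent snapshots (no tracking), matching the protocol
of averaging counts over a 10 s × 16 fps acquisition.

The inoculation concentration of a fresh 27 mL culture seeded with 2 mL
of mother culture is ``C0 = N_mother × 2/27``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, restoration

from .shaker import ChamberGeometry

__all__ = [
    "DetectionParams",
    "FrameStack",
    "CountResult",
    "SaturationError",
    "detect_cells",
    "stack_background",
    "stack_concentration",
    "concentration_from_mean_count",
    "initial_concentration",
]

INOCULATION_FRACTION = 2.0 / 27.0  # 2 mL of mother culture into 27 mL total


class SaturationError(ValueError):
    """Frame is saturated; the culture should be diluted before imaging."""


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection settings.

    ``min_snr``: the automatic threshold is only trusted when it exceeds
    this many robust noise standard deviations (MAD-based) of the
    background-subtracted frame — on a spot-free frame Otsu would
    otherwise split the noise in half.
    """

    background_mode: str = "stack_median"  # {"stack_median", "rolling_ball"}
    threshold_mode: str = "otsu"  # {"otsu", "fixed"}
    fixed_threshold: float | None = None
    min_area_px: int = 4
    max_area_px: int = 500
    rolling_ball_radius: int = 25
    min_snr: float = 5.0

    def __post_init__(self) -> None:
        if self.background_mode not in ("stack_median", "rolling_ball"):
            raise ValueError("background_mode must be 'stack_median' or 'rolling_ball'")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold mode requires fixed_threshold")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be smaller than max_area_px")


@dataclass
class FrameStack:
    """A time-lapse acquisition inside a counting chamber."""

    frames: np.ndarray  # (n_frames, H, W)
    chamber: ChamberGeometry
    fps: float = 16.0
    pixel_size_um: float | None = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, H, W) array")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class CountResult:
    per_frame_counts: tuple[int, ...]
    mean_count: float
    concentration: float  # cells mL⁻¹


def _saturation_level(frame: np.ndarray) -> float | None:
    if np.issubdtype(frame.dtype, np.integer):
        return float(np.iinfo(frame.dtype).max)
    return None


def detect_cells(
    frame: np.ndarray, background: np.ndarray, params: DetectionParams
) -> tuple[int, np.ndarray]:
    """Count bright spots in a background-subtracted frame.

    Returns the count and an (n, 2) array of centroids in pixel
    coordinates.  Connected components with area outside
    [min_area_px, max_area_px] are ignored.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    sat = _saturation_level(frame)
    if sat is not None and frame.min() >= sat:
        raise SaturationError(
            "frame is fully saturated; dilute the culture before imaging"
        )
    raw = frame.astype(float) - background.astype(float)
    diff = np.where(raw < 0, 0.0, raw)
    if diff.max() <= 0:
        return 0, np.empty((0, 2))

    if params.threshold_mode == "fixed":
        t = params.fixed_threshold
    else:
        t = filters.threshold_otsu(diff)
        # robust noise scale of the residual; spots must clear it
        noise = 1.4826 * np.median(np.abs(raw - np.median(raw)))
        if t < params.min_snr * max(noise, 1e-12):
            return 0, np.empty((0, 2))

    labels = measure.label(diff > t)
    centroids = [
        r.centroid
        for r in measure.regionprops(labels)
        if params.min_area_px <= r.area <= params.max_area_px
    ]
    return len(centroids), np.array(centroids).reshape(-1, 2)


def stack_background(stack: FrameStack, params: DetectionParams) -> np.ndarray:
    """Background estimate shared by all frames (stack-median mode) or
    computed per frame by the caller (rolling-ball mode)."""
    if params.background_mode == "stack_median":
        return np.median(stack.frames.astype(float), axis=0)
    raise ValueError("rolling-ball backgrounds are per-frame; use stack_concentration")


def concentration_from_mean_count(
    mean_count: float, chamber: ChamberGeometry, dilution_factor: float = 1.0
) -> float:
    """cells mL⁻¹ = mean per-frame count / chamber volume (µL) × 1000 × dilution."""
    return mean_count / chamber.volume_ul * 1000.0 * dilution_factor


def stack_concentration(
    stack: FrameStack, params: DetectionParams = DetectionParams()
) -> CountResult:
    """Mean per-frame spot count converted to cells mL⁻¹."""
    if params.background_mode == "stack_median":
        background = stack_background(stack, params)
        pairs = ((frame, background) for frame in stack.frames)
    else:
        pairs = (
            (frame, restoration.rolling_ball(frame, radius=params.rolling_ball_radius))
            for frame in stack.frames
        )
    counts = [detect_cells(frame, bg, params)[0] for frame, bg in pairs]
    mean_count = float(np.mean(counts))
    return CountResult(
        per_frame_counts=tuple(counts),
        mean_count=mean_count,
        concentration=concentration_from_mean_count(
            mean_count, stack.chamber, stack.dilution_factor
        ),
    )


def initial_concentration(N_mother: float) -> float:
    """Inoculation concentration C0 = N_mother × 2/27 (cells mL⁻¹)."""
    if N_mother < 0:
        raise ValueError("mother-culture concentration cannot be negative")
    return N_mother * INOCULATION_FRACTION
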