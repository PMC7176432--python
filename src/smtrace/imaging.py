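"""Spot detection and trace extraction from TIRF image stacks.

Background is removed by subtracting a boxcar-smoothed copy of each frame,
spots are the strict local maxima of a (background-subtracted) detection
image, and per-spot traces are the frame-wise sums over fixed 3x3 pixel
regions of interest around each maximum.  Pixel coordinates are 0-based
(row, col) with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from smtrace.errors import InvalidArgumentError
from smtrace.traces import FluorescenceTrace

ROI_HALF_WIDTH = 1  # fixed 3x3 window


@dataclass
class MovieStack:
    """Multi-frame grayscale movie.

    ``data`` has shape (n_frames, height, width); values are non-negative
    camera counts for raw movies but may be negative after background
    subtraction.
    """

    data: np.ndarray
    pixel_size: float = 0.1
    frame_interval: float = 0.1
    channel: str = "eGFP"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InvalidArgumentError("data must be (frames, height, width)")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self):
        return self.data.shape[1:]


@dataclass(frozen=True)
class ROI:
    """A fixed 3x3 region of interest centred on a local maximum."""

    row: int
    col: int
    trace_id: str = field(default="", compare=False)

    def window(self):
        return (slice(self.row - ROI_HALF_WIDTH, self.row + ROI_HALF_WIDTH + 1),
                slice(self.col - ROI_HALF_WIDTH, self.col + ROI_HALF_WIDTH + 1))

    def inside(self, shape) -> bool:
        h, w = shape
        return (ROI_HALF_WIDTH <= self.row < h - ROI_HALF_WIDTH
                and ROI_HALF_WIDTH <= self.col < w - ROI_HALF_WIDTH)


def subtract_background(movie: MovieStack, kernel_px: int = 6) -> MovieStack:
    """Subtract a boxcar-smoothed copy of each frame from itself.

    The boxcar is the mean over the ``kernel_px`` x ``kernel_px`` window
    whose top-left corner sits at (r - kernel_px//2, c - kernel_px//2);
    edges use reflected padding.  Negative residuals are kept (not
    clipped).
    """
    h, w = movie.frame_shape
    if kernel_px < 2 or kernel_px >= h or kernel_px >= w:
        raise InvalidArgumentError(
            "kernel must be >= 2 and smaller than both image dimensions"
        )
    data = movie.data.astype(float)
    smooth = ndimage.uniform_filter(
        data, size=(1, kernel_px, kernel_px), mode="reflect"
    )
    return MovieStack(
        data=data - smooth,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        channel=movie.channel,
    )


def noise_sigma(image) -> float:
    """Robust noise scale of an image via the median absolute deviation."""
    image = np.asarray(image, dtype=float)
    return 1.4826 * float(np.median(np.abs(image - np.median(image))))


def detect_spots(image, min_peak=None, merge_radius_px: float = 3.0):
    """Find ROIs around strict local maxima of a 2-D detection image.

    A pixel is a candidate if it exceeds all eight neighbours and
    ``min_peak`` (default: 5x the image's MAD-based noise SD).  Candidates
    closer than ``merge_radius_px`` are merged keeping the brighter
    (ties broken toward the smaller row, then smaller column), and ROIs
    whose 3x3 window would leave the frame are discarded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidArgumentError("detection image must be 2-D")
    if min_peak is None:
        min_peak = 5.0 * noise_sigma(image)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = ndimage.maximum_filter(image, footprint=footprint,
                                           mode="constant", cval=-np.inf)
    rows, cols = np.nonzero((image > neighbour_max) & (image > min_peak))
    values = image[rows, cols]
    order = np.lexsort((cols, rows, -values))  # brightness desc, then position
    kept: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if all((r - kr) ** 2 + (c - kc) ** 2 >= merge_radius_px**2
               for kr, kc in kept):
            kept.append((r, c))
    kept.sort()
    rois = [
        ROI(row=r, col=c, trace_id=f"spot-{i:04d}")
        for i, (r, c) in enumerate(kept)
    ]
    return [roi for roi in rois if roi.inside(image.shape)]


def count_spots(image, min_peak=None) -> int:
    """Number of detected spots in a detection image."""
    return len(detect_spots(image, min_peak=min_peak))


def detection_image(movie: MovieStack, n_frames: int = 10):
    """Mean of the first ``n_frames`` frames (spots present at movie start)."""
    n = min(n_frames, movie.n_frames)
    return movie.data[:n].astype(float).mean(axis=0)


def extract_trace(movie: MovieStack, roi: ROI) -> FluorescenceTrace:
    """Per-frame sum over the ROI's 3x3 window."""
    if not roi.inside(movie.frame_shape):
        raise InvalidArgumentError("ROI window leaves the frame")
    window = roi.window()
    intensity = movie.data[(slice(None), *window)].sum(axis=(1, 2))
    time = np.arange(movie.n_frames) * movie.frame_interval
    return FluorescenceTrace(
        trace_id=roi.trace_id or f"roi-{roi.row}-{roi.col}",
        time=time,
        intensity=np.asarray(intensity, dtype=float),
        frame_interval=movie.frame_interval,
        channel=movie.channel,
        provenance="roi",
        meta={"row": roi.row, "col": roi.col},
    )
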