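"""Ratiometric FRET calcium quantification and mean-fluorescence assays.

Intracellular calcium is read out with a genetically encoded Cameleon
biosensor: a rise in [Ca2+]i increases the acceptor/donor (YPet/ECFP)
emission ratio. The analysis follows the standard ratiometric recipe:

* per-frame, per-channel background subtraction from a cell-free region;
* acceptor/donor ratio of ROI-mean intensities in a circular region of
  interest (default 50 px diameter) near the stimulation site;
* the response statistic ``RelDiff = (maxRatio - basalRatio) / basalRatio``
  where ``basalRatio`` averages all pre-stimulus frames and ``maxRatio`` is
  the maximum ratio at or after the stimulation frame.

:func:`mean_fluorescence` implements the companion coating assay: mean
fluorescence of labelled fibronectin images minus the autofluorescence of a
control dish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoiSpec",
    "RatioTimecourse",
    "subtract_background",
    "ratio_timecourse",
    "rel_diff",
    "mean_fluorescence",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI plus a rectangular background region, in pixels.

    ``center_px`` is ``(x, y)``; a pixel belongs to the ROI when its center
    lies within ``diameter_px / 2`` of the ROI center. ``background_rect``
    is ``(x0, y0, width, height)`` and must be disjoint from the ROI.
    """

    center_px: tuple[float, float]
    diameter_px: float = 50.0
    background_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.diameter_px > 0:
            raise ValueError("diameter_px must be > 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean ROI mask for an image of the given shape."""
        ny, nx = shape
        cx, cy = self.center_px
        r = self.diameter_px / 2.0
        if cx - r < 0 or cy - r < 0 or cx + r > nx - 1 or cy + r > ny - 1:
            raise ValueError("ROI extends outside the image")
        yy, xx = np.mgrid[0:ny, 0:nx]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2

    def background_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the background rectangle."""
        if self.background_rect is None:
            raise ValueError("no background region specified")
        x0, y0, w, h = self.background_rect
        ny, nx = shape
        if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
            raise ValueError("background region outside the image or empty")
        mask = np.zeros(shape, dtype=bool)
        mask[y0 : y0 + h, x0 : x0 + w] = True
        if np.any(mask & self.mask(shape)):
            raise ValueError("background region overlaps the ROI")
        return mask


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Subtract the background-region mean from a frame, clipping at zero.

    ``background`` is a boolean mask of the cell-free region (same shape as
    the frame). Negative results are clipped to 0; whether the original
    procedure clipped is unrecorded, so the clip is a documented choice.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=bool)
    if background.shape != frame.shape:
        raise ValueError("background mask must match the frame shape")
    if not background.any():
        raise ValueError("background region is empty")
    level = frame[background].mean()
    return np.clip(frame - level, 0.0, None)


@dataclass
class RatioTimecourse:
    """Acceptor/donor ratio time series in an ROI with a stimulation index.

    ``stim_index`` is the first post-stimulus frame. ``basal_ratio``
    averages the ratios of all frames before it (no trimming),
    ``max_ratio`` maximizes over frames at or after it, and ``rel_diff``
    is ``(max - basal) / basal`` — negative if the cell never exceeds its
    basal ratio after the stimulus. Frame times are explicit because the
    acquisition interval shortens after stimulation (30 s down to 5 s).
    """

    times_s: np.ndarray
    ratios: np.ndarray
    stim_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times_s.shape != self.ratios.shape or self.times_s.ndim != 1:
            raise ValueError("times and ratios must be equal-length 1-D arrays")
        if self.times_s.size >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.stim_index < self.times_s.size:
            raise ValueError("stim_index out of range")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be positive")

    @property
    def basal_ratio(self) -> float:
        pre = self.ratios[: self.stim_index]
        if pre.size == 0:
            raise ValueError("no pre-stimulus frames")
        return float(pre.mean())

    @property
    def max_ratio(self) -> float:
        post = self.ratios[self.stim_index :]
        if post.size == 0:
            raise ValueError("no post-stimulus frames")
        return float(post.max())

    @property
    def rel_diff(self) -> float:
        basal = self.basal_ratio
        return (self.max_ratio - basal) / basal


def ratio_timecourse(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    roi: RoiSpec,
    times_s,
    stim_index: int,
    subtract_bg: bool = True,
) -> RatioTimecourse:
    """ROI-mean acceptor/donor ratio per frame of a two-channel stack.

    Background is estimated per frame and per channel from the ROI's
    background rectangle (lamp drift differs between channels) unless
    ``subtract_bg`` is False or no background region is given. A frame whose
    donor ROI mean is <= 0 is unusable and raises ``ValueError``.
    """
    donor = np.asarray(donor_stack, dtype=float)
    acceptor = np.asarray(acceptor_stack, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor stacks must have the same shape")
    if donor.ndim != 3:
        raise ValueError("stacks must be 3-D (frames, rows, cols)")
    roi_mask = roi.mask(donor.shape[1:])
    bg_mask = None
    if subtract_bg and roi.background_rect is not None:
        bg_mask = roi.background_mask(donor.shape[1:])

    ratios = np.empty(donor.shape[0])
    for t in range(donor.shape[0]):
        dframe, aframe = donor[t], acceptor[t]
        if bg_mask is not None:
            dframe = subtract_background(dframe, bg_mask)
            aframe = subtract_background(aframe, bg_mask)
        dmean = dframe[roi_mask].mean()
        if dmean <= 0:
            raise ValueError(f"donor ROI mean <= 0 in frame {t}: unusable frame")
        ratios[t] = aframe[roi_mask].mean() / dmean
    return RatioTimecourse(np.asarray(times_s, dtype=float), ratios, stim_index)


def rel_diff(tc: RatioTimecourse) -> float:
    """Calcium response statistic ``(maxRatio - basalRatio) / basalRatio``.

    Requires at least one pre-stimulus and one post-stimulus frame and a
    positive basal ratio; may be negative when the post-stimulus maximum
    falls below the basal level.
    """
    basal = tc.basal_ratio  # raises if no pre-stimulus frames
    if basal <= 0:
        raise ValueError("basal ratio must be positive")
    return (tc.max_ratio - basal) / basal


def mean_fluorescence(images, control_images) -> float:
    """Mean fluorescence of an image set minus an autofluorescence control.

    Each set contributes the mean over images of the per-image mean
    intensity; the returned value is the difference (signal minus control).
    """
    images = [np.asarray(im, dtype=float) for im in images]
    controls = [np.asarray(im, dtype=float) for im in control_images]
    if not images or not controls:
        raise ValueError("both image sets must be non-empty")
    sig = float(np.mean([im.mean() for im in images]))
    ctl = float(np.mean([im.mean() for im in controls]))
    return sig - ctl
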