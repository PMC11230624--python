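"""Pupil segmentation and ellipse-based diametry for eye-camera frames.

Each grayscale frame is downscaled, median-filtered, contrast-stretched
and thresholded (dark pixels foreground); connected components touching
the frame border are removed and the largest remaining component within
a relative area band is kept as the pupil.  An ellipse is fitted from
the region's second-order image moments and the pupil diameter reported
as the geometric mean of its axes, d = 2 * sqrt(a * b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage import measure, segmentation, transform
from skimage.exposure import rescale_intensity
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class PupilEllipse:
    """Moment-fitted pupil ellipse; diameter d = 2 * sqrt(a * b) pixels."""

    semi_major: float
    semi_minor: float
    center_rc: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    @property
    def diameter(self) -> float:
        return 2.0 * float(np.sqrt(self.semi_major * self.semi_minor))


class PupilNotFound(ValueError):
    """No acceptable pupil candidate in a frame (frame flagged upstream)."""


def segment_pupil(
    frame: np.ndarray,
    downscale: float = 1.0,
    median_size: int = 3,
    area_band: tuple[float, float] = (0.001, 0.35),
) -> tuple[np.ndarray, float]:
    """Binary mask of the pupil region in one grayscale frame.

    Operator chain: rescale by ``downscale`` (anti-aliased), 2-D median
    filter (``median_size`` square), contrast stretch, Otsu threshold
    with dark pixels as foreground, border-touching components cleared,
    then the largest component whose area lies within ``area_band``
    (fractions of the processed frame) is retained.

    Returns ``(mask, downscale)`` — the mask lives on the downscaled
    grid; measurements must be divided by ``downscale`` to return to
    original pixels.

    Raises
    ------
    PupilNotFound
        If no candidate region survives the chain.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    proc = transform.rescale(frame, downscale, anti_aliasing=True)
    proc = median_filter(proc, size=median_size)
    lo, hi = np.min(proc), np.max(proc)
    if hi <= lo:
        raise PupilNotFound("flat frame: no contrast to segment")
    proc = rescale_intensity(proc, in_range=(lo, hi), out_range=(0.0, 1.0))
    thr = threshold_otsu(proc)
    mask = proc < thr  # the pupil is the dark region
    mask = segmentation.clear_border(mask)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise PupilNotFound("no candidate region after border clearing")
    areas = np.bincount(labels.ravel())[1:]
    amin, amax = (area_band[0] * proc.size, area_band[1] * proc.size)
    ok = np.nonzero((areas >= amin) & (areas <= amax))[0]
    if len(ok) == 0:
        raise PupilNotFound(
            f"no region within area band {area_band} (areas: {areas.tolist()})"
        )
    keep = ok[np.argmax(areas[ok])] + 1
    return labels == keep, downscale


def fit_ellipse_diameter(mask: np.ndarray, scale: float = 1.0) -> PupilEllipse:
    """Ellipse from second-order image moments of a binary region.

    Semi-axes are half the region's major/minor axis lengths (four times
    the square root of the corresponding central-moment eigenvalue, the
    ellipse with matching normalized second moments).  ``scale`` is the
    downscale factor the mask was measured at; axes are converted back
    to original pixels.

    Raises
    ------
    ValueError
        For regions with fewer than 5 pixels or degenerate (collinear)
        geometry.
    """
    mask = np.asarray(mask).astype(bool)
    n_px = int(mask.sum())
    if n_px < 5:
        raise ValueError(f"region too small to fit an ellipse ({n_px} px)")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    a = props.axis_major_length / 2.0 / scale
    b = props.axis_minor_length / 2.0 / scale
    if b <= 0:
        raise ValueError("degenerate (collinear) region")
    cr, cc = props.centroid
    return PupilEllipse(semi_major=a, semi_minor=b, center_rc=(cr / scale, cc / scale))


class PupilDiameterExtractor(BaseEstimator, TransformerMixin):
    """Per-frame pupil diameter from an eye-video frame stack.

    ``transform`` maps a ``(n_frames, h, w)`` stack to a tidy frame with
    columns ``frame, diameter_px, flag`` — one row per input frame, with
    ``flag`` set (and diameter NaN) when no pupil was found, so trace
    length is preserved.
    """

    def __init__(
        self,
        downscale: float = 1.0,
        median_size: int = 3,
        area_band: tuple[float, float] = (0.001, 0.35),
    ):
        self.downscale = downscale
        self.median_size = median_size
        self.area_band = area_band

    def fit(self, X=None, y=None):
        return self

    def transform(self, frames: np.ndarray) -> pd.DataFrame:
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        rows = []
        for i, frame in enumerate(frames):
            try:
                mask, scale = segment_pupil(
                    frame,
                    downscale=self.downscale,
                    median_size=self.median_size,
                    area_band=self.area_band,
                )
                ellipse = fit_ellipse_diameter(mask, scale=scale)
                rows.append(dict(frame=i, diameter_px=ellipse.diameter, flag=False))
            except (PupilNotFound, ValueError) as exc:
                logger.warning("frame %d flagged: %s", i, exc)
                rows.append(dict(frame=i, diameter_px=np.nan, flag=True))
        return pd.DataFrame(rows)

    def measure(self, frame: np.ndarray) -> PupilEllipse:
        """Segment and fit a single frame, raising on failure."""
        mask, scale = segment_pupil(
            frame,
            downscale=self.downscale,
            median_size=self.median_size,
            area_band=self.area_band,
        )
        return fit_ellipse_diameter(mask, scale=scale)
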