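"""ROI-variance bubble detection on sample-cell video frames.

A bubble in the X-ray footprint ruins a solution-scattering measurement.
The check is deliberately primitive and camera-agnostic: crop the frame to
the beam-footprint ROI, convert to 8-bit greyscale, and compute the
population variance of the pixel intensities.  A flat, well-loaded cell is
nearly uniform (variance of order a few hundred on the camera that
motivated the thresholds); the dark body and bright rim of a bubble — or a
meniscus edge from an incomplete load — push the variance up by an order
of magnitude.  Frames are flagged, never aborted on: with sub-10 s
exposures, stopping mid-collection saves nothing.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

from .errors import ValidationError

#: empirical decision thresholds on the greyscale intensity variance
SUSPECT_THRESHOLD = 1500.0
BUBBLE_THRESHOLD = 2000.0
#: variance typical of a clean, fully loaded cell on the reference camera
TYPICAL_CLEAN_VARIANCE = 400.0


class BubbleLabel(enum.Enum):
    CLEAN = "CLEAN"
    SUSPECT = "SUSPECT"
    BUBBLE = "BUBBLE"


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [x0, x0+width) x [y0, y0+height), 0-based."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValidationError("ROI width and height must be >= 1")

    def clamp(self, frame_height: int, frame_width: int) -> "ROI":
        x0 = max(self.x0, 0)
        y0 = max(self.y0, 0)
        x1 = min(self.x0 + self.width, frame_width)
        y1 = min(self.y0 + self.height, frame_height)
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("ROI does not intersect the frame")
        return ROI(x0, y0, x1 - x0, y1 - y0)


@dataclass(frozen=True)
class BubbleScore:
    variance: float
    label: BubbleLabel
    frame_path: str = ""


def to_greyscale(frame: np.ndarray) -> np.ndarray:
    """8-bit greyscale view of a frame (2D already-grey, or HxWx3 RGB via Rec.601)."""
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return np.rint(arr).astype(np.int64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.rint(luma).astype(np.int64)
    raise ValidationError(f"unsupported frame shape {arr.shape}")


def roi_variance(frame: np.ndarray, roi: ROI) -> float:
    """Population variance of greyscale intensity over the ROI pixels."""
    grey = to_greyscale(frame)
    r = roi.clamp(*grey.shape)
    crop = grey[r.y0 : r.y0 + r.height, r.x0 : r.x0 + r.width].astype(float)
    return float(np.mean(crop * crop) - np.mean(crop) ** 2)


def classify(variance: float) -> BubbleLabel:
    """Map a ROI variance to a three-way label.

    >= 2000 means a bubble is very likely; [1500, 2000) means a probable
    bubble or dust worth inspecting; below 1500 the cell is taken as clean.
    Both printed boundaries belong to the more alarming side so the three
    intervals partition [0, inf).
    """
    if variance < 0:
        raise ValidationError("variance cannot be negative")
    if variance >= BUBBLE_THRESHOLD:
        return BubbleLabel.BUBBLE
    if variance >= SUSPECT_THRESHOLD:
        return BubbleLabel.SUSPECT
    return BubbleLabel.CLEAN


def detect(frame: Union[np.ndarray, str, Path], roi: ROI) -> BubbleScore:
    """Score a frame (array or image file path) over the ROI."""
    path = ""
    if isinstance(frame, (str, Path)):
        path = str(frame)
        try:
            with Image.open(frame) as img:
                frame = np.asarray(img.convert("RGB"))
        except (OSError, ValueError) as exc:
            raise ValidationError(f"unreadable frame {path}: {exc}") from exc
    var = roi_variance(frame, roi)
    return BubbleScore(variance=var, label=classify(var), frame_path=path)


def synth_frame(
    shape: tuple[int, int] = (120, 160),
    background: float = 60.0,
    noise_sd: float = 3.0,
    bubbles: Sequence[tuple[tuple[float, float], float, float]] = (),
    meniscus_row: Optional[int] = None,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Render a synthetic greyscale sample-cell frame (uint8).

    ``bubbles`` lists ((cx, cy), radius, rim_contrast) triples: each bubble
    is a dark disc with a bright rim ``rim_contrast`` above the flat
    ``background``.  ``meniscus_row`` draws the bright edge and darker
    upper region of an incompletely loaded cell.  Deterministic for a given
    seed/generator.
    """
    h, w = shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.full((h, w), float(background))
    if meniscus_row is not None:
        img[: int(meniscus_row)] = background * 0.55
        lo = max(int(meniscus_row) - 1, 0)
        # specular reflection along the liquid edge
        img[lo : int(meniscus_row) + 2] = min(background * 4.0, 255.0)
    yy, xx = np.mgrid[0:h, 0:w]
    rim_width = 2.0
    for (cx, cy), radius, rim_contrast in bubbles:
        if radius <= 0:
            raise ValidationError("bubble radius must be positive")
        r = np.hypot(xx - cx, yy - cy)
        img[r < radius - rim_width] = background * 0.3
        rim = (r >= radius - rim_width) & (r < radius)
        img[rim] = min(background + rim_contrast, 255.0)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def save_frame(frame: np.ndarray, path) -> None:
    """Write an 8-bit greyscale frame as PNG/PGM (format from the suffix)."""
    Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="L").save(path)
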