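"""Gel image loading and preprocessing.

The processing convention follows the standard densitometry workflow: the gel
is photographed with the wells at the top (row 0), DNA appears dark on a light
background, and migration distance increases downward.  Scoring requires three
preprocessing steps, in order: colour inversion (so DNA is bright and density
curves are positive), leveling with respect to the top ladder band on each
side, and smooth-background subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage import transform

from ._morphology import rolling_ball_background
from .errors import GeometryError, ImageStateError, ParameterError

__all__ = [
    "GelImage",
    "load_image",
    "write_image",
    "invert_image",
    "level_image",
    "subtract_background",
    "DEFAULT_BALL_RADIUS",
]

#: Default rolling-ball radius in pixels.  The radius sets the paraboloid
#: curvature 1/(2*R*255): the ball must be flat enough not to dip laterally
#: between lanes (which shaves faint broad smears; needs R >~ 1000 for 24 px
#: lanes) yet curved enough to follow illumination vignettes (R <~ 1900 for
#: the backgrounds this package targets).
DEFAULT_BALL_RADIUS = 1200.0

#: Fraction of saturated source pixels above which a quality warning attaches
#: to downstream records.
SATURATION_WARN_FRACTION = 0.01


@dataclass(frozen=True)
class GelImage:
    """An intensity raster plus its processing state.

    ``data`` has rows along the migration axis (row 0 at the wells) and columns
    along the lateral axis, values normalized to [0, 1].
    """

    data: np.ndarray
    bit_depth: int = 16
    inverted: bool = False
    leveled: bool = False
    background_subtracted: bool = False
    rotation_applied: float = 0.0
    saturation_fraction: float = 0.0
    source: str = "array"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ParameterError("gel image must be a 2-D raster")
        if data.size and (data.min() < -1e-12 or data.max() > 1 + 1e-12):
            raise ParameterError("gel intensities must lie in [0, 1]")
        object.__setattr__(self, "data", np.clip(data, 0.0, 1.0))
        if self.background_subtracted and not self.inverted:
            raise ImageStateError("background subtraction requires an inverted image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def load_image(path: str | Path) -> GelImage:
    """Load an 8/16-bit grayscale (or RGB) TIFF or PNG as a :class:`GelImage`.

    The raster is normalized to [0, 1] by the bit-depth maximum and the
    fraction of saturated source pixels is recorded.  Orientation is assumed
    wells-at-top; no inversion is applied.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = np.asarray(Image.open(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read gel image {path}: {exc}") from exc

    if raw.ndim == 3:  # RGB(A) -> luminance (ITU-R 601)
        rgb = raw[..., :3].astype(float)
        raw_gray = rgb @ np.array([0.299, 0.587, 0.114])
    elif raw.ndim == 2:
        raw_gray = raw.astype(float)
    else:
        raise OSError(f"unsupported image dimensionality {raw.ndim} in {path}")

    if raw.dtype == np.uint8:
        depth, maxval = 8, 255.0
    elif raw.dtype == np.uint16:
        depth, maxval = 16, 65535.0
    else:
        raise OSError(f"unsupported bit depth {raw.dtype} in {path} (need uint8/uint16)")

    saturated = float(np.mean(raw_gray >= maxval)) if raw_gray.size else 0.0
    return GelImage(
        data=raw_gray / maxval,
        bit_depth=depth,
        saturation_fraction=saturated,
        source=str(path),
    )


def write_image(gel: GelImage, path: str | Path, bit_depth: int = 16) -> None:
    """Write the raster as a grayscale TIFF (8 or 16 bit) for audit."""
    if bit_depth == 16:
        arr = np.round(gel.data * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(gel.data * 255.0).astype(np.uint8)
    else:
        raise ParameterError("bit_depth must be 8 or 16")
    tifffile.imwrite(str(path), arr)


def invert_image(gel: GelImage) -> GelImage:
    """Colour-invert so DNA bands become bright (intensity -> 1 - intensity)."""
    if gel.inverted:
        raise ImageStateError("image is already inverted")
    if float(np.median(gel.data)) < float(np.mean(gel.data)) - 1e-6:
        warnings.warn(
            "image appears to have a dark background (median < mean); "
            "it may already be band-bright",
            stacklevel=2,
        )
    return replace(gel, data=1.0 - gel.data, inverted=True)


def level_image(
    gel: GelImage, left_ref: tuple[float, float], right_ref: tuple[float, float]
) -> GelImage:
    """Rotate about the image centre so two reference points share a row.

    The references are the top ladder-band centres in the left and right
    ladder lanes, given as (row, col).  Resampling is bilinear; a zero-angle
    call is the identity apart from the state flags.
    """
    (r1, c1), (r2, c2) = left_ref, right_ref
    if c1 == c2:
        raise GeometryError("reference points must have distinct columns")
    if c1 > c2:
        (r1, c1), (r2, c2) = (r2, c2), (r1, c1)
    angle_rad = np.arctan2(r2 - r1, c2 - c1)
    angle_deg = float(np.degrees(angle_rad))
    if angle_deg == 0.0:
        return replace(gel, leveled=True, rotation_applied=0.0)
    # transform.rotate's positive angle lifts the right-hand content upward in
    # display orientation, which levels a reference segment sloping down-right.
    data = transform.rotate(gel.data, angle_deg, order=1, mode="edge", preserve_range=True)
    return replace(
        gel, data=np.clip(data, 0.0, 1.0), leveled=True, rotation_applied=angle_deg
    )


def subtract_background(
    gel: GelImage,
    ball_radius: float = DEFAULT_BALL_RADIUS,
    smooth_sigma: float = 2.0,
) -> GelImage:
    """Remove smooth continuous background by rolling-ball opening.

    ``ball_radius`` (pixels) must exceed the largest band half-width so bands
    survive.  The background is estimated on a lightly Gaussian-smoothed copy
    of the image (``smooth_sigma``) so the ball rides the mean background
    rather than the noise minima — the same reason ImageJ pre-smooths before
    rolling the ball — then subtracted from the unsmoothed image and clamped
    at zero.
    """
    if ball_radius <= 0:
        raise ParameterError("ball_radius must be positive")
    if not gel.inverted:
        raise ImageStateError("background subtraction requires an inverted (band-bright) image")
    surface = gaussian_filter(gel.data, smooth_sigma) if smooth_sigma > 0 else gel.data
    background = rolling_ball_background(surface, ball_radius)
    data = np.clip(gel.data - background, 0.0, 1.0)
    return replace(gel, data=data, background_subtracted=True)
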