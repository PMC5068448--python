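"""Lane boxes and per-lane intensity profiles.

A lane is scored through a vertical box encompassing the whole migration
range; all boxes in one analysis share the same vertical extent, mirroring
the shared-box semantics of the classic ImageJ workflow.  The 1-D profile is
the mean intensity across the box width at each row, so a wider box on a
laterally uniform lane leaves the profile (and every downstream percentage)
unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d, grey_opening
from scipy.signal import find_peaks

from .errors import DetectionError, GeometryError, ParameterError
from .gelimage import GelImage

__all__ = [
    "LaneBox",
    "IntensityProfile",
    "define_lane",
    "auto_detect_lanes",
    "extract_profile",
    "load_lane_layout",
]


@dataclass(frozen=True)
class LaneBox:
    """Rectangular lane region: a vertical box over one lane."""

    center_col: float
    width: int
    row_top: int
    row_bottom: int
    role: str = "sample"  # "ladder" | "sample"
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("ladder", "sample"):
            raise ParameterError(f"lane role must be 'ladder' or 'sample', got {self.role!r}")
        if self.width < 3:
            raise GeometryError("lane box width must be at least 3 px")
        if self.row_top >= self.row_bottom:
            raise GeometryError("row_top must be smaller than row_bottom")

    @property
    def col_start(self) -> int:
        return int(round(self.center_col - self.width / 2))

    @property
    def col_stop(self) -> int:
        return self.col_start + self.width

    @property
    def height(self) -> int:
        return self.row_bottom - self.row_top


@dataclass(frozen=True)
class IntensityProfile:
    """1-D intensity vs migration distance for one lane box.

    ``values[r]`` is the mean intensity across the box width at image row
    ``lane.row_top + r``.  ``mask_segments`` lists artifact chords already
    applied, as (start_row, end_row) pairs in profile coordinates.
    """

    values: np.ndarray
    lane: LaneBox
    closed: bool = False
    closure_applied: bool = False
    mask_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != self.lane.height:
            raise ParameterError("profile length must equal the lane box height")
        if values.size and values.min() < -1e-12:
            raise ParameterError("profile values must be non-negative")
        object.__setattr__(self, "values", np.clip(values, 0.0, None))

    def __len__(self) -> int:
        return len(self.values)


def define_lane(
    gel: GelImage,
    center_col: float,
    width: int,
    row_top: int,
    row_bottom: int,
    role: str = "sample",
    label: str = "",
) -> LaneBox:
    """Validate and return a lane box fully inside the gel image."""
    box = LaneBox(center_col, int(width), int(row_top), int(row_bottom), role, label)
    nrows, ncols = gel.shape
    if box.row_top < 0 or box.row_bottom > nrows or box.col_start < 0 or box.col_stop > ncols:
        raise GeometryError(
            f"lane box {label!r} [{box.row_top}:{box.row_bottom}, "
            f"{box.col_start}:{box.col_stop}] lies outside the {nrows}x{ncols} image"
        )
    return box


def extract_profile(gel: GelImage, lane: LaneBox) -> IntensityProfile:
    """Mean-across-width intensity profile of one lane box."""
    nrows, ncols = gel.shape
    if lane.row_bottom > nrows or lane.col_start < 0 or lane.col_stop > ncols:
        raise GeometryError("lane box lies outside the gel image")
    block = gel.data[lane.row_top : lane.row_bottom, lane.col_start : lane.col_stop]
    return IntensityProfile(values=block.mean(axis=1), lane=lane)


def auto_detect_lanes(
    gel: GelImage,
    expected_count: int | None = None,
    row_top: int | None = None,
    row_bottom: int | None = None,
    smooth_sigma: float = 2.0,
) -> list[LaneBox]:
    """Propose lane boxes from peaks of the column-wise mean intensity.

    Intended as a convenience on a preprocessed (band-bright) gel; manual
    layouts remain authoritative.  Lanes are placed at peaks of the smoothed
    column-mean separated by at least half the median peak spacing, with a
    default width of 80% of the inter-lane spacing.  If ``expected_count``
    is set and not matched, candidates are returned with a warning.
    """
    nrows, ncols = gel.shape
    row_top = 0 if row_top is None else row_top
    row_bottom = nrows if row_bottom is None else row_bottom
    colmean = gel.data[row_top:row_bottom].mean(axis=0)
    smooth = gaussian_filter1d(colmean, smooth_sigma)
    # detrend slow lateral background (vignette) so lane tops stay symmetric
    baseline = grey_opening(smooth, size=max(5, ncols // 6))
    smooth = smooth - baseline
    span = float(smooth.max() - smooth.min())
    if span < 1e-6:
        raise DetectionError("no lanes detected: image has no lateral intensity structure")
    peaks, _ = find_peaks(smooth, prominence=0.1 * span)
    if len(peaks) == 0:
        raise DetectionError("no lanes detected: no column-intensity peaks found")
    if len(peaks) > 1:
        spacing = float(np.median(np.diff(peaks)))
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] >= spacing / 2:
                keep.append(p)
        peaks = np.asarray(keep)
    else:
        spacing = ncols / 4
    if expected_count is not None and len(peaks) != expected_count:
        warnings.warn(
            f"auto-detection found {len(peaks)} lanes, expected {expected_count}; "
            "returning candidates",
            stacklevel=2,
        )
    # refine plateau-shaped lane tops to the centroid of their half-height region
    centers = []
    for p in peaks:
        level = 0.5 * smooth[p]
        lo = p
        while lo > 0 and smooth[lo - 1] >= level and p - lo < spacing / 2:
            lo -= 1
        hi = p
        while hi < ncols - 1 and smooth[hi + 1] >= level and hi - p < spacing / 2:
            hi += 1
        w = smooth[lo : hi + 1]
        cols_w = np.arange(lo, hi + 1)
        centers.append(float((w * cols_w).sum() / w.sum()) if w.sum() > 0 else float(p))
    width = max(3, int(round(0.8 * spacing)))
    boxes = []
    for i, p in enumerate(centers):
        w = min(width, 2 * int(p), 2 * int(ncols - 1 - p))  # keep box inside image
        boxes.append(
            LaneBox(
                center_col=float(p),
                width=max(3, w),
                row_top=row_top,
                row_bottom=row_bottom,
                role="sample",
                label=f"lane{i + 1:02d}",
            )
        )
    return boxes


def load_lane_layout(path: str | Path) -> list[LaneBox]:
    """Load lane boxes from a JSON/YAML layout config.

    Format::

        row_top: 20
        row_bottom: 380
        lanes:
          - {label: ladderL, role: ladder, center_col: 40, width: 24}
          - {label: I, role: sample, center_col: 100, width: 24}
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    try:
        row_top, row_bottom = int(cfg["row_top"]), int(cfg["row_bottom"])
        lanes = [
            LaneBox(
                center_col=float(entry["center_col"]),
                width=int(entry["width"]),
                row_top=row_top,
                row_bottom=row_bottom,
                role=entry.get("role", "sample"),
                label=str(entry.get("label", f"lane{i + 1:02d}")),
            )
            for i, entry in enumerate(cfg["lanes"])
        ]
    except KeyError as exc:
        raise ParameterError(f"lane layout {path} is missing required key {exc}") from exc
    return lanes
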