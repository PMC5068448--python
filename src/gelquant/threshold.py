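"""Percent-above-threshold quantification: the core scoring algorithm.

The DNA Threshold is a ladder band (for example the 9,416 bp band of the
lambda/HindIII digest).  Its apex is located in the intensity profile of each
of the two flanking ladder lanes; a straight line between the two apexes
defines a per-lane threshold row for every bracketed sample lane (so linear
gel skew is compensated without re-detecting anything in the samples).  The
region of each closed sample profile nearer the wells than the threshold row
integrates to the "above" area (fragments at or above the threshold size);
the Percent Above Threshold is 100 * above / (above + below).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    BracketingError,
    GelQuantError,
    GeometryError,
    LadderCallError,
    ParameterError,
    ThresholdError,
)
from .gelimage import (
    DEFAULT_BALL_RADIUS,
    SATURATION_WARN_FRACTION,
    GelImage,
    invert_image,
    subtract_background,
)
from .ladders import LadderDefinition
from .lanes import IntensityProfile, LaneBox, extract_profile

__all__ = [
    "PeakCall",
    "ThresholdSpec",
    "LaneQuantification",
    "ScoredGel",
    "find_band_peaks",
    "apex_of_threshold_band",
    "threshold_row_for_lane",
    "close_profile",
    "mask_artifact",
    "integrate_regions",
    "percent_above_threshold",
    "score_gel",
]


@dataclass(frozen=True)
class PeakCall:
    """A detected ladder-band apex, possibly assigned to a fragment size."""

    row: float  # profile-relative, sub-pixel
    height: float
    prominence: float
    assigned_size: int | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.prominence > self.height + 1e-12:
            raise ParameterError("peak height must be positive and >= prominence")


@dataclass(frozen=True)
class ThresholdSpec:
    """The apex-to-apex DNA-threshold line across the gel."""

    ladder_name: str
    band_size: int
    left_apex_row: float  # absolute image rows
    right_apex_row: float
    left_lane_col: float
    right_lane_col: float


@dataclass(frozen=True)
class LaneQuantification:
    """Areas and Percent Above Threshold for one sample lane."""

    label: str
    threshold_row: float  # absolute image row in this lane
    area_above: float
    area_below: float
    percent_above: float | None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.area_above < 0 or self.area_below < 0:
            raise GelQuantError("internal invariant violation: negative area")
        if self.percent_above is not None and not 0.0 <= self.percent_above <= 100.0:
            raise GelQuantError("internal invariant violation: percent outside [0, 100]")


def _subpixel_apex(values: np.ndarray, idx: int) -> float:
    """Parabolic refinement of a local maximum through its two neighbours."""
    if idx <= 0 or idx >= len(values) - 1:
        return float(idx)
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def _best_assignment(
    rows: np.ndarray, heights: np.ndarray, sizes: Sequence[int], rms_tol: float
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Order-preserving peak-to-band matching by log-linear fit quality.

    Larger fragment sizes must sit at smaller rows.  Among assignments of
    equal cardinality the lowest migration-fit RMS wins, then the largest
    total peak height; cardinality is reduced only when no assignment fits
    within ``rms_tol``.
    """
    logs = np.log10(np.asarray(sizes, dtype=float))
    n_pk, n_bd = len(rows), len(sizes)
    for k in range(min(n_pk, n_bd), 1, -1):
        candidates = []
        for pk in combinations(range(n_pk), k):
            prow = rows[list(pk)]
            for bd in combinations(range(n_bd), k):
                x = logs[list(bd)]
                if k == 2:
                    slope = (prow[1] - prow[0]) / (x[1] - x[0])
                    if slope >= 0:
                        continue
                    rms = 0.0
                else:
                    slope, intercept = np.polyfit(x, prow, 1)
                    if slope >= 0:
                        continue
                    rms = float(np.sqrt(np.mean((intercept + slope * x - prow) ** 2)))
                candidates.append((rms, -float(heights[list(pk)].sum()), pk, bd))
        if not candidates:
            continue
        candidates.sort()
        rms, _, pk, bd = candidates[0]
        if rms <= rms_tol or k == 2:
            return pk, bd
    raise LadderCallError("fewer than 2 ladder bands could be assigned")


def find_band_peaks(
    profile: IntensityProfile,
    ladder: LadderDefinition,
    prominence_frac: float = 0.05,
    max_peaks: int = 9,
) -> list[PeakCall]:
    """Detect band apexes in a ladder-lane profile and assign fragment sizes.

    Local maxima with prominence of at least ``prominence_frac`` of the
    profile maximum are detected (sub-pixel refined), then greedily matched to
    ladder band sizes preserving migration order.  Peaks left unassigned are
    returned with ``assigned_size=None``; missing bands are simply absent from
    the assigned set.
    """
    values = profile.values
    vmax = float(values.max(initial=0.0))
    if vmax <= 0:
        raise LadderCallError(f"ladder lane {profile.lane.label!r} is empty")
    idx, props = find_peaks(values, prominence=prominence_frac * vmax)
    if len(idx) < 2:
        raise LadderCallError(
            f"only {len(idx)} band peak(s) detected in ladder lane "
            f"{profile.lane.label!r}; need at least 2"
        )
    if len(idx) > max_peaks:  # keep the most prominent, in row order
        keep = np.sort(np.argsort(props["prominences"])[-max_peaks:])
        idx, props = idx[keep], {k: v[keep] for k, v in props.items()}
    rows = np.array([_subpixel_apex(values, i) for i in idx])
    heights = values[idx].astype(float)
    proms = props["prominences"].astype(float)

    rms_tol = max(3.0, 0.02 * len(values))
    pk_sel, bd_sel = _best_assignment(rows, heights, ladder.band_sizes, rms_tol)
    assigned = dict(zip(pk_sel, bd_sel))
    return [
        PeakCall(
            row=float(rows[i]),
            height=float(heights[i]),
            prominence=float(min(proms[i], heights[i])),
            assigned_size=ladder.band_sizes[assigned[i]] if i in assigned else None,
        )
        for i in range(len(rows))
    ]


def apex_of_threshold_band(
    peaks: Sequence[PeakCall], band_size: int, lane_label: str = ""
) -> float:
    """Profile row of the apex assigned to ``band_size``."""
    for p in peaks:
        if p.assigned_size == int(band_size):
            return p.row
    where = f" in ladder lane {lane_label!r}" if lane_label else ""
    raise ThresholdError(f"threshold band {band_size} bp is not assigned{where}")


def threshold_row_for_lane(spec: ThresholdSpec, lane_center_col: float) -> float:
    """Straight-line interpolation of the threshold row at a lane's column."""
    if not spec.left_lane_col <= lane_center_col <= spec.right_lane_col:
        raise BracketingError(
            f"lane at column {lane_center_col} is outside the bracketing ladders "
            f"[{spec.left_lane_col}, {spec.right_lane_col}]"
        )
    frac = (lane_center_col - spec.left_lane_col) / (spec.right_lane_col - spec.left_lane_col)
    return spec.left_apex_row + (spec.right_apex_row - spec.left_apex_row) * frac


def close_profile(profile: IntensityProfile, tol_frac: float = 0.01) -> IntensityProfile:
    """Close the profile region for integration.

    If the terminal value exceeds ``tol_frac`` of the profile maximum the
    region is closed by a vertical drop at the final row — which adds no area,
    so the values are unchanged; only the closure state is recorded.
    """
    vmax = float(profile.values.max(initial=0.0))
    applied = bool(vmax > 0 and profile.values[-1] > tol_frac * vmax)
    return replace(profile, closed=True, closure_applied=applied)


def mask_artifact(profile: IntensityProfile, start_row: int, end_row: int) -> IntensityProfile:
    """Replace an artifact spur by the straight chord between two profile rows.

    Mirrors the manual straight-line elimination of an erroneous peak: values
    strictly inside ``(start_row, end_row)`` are replaced by the linear chord
    between ``values[start_row]`` and ``values[end_row]``.
    """
    start_row, end_row = int(start_row), int(end_row)
    if not 0 <= start_row < end_row <= len(profile) - 1:
        raise ParameterError(
            f"mask rows ({start_row}, {end_row}) must be increasing and inside the profile"
        )
    values = profile.values.copy()
    values[start_row : end_row + 1] = np.linspace(
        values[start_row], values[end_row], end_row - start_row + 1
    )
    return replace(
        profile,
        values=values,
        mask_segments=profile.mask_segments + ((start_row, end_row),),
    )


def integrate_regions(
    profile: IntensityProfile, threshold_row: float
) -> tuple[float, float]:
    """Trapezoidal areas above (nearer the wells) and below the threshold row.

    ``threshold_row`` is profile-relative and may be fractional; the trapezoid
    cell containing it is split exactly, so the two areas always sum to the
    profile's total integral.
    """
    if not profile.closed:
        raise ParameterError("profile must be closed before integration")
    v = profile.values
    t = float(threshold_row)
    if not 0.0 <= t <= len(v) - 1:
        raise ParameterError(f"threshold row {t} outside profile [0, {len(v) - 1}]")
    i = int(math.floor(t))
    if t == i:
        area_above = float(np.trapezoid(v[: i + 1]))
        area_below = float(np.trapezoid(v[i:]))
    else:
        vt = v[i] + (t - i) * (v[i + 1] - v[i])
        area_above = float(np.trapezoid(v[: i + 1])) + 0.5 * (v[i] + vt) * (t - i)
        area_below = 0.5 * (vt + v[i + 1]) * (i + 1 - t) + float(np.trapezoid(v[i + 1 :]))
    return area_above, area_below


def percent_above_threshold(
    area_above: float, area_below: float, profile_length: int | None = None
) -> float | None:
    """Percent Above Threshold: 100 * above / (above + below).

    Returns ``None`` (with an empty-lane warning) when the total area is
    negligible — below ``1e-6 *`` the profile length when a length is given,
    or exactly zero otherwise.
    """
    if area_above < 0 or area_below < 0:
        raise GelQuantError("internal invariant violation: negative area")
    total = area_above + area_below
    floor = 1e-6 * profile_length if profile_length else 0.0
    if total <= floor:
        warnings.warn("empty lane: total area is negligible; percent undefined", stacklevel=2)
        return None
    return 100.0 * area_above / total


@dataclass(frozen=True)
class ScoredGel:
    """Result of scoring a whole gel: per-lane quantifications plus context."""

    quantifications: tuple[LaneQuantification, ...]
    threshold_spec: ThresholdSpec
    ladder: LadderDefinition
    sample_profiles: dict
    ladder_profiles: dict
    ladder_peaks: dict
    gel: GelImage
    params: dict

    def __iter__(self):
        return iter(self.quantifications)

    def percent(self, label: str) -> float | None:
        for q in self.quantifications:
            if q.label == label:
                return q.percent_above
        raise KeyError(label)


def _pick_ladder_lane(
    gel: GelImage,
    candidates: Sequence[LaneBox],
    ladder: LadderDefinition,
    prominence_frac: float,
) -> tuple[LaneBox, list[PeakCall]]:
    """Pick the dilution lane with the most assigned bands (ties: brightest)."""
    scored = []
    for box in candidates:
        prof = extract_profile(gel, box)
        try:
            peaks = find_band_peaks(prof, ladder, prominence_frac=prominence_frac)
        except LadderCallError:
            continue
        n_assigned = sum(p.assigned_size is not None for p in peaks)
        scored.append((n_assigned, float(prof.values.sum()), box, peaks))
    if not scored:
        raise LadderCallError("no usable ladder lane: band assignment failed on every candidate")
    scored.sort(key=lambda s: (s[0], s[1]))
    _, _, box, peaks = scored[-1]
    return box, peaks


def score_gel(
    gel: GelImage,
    lanes: Sequence[LaneBox],
    ladder: LadderDefinition,
    band_size: int,
    masks: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    ball_radius: float = DEFAULT_BALL_RADIUS,
    prominence_frac: float = 0.05,
    closure_tol_frac: float = 0.01,
) -> ScoredGel:
    """Run the full scoring pipeline on one gel.

    Preprocessing (inversion, rolling-ball background subtraction) is applied
    if the image state flags show it has not been done yet; leveling is
    optional because the apex-to-apex threshold line already compensates
    linear skew.  ``masks`` maps sample-lane labels to artifact segments given
    as (start_row, end_row) in absolute image rows.

    Every sample lane must be bracketed by at least one ladder lane on each
    side; with several dilution lanes per side the one with the most assigned
    bands (ties: brightest) is used.
    """
    band_size = int(band_size)
    if band_size not in ladder:
        raise ThresholdError(f"{band_size} bp is not a band of ladder {ladder.name!r}")
    extents = {(l.row_top, l.row_bottom) for l in lanes}
    if len(extents) > 1:
        raise GeometryError("all lane boxes in one analysis must share the vertical extent")
    row_top = lanes[0].row_top

    if not gel.inverted:
        gel = invert_image(gel)
    if not gel.background_subtracted:
        gel = subtract_background(gel, ball_radius)

    ladder_lanes = [l for l in lanes if l.role == "ladder"]
    sample_lanes = [l for l in lanes if l.role == "sample"]
    if not sample_lanes:
        raise ParameterError("no sample lanes to score")
    lo = min(l.center_col for l in sample_lanes)
    hi = max(l.center_col for l in sample_lanes)
    left_cands = [l for l in ladder_lanes if l.center_col < lo]
    right_cands = [l for l in ladder_lanes if l.center_col > hi]
    if not left_cands or not right_cands:
        raise BracketingError(
            "sample lanes must be bracketed by a ladder lane on each side"
        )

    left_box, left_peaks = _pick_ladder_lane(gel, left_cands, ladder, prominence_frac)
    right_box, right_peaks = _pick_ladder_lane(gel, right_cands, ladder, prominence_frac)
    left_apex = apex_of_threshold_band(left_peaks, band_size, left_box.label)
    right_apex = apex_of_threshold_band(right_peaks, band_size, right_box.label)

    spec = ThresholdSpec(
        ladder_name=ladder.name,
        band_size=band_size,
        left_apex_row=row_top + left_apex,
        right_apex_row=row_top + right_apex,
        left_lane_col=left_box.center_col,
        right_lane_col=right_box.center_col,
    )

    global_warnings = []
    if gel.saturation_fraction > SATURATION_WARN_FRACTION:
        global_warnings.append(
            f"saturation: {gel.saturation_fraction:.1%} of source pixels saturated"
        )

    masks = masks or {}
    results = []
    sample_profiles: dict[str, IntensityProfile] = {}
    for box in sample_lanes:
        lane_warnings = list(global_warnings)
        prof = extract_profile(gel, box)
        for start, end in masks.get(box.label, ()):
            prof = mask_artifact(prof, int(start) - row_top, int(end) - row_top)
        prof = close_profile(prof, closure_tol_frac)
        if prof.closure_applied:
            lane_warnings.append("closure applied: profile did not return to baseline")
        t_abs = threshold_row_for_lane(spec, box.center_col)
        t_rel = t_abs - row_top
        area_above, area_below = integrate_regions(prof, t_rel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = percent_above_threshold(area_above, area_below, len(prof))
        if pct is None:
            lane_warnings.append("empty lane: total area is negligible; percent undefined")
        sample_profiles[box.label] = prof
        results.append(
            LaneQuantification(
                label=box.label,
                threshold_row=t_abs,
                area_above=area_above,
                area_below=area_below,
                percent_above=pct,
                warnings=tuple(lane_warnings),
            )
        )

    return ScoredGel(
        quantifications=tuple(results),
        threshold_spec=spec,
        ladder=ladder,
        sample_profiles=sample_profiles,
        ladder_profiles={
            left_box.label: extract_profile(gel, left_box),
            right_box.label: extract_profile(gel, right_box),
        },
        ladder_peaks={left_box.label: left_peaks, right_box.label: right_peaks},
        gel=gel,
        params={
            "ball_radius_px": ball_radius,
            "prominence_frac": prominence_frac,
            "closure_tol_frac": closure_tol_frac,
            "profile_statistic": "mean-across-width",
        },
    )
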