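"""DNA ladder catalog and size <-> migration-distance calibration.

Agarose migration distance is, to first order, linear in log10(fragment size).
A :class:`MigrationModel` is least-squares fitted to matched (band position,
band size) pairs and exposes the forward map (``position_of_size``) and its
inverse (``size_at_position``).  Residuals are reported per band so curvature
is visible to the user rather than silently absorbed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CalibrationError, CatalogError, ParameterError

__all__ = [
    "LadderDefinition",
    "MigrationModel",
    "Estimate",
    "builtin_ladder",
    "available_ladders",
    "load_ladder",
    "fit_migration_model",
]


@dataclass(frozen=True)
class LadderDefinition:
    """A named set of ladder fragment sizes (bp), largest first."""

    name: str
    band_sizes: tuple[int, ...]
    threshold_candidates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.band_sizes)
        if len(sizes) < 1 or any(s <= 0 for s in sizes):
            raise CatalogError(f"ladder {self.name!r}: band sizes must be positive")
        if list(sizes) != sorted(sizes, reverse=True) or len(set(sizes)) != len(sizes):
            raise CatalogError(f"ladder {self.name!r}: band sizes must be strictly decreasing")
        object.__setattr__(self, "band_sizes", sizes)
        cands = tuple(int(c) for c in self.threshold_candidates)
        unknown = [c for c in cands if c not in sizes]
        if unknown:
            raise CatalogError(
                f"ladder {self.name!r}: threshold candidates {unknown} are not ladder bands"
            )
        object.__setattr__(self, "threshold_candidates", cands)

    def __contains__(self, size: int) -> bool:
        return int(size) in self.band_sizes


def _catalog() -> dict:
    with resources.files("gelquant.data").joinpath("ladders.json").open() as fh:
        return json.load(fh)


def available_ladders() -> list[str]:
    return sorted(_catalog())


def builtin_ladder(name: str) -> LadderDefinition:
    """Look up a ladder in the built-in catalog (e.g. ``"hindiii"``)."""
    cat = _catalog()
    key = name.strip().lower()
    if key not in cat:
        raise CatalogError(
            f"unknown ladder {name!r}; available ladders: {', '.join(sorted(cat))}"
        )
    entry = cat[key]
    return LadderDefinition(
        name=entry["name"],
        band_sizes=tuple(entry["band_sizes_bp"]),
        threshold_candidates=tuple(entry.get("threshold_candidates_bp", ())),
    )


def load_ladder(path: str | Path) -> LadderDefinition:
    """Load a user ladder from a JSON file with the catalog entry format."""
    with open(path) as fh:
        entry = json.load(fh)
    return LadderDefinition(
        name=entry["name"],
        band_sizes=tuple(entry["band_sizes_bp"]),
        threshold_candidates=tuple(entry.get("threshold_candidates_bp", ())),
    )


@dataclass(frozen=True)
class Estimate:
    """A calibrated value plus an extrapolation flag."""

    value: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class MigrationModel:
    """Log-linear migration calibration: distance = intercept + slope*log10(size).

    ``slope`` is negative (larger fragments migrate less).  ``residuals`` are
    observed minus fitted positions, in pixels, for each calibration band.
    """

    intercept: float
    slope: float
    band_sizes: tuple[int, ...] = ()
    band_positions: tuple[float, ...] = ()
    residuals: tuple[float, ...] = ()
    size_range: tuple[float, float] = (0.0, math.inf)  # (min bp, max bp)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError("migration slope must be negative (distance falls with size)")

    def position_of_size(self, size: float) -> Estimate:
        """Predicted migration distance (pixels from the wells) of a fragment."""
        if size <= 0:
            raise ParameterError("fragment size must be positive")
        extrap = not (self.size_range[0] <= size <= self.size_range[1])
        return Estimate(self.intercept + self.slope * math.log10(size), extrap)

    def size_at_position(self, distance: float) -> Estimate:
        """Inverse map: fragment size (bp) at a migration distance."""
        log_size = (distance - self.intercept) / self.slope
        size = 10.0**log_size
        extrap = not (self.size_range[0] <= size <= self.size_range[1])
        return Estimate(size, extrap)


def fit_migration_model(
    band_positions: Sequence[float], band_sizes: Sequence[float]
) -> MigrationModel:
    """Least-squares fit of migration distance vs log10(fragment size).

    Positions are pixel distances from the wells; sizes are in bp.  Requires at
    least two matched pairs, and positions must increase strictly as sizes
    decrease (fragments never overtake smaller ones).
    """
    pos = np.asarray(band_positions, dtype=float)
    sizes = np.asarray(band_sizes, dtype=float)
    if pos.shape != sizes.shape or pos.ndim != 1:
        raise CalibrationError("band_positions and band_sizes must be matched 1-D sequences")
    if len(pos) < 2:
        raise CalibrationError("need at least 2 matched (position, size) pairs")
    if np.any(sizes <= 0):
        raise CalibrationError("band sizes must be positive")
    order = np.argsort(-sizes)  # largest fragment first
    sizes, pos = sizes[order], pos[order]
    if np.any(np.diff(sizes) >= 0) or np.any(np.diff(pos) <= 0):
        raise CalibrationError(
            "calibration pairs are not monotone: positions must strictly increase "
            "as fragment sizes decrease"
        )
    x = np.log10(sizes)
    slope, intercept = np.polyfit(x, pos, 1)
    fitted = intercept + slope * x
    return MigrationModel(
        intercept=float(intercept),
        slope=float(slope),
        band_sizes=tuple(int(s) for s in sizes),
        band_positions=tuple(float(p) for p in pos),
        residuals=tuple(float(r) for r in (pos - fitted)),
        size_range=(float(sizes.min()), float(sizes.max())),
    )
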