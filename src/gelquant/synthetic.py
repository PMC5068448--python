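"""Forward simulator for genomic-DNA agarose gel images with known truth.

Each sample lane carries a fragment-size distribution modelled as a two
component mixture on the log10(bp) scale: a narrow "intact" high-molecular
weight component (centred near 30 kb) and a broader "degraded" smear.  The
mixture describes DNA *mass* (intercalating stains bind per base pair), so
the true percent of DNA above a ladder band size is the mixture's upper tail
mass, available in closed form.

Rendering maps mass density through a log-linear migration model
(distance = a + b*log10(bp), b < 0), convolves with a Gaussian band spread,
broadcasts across the lane width, then applies background (constant +
vignette), gel skew (small-angle vertical shear), sensor noise, and optional
dark artifact specks.  The photographic convention is light background with
dark DNA, wells at the top; scoring pipelines must invert first.  A seed
fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import norm

from .errors import ParameterError, SpecError
from .gelimage import GelImage
from .ladders import LadderDefinition, MigrationModel, builtin_ladder
from .lanes import LaneBox

__all__ = [
    "LaneMixture",
    "Speck",
    "SyntheticGelSpec",
    "GroundTruth",
    "true_percent_above",
    "analytic_lane_profile",
    "analytic_ladder_profile",
    "render_gel",
    "degrade",
    "random_gel_spec",
    "sample_fragment_sizes",
    "default_lane_boxes",
]

# default migration calibration: 23,130 bp at row 60 and 564 bp at row 340
_LOG_BIG, _LOG_SMALL = math.log10(23130), math.log10(564)
DEFAULT_SLOPE = (340.0 - 60.0) / (_LOG_SMALL - _LOG_BIG)  # ~ -173.6 px per log10(bp)
DEFAULT_INTERCEPT = 60.0 - DEFAULT_SLOPE * _LOG_BIG


@dataclass(frozen=True)
class LaneMixture:
    """Mass-weighted fragment-size mixture of one sample lane (log10 bp scale)."""

    w_intact: float = 0.5
    mu_intact: float = math.log10(30000.0)
    sigma_intact: float = 0.04
    mu_degraded: float = 3.45
    sigma_degraded: float = 0.30
    mass: float = 16.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_intact <= 1.0:
            raise SpecError("w_intact must lie in [0, 1]")
        if self.sigma_intact <= 0 or self.sigma_degraded <= 0 or self.mass < 0:
            raise SpecError("mixture scales must be positive and mass non-negative")

    def fraction_above(self, band_size: float) -> float:
        """Closed-form mass fraction of fragments longer than ``band_size``."""
        x = math.log10(band_size)
        tail_i = norm.sf(x, loc=self.mu_intact, scale=self.sigma_intact)
        tail_d = norm.sf(x, loc=self.mu_degraded, scale=self.sigma_degraded)
        return float(self.w_intact * tail_i + (1.0 - self.w_intact) * tail_d)


@dataclass(frozen=True)
class Speck:
    """A dark artifact blob in the gel (a flaw, not DNA)."""

    row: float
    col: float
    amplitude: float = 0.3
    sigma: float = 3.0


@dataclass(frozen=True)
class SyntheticGelSpec:
    """Full description of a synthetic gel; the seed determines the image."""

    rows: int = 400
    cols: int = 440
    ladder_cols: tuple[float, ...] = (40.0, 400.0)
    sample_cols: tuple[float, ...] = (100.0, 175.0, 250.0, 325.0)
    samples: tuple[LaneMixture, ...] = (
        LaneMixture(w_intact=0.9),
        LaneMixture(w_intact=0.5),
        LaneMixture(w_intact=0.2),
        LaneMixture(w_intact=0.0),
    )
    lane_width: int = 24
    edge_ramp: int = 4
    migration_intercept: float = DEFAULT_INTERCEPT
    migration_slope: float = DEFAULT_SLOPE
    sigma_band: float = 3.0
    ladder_name: str = "hindiii"
    ladder_mass: float = 8.0
    ladder_band_weights: tuple[float, ...] | None = None  # default: sqrt(bp), normalized
    ladder_dilutions: tuple[float, ...] = (1.0, 1.0)
    background_const: float = 0.08
    vignette_amplitude: float = 0.06
    noise_sigma: float = 0.005
    skew_deg: float = 0.0
    specks: tuple[Speck, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration_slope >= 0:
            raise SpecError("migration slope must be negative")
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be non-negative")
        if len(self.samples) != len(self.sample_cols):
            raise SpecError("one mixture is required per sample lane")
        if len(self.ladder_dilutions) != len(self.ladder_cols):
            raise SpecError("one dilution factor is required per ladder lane")

    # -- derived geometry -------------------------------------------------
    @property
    def ladder(self) -> LadderDefinition:
        return builtin_ladder(self.ladder_name)

    @property
    def migration_model(self) -> MigrationModel:
        sizes = self.ladder.band_sizes
        return MigrationModel(
            intercept=self.migration_intercept,
            slope=self.migration_slope,
            band_sizes=sizes,
            band_positions=tuple(self.band_row(s) for s in sizes),
            residuals=(0.0,) * len(sizes),
            size_range=(float(min(sizes)), float(max(sizes))),
        )

    def band_row(self, band_size: float, col: float | None = None) -> float:
        """True centre row of a fragment of ``band_size`` bp (skew included)."""
        row = self.migration_intercept + self.migration_slope * math.log10(band_size)
        if col is not None and self.skew_deg != 0.0:
            row += math.tan(math.radians(self.skew_deg)) * (col - (self.cols - 1) / 2.0)
        return row

    def _layout(self) -> list[tuple[str, float, str]]:
        """(label, column, role) for every lane, in column order."""
        lo = min(self.sample_cols)
        left = sorted(c for c in self.ladder_cols if c < lo)
        right = sorted(c for c in self.ladder_cols if c >= lo)

        def named(prefix: str, cols: list[float]) -> list[tuple[str, float]]:
            if len(cols) == 1:
                return [(prefix, cols[0])]
            return [(f"{prefix}{i + 1}", c) for i, c in enumerate(cols)]

        entries = [(lab, c, "ladder") for lab, c in named("ladderL", left)]
        entries += [(f"S{i + 1}", c, "sample") for i, c in enumerate(self.sample_cols)]
        entries += [(lab, c, "ladder") for lab, c in named("ladderR", right)]
        entries.sort(key=lambda e: e[1])
        return entries

    @property
    def lane_cols(self) -> tuple[float, ...]:
        return tuple(c for _, c, _ in self._layout())

    @property
    def lane_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _, _ in self._layout())

    def band_weights(self) -> np.ndarray:
        sizes = np.asarray(self.ladder.band_sizes, dtype=float)
        w = (
            np.asarray(self.ladder_band_weights, dtype=float)
            if self.ladder_band_weights is not None
            else np.sqrt(sizes)
        )
        if len(w) != len(sizes):
            raise SpecError("ladder_band_weights must match the ladder band count")
        return w / w.sum()

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["samples"] = [asdict(m) for m in self.samples]
        d["specks"] = [asdict(s) for s in self.specks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGelSpec":
        d = dict(d)
        if "samples" in d:
            d["samples"] = tuple(LaneMixture(**m) for m in d["samples"])
        if "specks" in d:
            d["specks"] = tuple(Speck(**s) for s in d["specks"])
        for key in ("ladder_cols", "sample_cols", "ladder_dilutions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("ladder_band_weights") is not None:
            d["ladder_band_weights"] = tuple(d["ladder_band_weights"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Per-lane truth of a rendered gel.

    ``fraction_above[band_size]`` holds the true mass fraction above that
    band for each sample lane (ordered as ``sample_labels``);
    ``band_rows[band_size]`` holds the true band-centre row in every lane
    (ordered as ``lane_labels``), skew included.
    """

    lane_labels: tuple[str, ...]
    lane_cols: tuple[float, ...]
    sample_labels: tuple[str, ...]
    fraction_above: dict[int, tuple[float, ...]]
    band_rows: dict[int, tuple[float, ...]]

    def percent_above(self, band_size: int, lane: int | str) -> float:
        idx = self.sample_labels.index(lane) if isinstance(lane, str) else lane
        return 100.0 * self.fraction_above[int(band_size)][idx]

    def to_dict(self) -> dict:
        return {
            "lane_labels": list(self.lane_labels),
            "lane_cols": list(self.lane_cols),
            "sample_labels": list(self.sample_labels),
            "fraction_above": {str(k): list(v) for k, v in self.fraction_above.items()},
            "band_rows": {str(k): list(v) for k, v in self.band_rows.items()},
        }


def true_percent_above(spec: SyntheticGelSpec, lane: int, band_size: float) -> float:
    """True percent of lane DNA mass above ``band_size``, from the closed form."""
    return 100.0 * spec.samples[lane].fraction_above(band_size)


def _row_density(rows: int, centers, sds, masses) -> np.ndarray:
    """Sum of Gaussian mass densities evaluated on integer rows."""
    r = np.arange(rows, dtype=float)[:, None]
    centers = np.atleast_1d(np.asarray(centers, dtype=float))[None, :]
    sds = np.atleast_1d(np.asarray(sds, dtype=float))[None, :]
    masses = np.atleast_1d(np.asarray(masses, dtype=float))[None, :]
    dens = masses * np.exp(-0.5 * ((r - centers) / sds) ** 2) / (sds * math.sqrt(2 * math.pi))
    return dens.sum(axis=1)


def analytic_lane_profile(spec: SyntheticGelSpec, lane: int) -> np.ndarray:
    """Noise/background-free 1-D mass-density profile of a sample lane.

    A Gaussian mixture in log-size maps through the linear migration model to
    a Gaussian mixture in row coordinates; the band spread adds in quadrature,
    so the convolution is exact.
    """
    m = spec.samples[lane]
    b = spec.migration_slope
    centers = [
        spec.migration_intercept + b * m.mu_intact,
        spec.migration_intercept + b * m.mu_degraded,
    ]
    sds = [
        math.hypot(b * m.sigma_intact, spec.sigma_band),
        math.hypot(b * m.sigma_degraded, spec.sigma_band),
    ]
    masses = [m.mass * m.w_intact, m.mass * (1.0 - m.w_intact)]
    return _row_density(spec.rows, centers, sds, masses)


def analytic_ladder_profile(spec: SyntheticGelSpec, dilution: float = 1.0) -> np.ndarray:
    """Noise/background-free 1-D profile of a ladder lane (discrete bands)."""
    sizes = spec.ladder.band_sizes
    centers = [spec.band_row(s) for s in sizes]
    if min(centers) < 0 or max(centers) >= spec.rows:
        raise SpecError("migration model places ladder bands outside the image")
    masses = spec.ladder_mass * dilution * spec.band_weights()
    sds = [spec.sigma_band] * len(sizes)
    return _row_density(spec.rows, centers, sds, masses)


def _lateral_weight(cols: int, center: float, half: float, ramp: float) -> np.ndarray:
    """Flat-top lane cross-section with cosine shoulders."""
    d = np.abs(np.arange(cols, dtype=float) - center)
    w = np.zeros(cols)
    w[d <= half] = 1.0
    shoulder = (d > half) & (d < half + ramp)
    w[shoulder] = 0.5 * (1.0 + np.cos(math.pi * (d[shoulder] - half) / ramp))
    return w


def render_gel(spec: SyntheticGelSpec) -> tuple[GelImage, GroundTruth]:
    """Render the gel photograph and its ground truth.

    Order of corruption: DNA signal -> specks -> skew shear -> background
    (constant + vignette) -> photographic inversion -> Gaussian noise -> clamp.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols
    half = spec.lane_width / 2.0

    signal = np.zeros((rows, cols))
    for col, dil in zip(spec.ladder_cols, spec.ladder_dilutions):
        signal += np.outer(
            analytic_ladder_profile(spec, dil), _lateral_weight(cols, col, half, spec.edge_ramp)
        )
    for i, col in enumerate(spec.sample_cols):
        signal += np.outer(
            analytic_lane_profile(spec, i), _lateral_weight(cols, col, half, spec.edge_ramp)
        )

    for sp in spec.specks:
        rr = np.arange(rows, dtype=float)[:, None]
        cc = np.arange(cols, dtype=float)[None, :]
        signal += sp.amplitude * np.exp(
            -0.5 * (((rr - sp.row) / sp.sigma) ** 2 + ((cc - sp.col) / sp.sigma) ** 2)
        )

    if spec.skew_deg != 0.0:
        shift = math.tan(math.radians(spec.skew_deg)) * (
            np.arange(cols, dtype=float) - (cols - 1) / 2.0
        )
        rr = np.arange(rows, dtype=float)[:, None] - shift[None, :]
        cc = np.broadcast_to(np.arange(cols, dtype=float)[None, :], (rows, cols))
        signal = map_coordinates(signal, [rr, cc], order=1, mode="constant")

    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    vignette = spec.vignette_amplitude * np.exp(
        -0.5
        * (
            ((rr - (rows - 1) / 2.0) / (0.55 * rows)) ** 2
            + ((cc - (cols - 1) / 2.0) / (0.55 * cols)) ** 2
        )
    )
    signal += spec.background_const + vignette

    photo = 1.0 - signal
    if spec.noise_sigma > 0:
        photo = photo + rng.normal(0.0, spec.noise_sigma, size=photo.shape)
    saturation = float(np.mean((photo <= 0.0) | (photo >= 1.0)))
    photo = np.clip(photo, 0.0, 1.0)

    gel = GelImage(
        data=photo,
        bit_depth=16,
        saturation_fraction=saturation,
        source=f"synthetic(seed={spec.seed})",
    )

    band_sizes = spec.ladder.band_sizes
    truth = GroundTruth(
        lane_labels=spec.lane_labels,
        lane_cols=spec.lane_cols,
        sample_labels=tuple(f"S{i + 1}" for i in range(len(spec.sample_cols))),
        fraction_above={
            s: tuple(m.fraction_above(s) for m in spec.samples) for s in band_sizes
        },
        band_rows={
            s: tuple(spec.band_row(s, col) for col in spec.lane_cols) for s in band_sizes
        },
    )
    return gel, truth


def degrade(
    spec: SyntheticGelSpec,
    hours: float,
    rate_per_hour: float = 0.15,
    mu_shift_per_hour: float = 0.01,
) -> SyntheticGelSpec:
    """Emulate time-since-death degradation of every sample lane.

    The intact mass fraction decays exponentially (``w_intact * exp(-k*t)``)
    and the degraded smear centre drifts to smaller sizes; ``hours = 0``
    returns the spec unchanged.  The rate constants are purely synthetic.
    """
    if hours < 0:
        raise ParameterError("hours must be non-negative")
    if hours == 0:
        return spec
    factor = math.exp(-rate_per_hour * hours)
    samples = tuple(
        replace(
            m,
            w_intact=m.w_intact * factor,
            mu_degraded=m.mu_degraded - mu_shift_per_hour * hours,
        )
        for m in spec.samples
    )
    return replace(spec, samples=samples)


def sample_fragment_sizes(mixture: LaneMixture, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo oracle: draw ``n`` mass-weighted fragment sizes (bp)."""
    intact = rng.random(n) < mixture.w_intact
    x = np.where(
        intact,
        rng.normal(mixture.mu_intact, mixture.sigma_intact, n),
        rng.normal(mixture.mu_degraded, mixture.sigma_degraded, n),
    )
    return 10.0**x


def random_gel_spec(seed: int, n_samples: int = 4) -> SyntheticGelSpec:
    """A randomized study-condition gel: default geometry and noise, random mixtures."""
    rng = np.random.default_rng(seed)
    base = SyntheticGelSpec()
    spacing = (base.ladder_cols[-1] - base.ladder_cols[0]) / (n_samples + 1)
    sample_cols = tuple(base.ladder_cols[0] + spacing * (i + 1) for i in range(n_samples))
    samples = tuple(
        LaneMixture(
            w_intact=float(rng.uniform(0.0, 1.0)),
            mu_degraded=float(rng.uniform(3.3, 3.7)),
            sigma_degraded=float(rng.uniform(0.22, 0.38)),
        )
        for _ in range(n_samples)
    )
    return replace(base, sample_cols=sample_cols, samples=samples, seed=int(seed))


def default_lane_boxes(spec: SyntheticGelSpec, margin: int = 20) -> list[LaneBox]:
    """Shared-extent lane boxes matching the rendered lane layout."""
    row_top, row_bottom = margin, spec.rows - margin
    boxes = []
    for label, col in zip(spec.lane_labels, spec.lane_cols):
        boxes.append(
            LaneBox(
                center_col=col,
                width=spec.lane_width,
                row_top=row_top,
                row_bottom=row_bottom,
                role="ladder" if label.startswith("ladder") else "sample",
                label=label,
            )
        )
    return boxes
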