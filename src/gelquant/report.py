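"""GGBN-standard output records, tabular writers, and audit plots.

The two key terms follow the GGBN Gel Image Vocabulary verbatim:
``DNAThreshold`` (the ladder fragment size chosen as the standard) and
``percentAboveThreshold`` (percent of DNA at or above that size).  A record
with at least 50% above the 9,416 bp threshold may optionally be annotated
"genomic quality" — an annotation, never a filter.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .threshold import LaneQuantification, ScoredGel, ThresholdSpec

__all__ = [
    "GGBNRecord",
    "make_record",
    "records_from_scored_gel",
    "write_outputs",
    "read_records_json",
    "validate_record",
    "render_audit_plot",
    "GENOMIC_QUALITY_THRESHOLD_BP",
    "GENOMIC_QUALITY_MIN_PERCENT",
]

GENOMIC_QUALITY_THRESHOLD_BP = 9416
GENOMIC_QUALITY_MIN_PERCENT = 50.0

_CSV_COLUMNS = [
    "lane",
    "DNAThreshold",
    "areaAbove",
    "areaBelow",
    "percentAboveThreshold",
    "genomicQuality",
    "warnings",
]


def _version() -> str:
    from . import __version__

    return __version__


@dataclass(frozen=True)
class GGBNRecord:
    """One lane's quality record in GGBN Gel Image Vocabulary terms."""

    DNAThreshold: int
    percentAboveThreshold: float | None
    ladder: str
    image: str
    lane: str
    areaAbove: float
    areaBelow: float
    genomicQuality: bool | None
    method: dict
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pct = self.percentAboveThreshold
        if pct is not None and not 0.0 <= pct <= 100.0:
            raise ParameterError("percentAboveThreshold must lie in [0, 100] or be null")

    def to_dict(self) -> dict:
        return {
            "DNAThreshold": self.DNAThreshold,
            "percentAboveThreshold": self.percentAboveThreshold,
            "ladder": self.ladder,
            "image": self.image,
            "lane": self.lane,
            "areaAbove": self.areaAbove,
            "areaBelow": self.areaBelow,
            "genomicQuality": self.genomicQuality,
            "method": self.method,
            "warnings": list(self.warnings),
        }


def make_record(
    q: LaneQuantification, spec: ThresholdSpec, provenance: dict | None = None
) -> GGBNRecord:
    """Map a lane quantification onto a GGBN record.

    ``provenance`` may carry ``image`` (identifier) and method metadata (box
    geometry, background radius); software name/version are filled in.
    """
    provenance = dict(provenance or {})
    method = {
        "software": "gelquant",
        "softwareVersion": _version(),
        **provenance.get("method", {}),
    }
    pct = q.percent_above
    if pct is None:
        quality = None
    elif spec.band_size == GENOMIC_QUALITY_THRESHOLD_BP:
        quality = bool(pct >= GENOMIC_QUALITY_MIN_PERCENT)
    else:
        quality = None
    sig6 = lambda x: float(f"{x:.6g}")
    return GGBNRecord(
        DNAThreshold=spec.band_size,
        percentAboveThreshold=None if pct is None else round(pct, 1),
        ladder=spec.ladder_name,
        image=str(provenance.get("image", "")),
        lane=q.label,
        areaAbove=sig6(q.area_above),
        areaBelow=sig6(q.area_below),
        genomicQuality=quality,
        method=method,
        warnings=tuple(q.warnings),
    )


def records_from_scored_gel(scored: ScoredGel, image_id: str = "") -> list[GGBNRecord]:
    """Build one record per scored sample lane."""
    box = next(iter(scored.sample_profiles.values())).lane
    provenance = {
        "image": image_id or scored.gel.source,
        "method": {
            "boxWidth_px": box.width,
            "rowTop_px": box.row_top,
            "rowBottom_px": box.row_bottom,
            "backgroundRadius_px": scored.params.get("ball_radius_px"),
            "profileStatistic": scored.params.get("profile_statistic", "mean-across-width"),
        },
    }
    return [make_record(q, scored.threshold_spec, provenance) for q in scored.quantifications]


# ---------------------------------------------------------------------------
# schema validation (minimal, for the shipped record schema)

def _schema() -> dict:
    with resources.files("gelquant.data").joinpath("ggbn_record.schema.json").open() as fh:
        return json.load(fh)


def _check(instance, schema: dict, path: str, errors: list[str]) -> None:
    types = schema.get("type")
    if types is not None:
        types = [types] if isinstance(types, str) else types
        pytypes = {
            "object": dict,
            "array": list,
            "string": str,
            "integer": int,
            "number": (int, float),
            "boolean": bool,
            "null": type(None),
        }
        ok = any(
            isinstance(instance, pytypes[t])
            and not (t in ("integer", "number") and isinstance(instance, bool))
            for t in types
        )
        if not ok:
            errors.append(f"{path}: expected {types}, got {type(instance).__name__}")
            return
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            errors.append(f"{path}: {instance} < minimum {schema['minimum']}")
        if "maximum" in schema and instance > schema["maximum"]:
            errors.append(f"{path}: {instance} > maximum {schema['maximum']}")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}: missing required field {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_record(record: GGBNRecord | dict) -> list[str]:
    """Validate a record against the shipped schema; returns a list of problems."""
    obj = record.to_dict() if isinstance(record, GGBNRecord) else record
    errors: list[str] = []
    _check(obj, _schema(), "record", errors)
    return errors


# ---------------------------------------------------------------------------
# writers

def write_outputs(
    records: Sequence[GGBNRecord],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write records as CSV and/or JSON with deterministic field order.

    Percentages carry 1 decimal place; areas 6 significant digits; both
    formats carry identical numeric values.
    """
    if not records:
        raise ParameterError("no records to write")
    bad = [e for r in records for e in validate_record(r)]
    if bad:
        raise ParameterError("records failed schema validation: " + "; ".join(bad))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for r in records:
                d = r.to_dict()
                writer.writerow(
                    {
                        "lane": d["lane"],
                        "DNAThreshold": d["DNAThreshold"],
                        "areaAbove": f"{d['areaAbove']:.6g}",
                        "areaBelow": f"{d['areaBelow']:.6g}",
                        "percentAboveThreshold": (
                            "" if d["percentAboveThreshold"] is None
                            else f"{d['percentAboveThreshold']:.1f}"
                        ),
                        "genomicQuality": (
                            "" if d["genomicQuality"] is None else str(d["genomicQuality"]).lower()
                        ),
                        "warnings": "; ".join(d["warnings"]),
                    }
                )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in records], fh, indent=2)
            fh.write("\n")


def read_records_json(path: str | Path) -> list[GGBNRecord]:
    """Read back records written by :func:`write_outputs`."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        GGBNRecord(
            DNAThreshold=d["DNAThreshold"],
            percentAboveThreshold=d["percentAboveThreshold"],
            ladder=d["ladder"],
            image=d["image"],
            lane=d["lane"],
            areaAbove=d["areaAbove"],
            areaBelow=d["areaBelow"],
            genomicQuality=d["genomicQuality"],
            method=d["method"],
            warnings=tuple(d["warnings"]),
        )
        for d in data
    ]


# ---------------------------------------------------------------------------
# audit plot

def render_audit_plot(scored: ScoredGel, path: str | Path) -> dict | None:
    """Annotated audit figure: lane boxes on the gel plus stacked profiles.

    The stacked-profile panel shows the interpolated threshold line between
    the two ladder apexes, shades the above/below regions of each sample
    profile, and draws masked segments distinctly.  Returns the annotation
    coordinates used (for verification); plot failures only warn.
    """
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib import patches

        spec = scored.threshold_spec
        profiles = {**scored.ladder_profiles, **scored.sample_profiles}
        boxes = [p.lane for p in profiles.values()]
        fig, (ax_img, ax_prof) = plt.subplots(
            1, 2, figsize=(11, 6), gridspec_kw={"width_ratios": [1, 1.4]}
        )
        ax_img.imshow(scored.gel.data, cmap="gray_r", aspect="auto")
        for box in boxes:
            ax_img.add_patch(
                patches.Rectangle(
                    (box.col_start, box.row_top),
                    box.width,
                    box.height,
                    fill=False,
                    edgecolor="gold" if box.role == "sample" else "deepskyblue",
                    linewidth=1.2,
                )
            )
            ax_img.text(box.center_col, box.row_top - 4, box.label, ha="center", fontsize=7)
        ax_img.plot(
            [spec.left_lane_col, spec.right_lane_col],
            [spec.left_apex_row, spec.right_apex_row],
            "r--",
            linewidth=1.2,
        )
        ax_img.set_title(f"DNA threshold {spec.band_size} bp ({spec.ladder_name})")
        ax_img.set_xlabel("lateral (px)")
        ax_img.set_ylabel("migration (px)")

        ordered = sorted(profiles.values(), key=lambda p: p.lane.center_col)
        offset = 0.0
        step = 1.1 * max(float(p.values.max(initial=0.0)) for p in ordered)
        quant = {q.label: q for q in scored.quantifications}
        row_top = ordered[0].lane.row_top
        for prof in ordered:
            rows = np.arange(len(prof)) + row_top
            base = offset
            ax_prof.plot(rows, prof.values + base, "k-", linewidth=0.8)
            q = quant.get(prof.lane.label)
            if q is not None:
                t = q.threshold_row
                above = rows <= t
                ax_prof.fill_between(
                    rows[above], base, prof.values[above] + base, color="tab:green", alpha=0.3
                )
                ax_prof.fill_between(
                    rows[~above], base, prof.values[~above] + base, color="tab:orange", alpha=0.3
                )
                ax_prof.axvline(t, color="r", linestyle=":", linewidth=0.6)
            for start, end in prof.mask_segments:
                seg = slice(start, end + 1)
                ax_prof.plot(rows[seg], prof.values[seg] + base, "m-", linewidth=2.0)
            label = prof.lane.label
            pct = q.percent_above if q is not None else None
            if pct is not None:
                label += f"  ({pct:.1f}% > {spec.band_size} bp)"
            ax_prof.text(rows[0], base + 0.05 * step, label, fontsize=7)
            offset += step
        ax_prof.set_xlabel("migration (px)")
        ax_prof.set_ylabel("intensity (stacked)")
        ax_prof.set_title("lane intensity profiles")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return {
            "threshold_line": (
                (spec.left_lane_col, spec.left_apex_row),
                (spec.right_lane_col, spec.right_apex_row),
            )
        }
    except Exception as exc:  # plotting must never kill a scoring run
        warnings.warn(f"audit plot failed: {exc}", stacklevel=2)
        return None
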