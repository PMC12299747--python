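"""Batch pipeline: segment (or load masks) -> broken check -> measure -> grade.

The pipeline consumes a directory of frames — either a fixture directory
with a ``manifest.csv`` (which then supplies ground-truth grades and
enables accuracy reporting) or a plain directory of ``*.png`` images with
``*_mask.png`` label maps beside them — and emits a :class:`BatchReport`
with one row per frame.  Broken specimens bypass grading and are excluded
from the accuracy tally, mirroring the sorting line where they ride the
belt to the terminal box.

Per-frame failures are logged into the report and skipped; the run only
fails outright when every frame fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from .errors import ConfigError, SegGradeError
from .grading import Grade, GradeCriteria, GradeResult, assign_grade, detect_broken
from .mask import LabelMask, read_mask
from .metrics import GradeCounts, grading_accuracy
from .morphometry import measure_mushroom
from .segmentation import ReferenceSegmenter

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "image_id", "grade", "conflict", "reason",
    "D1_px", "H_px", "L_px", "D2_px", "tilt_deg", "RDHP", "RLDS",
    "true_grade", "warnings",
]

_KNOWN_KEYS = {
    "input", "output", "backend", "seed", "criteria",
    "min_fragment_fraction", "airblow", "include_background", "overlays",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated batch-run configuration."""

    input: Path
    output: Path
    backend: str = "file"            # file | reference
    seed: int = 0
    criteria: GradeCriteria = field(default_factory=GradeCriteria.default)
    min_fragment_fraction: float = 0.10
    include_background: bool = True
    overlays: bool = False

    def __post_init__(self) -> None:
        if self.backend not in ("file", "reference"):
            raise ConfigError(f"unknown backend {self.backend!r}")
        if not 0 < self.min_fragment_fraction < 1:
            raise ConfigError("min_fragment_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.pop("airblow", None)  # consumed by the trajectory CLI, not the batch run
        raw.update(overrides)
        if "criteria" in raw and raw["criteria"] is not None:
            raw["criteria"] = GradeCriteria.from_dict(raw["criteria"])
        for key in ("input", "output"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
            raw[key] = Path(raw[key])
        return cls(**raw)


@dataclass
class BatchReport:
    """Per-image grade rows plus batch-level aggregates."""

    rows: list[dict]
    grade_counts: GradeCounts | None = None
    accuracy_pct: float | None = None

    @property
    def n_processed(self) -> int:
        return len(self.rows)

    def summary(self) -> dict:
        graded = [r for r in self.rows if r["grade"] in (1, 2, 3)]
        return {
            "n_processed": self.n_processed,
            "n_graded": len(graded),
            "n_broken": sum(r["grade"] == "BROKEN" for r in self.rows),
            "n_failed": sum(r["grade"] == "ERROR" for r in self.rows),
            "accuracy_pct": self.accuracy_pct,
        }


def _discover_items(input_dir: Path) -> list[dict]:
    """Frame list from a manifest if present, else by filename pairing."""
    manifest_path = input_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        return [
            {
                "image_id": Path(row["image"]).stem,
                "image": input_dir / row["image"],
                "mask": input_dir / row["mask"],
                "true_grade": row.get("true_grade"),
            }
            for _, row in manifest.iterrows()
        ]
    items = []
    for image in sorted(input_dir.glob("*.png")):
        if image.stem.endswith("_mask"):
            continue
        mask = image.with_name(image.stem + "_mask.png")
        items.append({
            "image_id": image.stem,
            "image": image,
            "mask": mask if mask.exists() else None,
            "true_grade": None,
        })
    return items


def _grade_one(mask: LabelMask, config: PipelineConfig) -> tuple[GradeResult, dict]:
    broken, reason = detect_broken(mask, config.min_fragment_fraction)
    if broken:
        result = GradeResult(
            grade=Grade.BROKEN, rdhp_grade=None, rlds_grade=None,
            conflict=False, measurement=None, reason=reason,
        )
        return result, {"warnings": ""}
    outcome = measure_mushroom(mask)
    result = assign_grade(outcome.measurement, config.criteria)
    extra = {
        "warnings": "; ".join(outcome.warnings),
        "tilt_deg": outcome.tilt_deg,
        "cap_rect": outcome.cap_rect,
    }
    return result, extra


def run_pipeline(config: PipelineConfig) -> BatchReport:
    """Grade every frame under ``config.input``."""
    items = _discover_items(config.input)
    if not items:
        raise ConfigError(f"no input frames found under {config.input}")
    segmenter = ReferenceSegmenter() if config.backend == "reference" else None

    rows: list[dict] = []
    n_failed = 0
    for item in items:
        row: dict = {c: "" for c in REPORT_COLUMNS}
        row["image_id"] = item["image_id"]
        row["true_grade"] = item["true_grade"] if item["true_grade"] is not None else ""
        try:
            if segmenter is not None:
                with Image.open(item["image"]) as im:
                    mask = segmenter.segment(np.asarray(im.convert("RGB")))
            else:
                if item["mask"] is None:
                    raise ConfigError(f"no mask file for {item['image_id']}")
                mask = read_mask(item["mask"])
            result, extra = _grade_one(mask, config)
        except SegGradeError as exc:
            logger.warning("frame %s failed: %s", item["image_id"], exc)
            row.update(grade="ERROR", reason=str(exc))
            rows.append(row)
            n_failed += 1
            continue
        row.update(
            grade=result.grade.value,
            conflict=result.conflict,
            reason=result.reason,
            warnings=extra.get("warnings", ""),
        )
        if result.measurement is not None:
            m = result.measurement
            row.update(
                D1_px=m.cap.D1, H_px=m.cap.H, L_px=m.stalk.L, D2_px=m.stalk.D2,
                tilt_deg=extra.get("tilt_deg", ""), RDHP=m.RDHP, RLDS=m.RLDS,
            )
            row["_cap_rect"] = extra.get("cap_rect")
            row["_image"] = item["image"]
        rows.append(row)

    if n_failed == len(items):
        raise SegGradeError("all frames failed")

    report = BatchReport(rows=rows)
    _tally_accuracy(report)
    return report


def _tally_accuracy(report: BatchReport) -> None:
    """Fill grade_counts and accuracy when ground-truth grades are present."""
    truthy = [
        r for r in report.rows
        if str(r.get("true_grade", "")) in ("1", "2", "3") and r["grade"] != "ERROR"
    ]
    if not truthy:
        return
    totals = [0, 0, 0]
    correct = [0, 0, 0]
    for r in truthy:
        t = int(r["true_grade"])
        totals[t - 1] += 1
        if r["grade"] == t:
            correct[t - 1] += 1
    if all(totals):
        counts = GradeCounts(totals=tuple(totals), correct=tuple(correct))
        report.grade_counts = counts
        report.accuracy_pct = grading_accuracy(counts)


def write_report(report: BatchReport, out_dir: str | Path, overlays: bool = False) -> dict[str, Path]:
    """Write the report as CSV + JSON (and optional overlay PNGs).

    Returns the paths written.  Output is deterministic: identical
    reports produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [{k: v for k, v in r.items() if not k.startswith("_")} for r in report.rows],
        columns=REPORT_COLUMNS,
    )
    csv_path = out / "report.csv"
    frame.to_csv(csv_path, index=False)

    json_path = out / "report.json"
    payload = {
        "summary": report.summary(),
        "rows": frame.to_dict(orient="records"),
    }
    if report.grade_counts is not None:
        payload["grade_counts"] = {
            "totals": list(report.grade_counts.totals),
            "correct": list(report.grade_counts.correct),
        }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))

    paths = {"csv": csv_path, "json": json_path}
    if overlays:
        overlay_dir = out / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for r in report.rows:
            rect, image_path = r.get("_cap_rect"), r.get("_image")
            if rect is None or image_path is None or not Path(image_path).exists():
                continue
            with Image.open(image_path) as im:
                canvas = im.convert("RGB")
            draw = ImageDraw.Draw(canvas)
            draw.polygon([tuple(p) for p in rect.corners()], outline=(255, 255, 0))
            draw.text((2, 2), f"grade {r['grade']}", fill=(255, 255, 0))
            canvas.save(overlay_dir / f"{r['image_id']}_overlay.png")
        paths["overlays"] = overlay_dir
    return paths


def load_report(json_path: str | Path) -> BatchReport:
    """Reload a report written by :func:`write_report`."""
    payload = json.loads(Path(json_path).read_text())
    rows = payload["rows"]
    for r in rows:  # grade column round-trips through JSON as str or int
        if isinstance(r["grade"], str) and r["grade"].isdigit():
            r["grade"] = int(r["grade"])
    report = BatchReport(rows=rows)
    gc = payload.get("grade_counts")
    if gc is not None:
        report.grade_counts = GradeCounts(totals=tuple(gc["totals"]), correct=tuple(gc["correct"]))
        report.accuracy_pct = payload["summary"].get("accuracy_pct")
    return report
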