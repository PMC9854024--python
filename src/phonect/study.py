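"""End-to-end in-silico replica of the capture study.

The design: 8 index phantoms spanning the severity menu, each recorded
``n_captures_per_scan`` times (10 in the original design, for 80 capture
records) with devices assigned by cycling through the ladder.  Each capture
runs the full pipeline — simulate the recording, extract frames, collapse
dwell runs, re-derive the spatial scale from the scalebar, measure — and is
compared against the PACS reference measured directly on the pristine
stack.  Every lesion × capture cell is re-derivable in isolation from the
seeds recorded in the measurement table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import agreement, capture, frames, metrics, phantom

logger = logging.getLogger("phonect.study")


class StudyError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cell."""


#: a-priori critical differences for the quantitative measures that get a
#: Bland-Altman analysis (see docs/methods.md); Marshall and CNR are
#: compared by ICC/Friedman only
DEFAULT_CRITICAL_DIFFERENCES = {
    "volume_cc": 5.0,
    "sdh_width_mm": 2.0,
    "midline_shift_mm": 2.0,
}


@dataclass
class StudyConfig:
    """Reproducible description of one study run."""

    menu: str = "default"
    n_captures_per_scan: int = 10
    seed: int = 0
    geometry: phantom.StackGeometry = field(
        default_factory=lambda: phantom.STUDY_GEOMETRY
    )
    phantom_noise_sd: float = 6.0
    devices: list[capture.DeviceProfile] = field(
        default_factory=capture.default_device_ladder
    )
    critical_differences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CRITICAL_DIFFERENCES)
    )
    keep_frames: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_captures_per_scan < 1:
            raise StudyError("n_captures_per_scan must be >= 1")
        if not self.devices:
            raise StudyError("device ladder must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        geometry = payload.pop("geometry", None)
        devices = payload.pop("devices", None)
        config = cls(**payload)
        if geometry is not None:
            config.geometry = phantom.StackGeometry(**geometry)
        if devices is not None:
            config.devices = [capture.DeviceProfile(**d) for d in devices]
        return config

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class StudyResult:
    measurements: pd.DataFrame  # one row per lesion × method (PACS + captures)
    reports: dict[str, agreement.AgreementReport]
    summary: pd.DataFrame  # Table-1-shaped median (IQR) per lesion and measure
    truths: dict[str, phantom.GroundTruth]
    n_capture_records: int


def _entry_kind(entry: phantom.MenuEntry) -> str:
    kinds = {l.kind for l in entry.lesions}
    if len(entry.lesions) > 1:
        return "multi-compartment"
    return next(iter(kinds))


def _measure_cell(
    stack: phantom.SliceStack,
    lesion_masks: list[np.ndarray],
    entry: phantom.MenuEntry,
    truth: phantom.GroundTruth,
    device_name: str,
) -> metrics.MeasurementRecord:
    """Measure one lesion on one (pristine or captured) calibrated stack.

    The ABC/2 volume is summed over compartments, as the bedside rule is
    applied per bleeding site.  For subdural crescents B is the maximal
    thickness (the standard adaptation of the rule to crescents, whose
    longest perpendicular chord would trace the arc rather than the
    collection's width).
    """
    shape = stack.pixels.shape[1:]
    projected = [metrics.project_mask(m, shape) for m in lesion_masks]
    union = np.zeros(stack.pixels.shape, dtype=bool)
    for m in projected:
        union |= m
    brain = _brain_mask(stack)
    union_roi = metrics.roi_from_masks(union, brain)

    volume = 0.0
    width: float | None = None
    for m, lesion in zip(projected, entry.lesions):
        roi = metrics.roi_from_masks(m, brain)
        a_mm, b_mm, c_mm = metrics.measure_abc(stack, roi)
        if lesion.kind == "subdural":
            w, _ = metrics.sdh_max_thickness(stack, roi)
            volume += metrics.abc2_volume(a_mm, w, c_mm)
            width = w if width is None else max(width, w)
        else:
            volume += metrics.abc2_volume(a_mm, b_mm, c_mm)

    shift = metrics.midline_shift(stack)
    score = metrics.marshall_score(
        mass_cc=volume,
        shift_mm=shift,
        cisterns_effaced=truth.cisterns_effaced,
        evacuated=truth.evacuated,
        visible_pathology=True,
    )
    kind = _entry_kind(entry)
    severity = metrics.severity_class(kind, width_mm=width, total_volume_cc=volume)
    return metrics.MeasurementRecord(
        lesion_id=entry.name,
        device_name=device_name,
        volume_cc=volume,
        sdh_width_mm=width,
        midline_shift_mm=shift,
        marshall=score,
        cnr=metrics.cnr(stack, union_roi),
        severity=severity,
    )


def _brain_mask(stack: phantom.SliceStack) -> np.ndarray:
    """Brain interior from the image itself (filled skull rim minus rim)."""
    from scipy import ndimage

    thresh = (phantom.BRAIN_INTENSITY + phantom.SKULL_INTENSITY) / 2.0
    brain = np.zeros(stack.pixels.shape, dtype=bool)
    for k, slice_px in enumerate(stack.pixels):
        rim = slice_px >= thresh
        labels, n = ndimage.label(rim)
        if n >= 1:
            sizes = ndimage.sum_labels(rim, labels, index=np.arange(1, n + 1))
            rim = labels == (1 + int(np.argmax(sizes)))
        interior = ndimage.binary_fill_holes(rim) & ~rim
        # exclude the dark midline structure so it cannot enter a surround
        # annulus and masquerade as image noise
        brain[k] = interior & (slice_px > (phantom.MIDLINE_INTENSITY + phantom.BRAIN_INTENSITY) / 2.0)
    return brain


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full design and return measurements, agreement reports and a
    Table-1-shaped summary.  Fully reproducible from (config, seed)."""
    menu = phantom.default_lesion_menu()
    scalebar = phantom.ScalebarSpec()
    root_ss = np.random.SeedSequence(config.seed)
    # one independent child per (lesion, capture slot) plus one per phantom
    phantom_seeds = root_ss.spawn(len(menu))

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    truths: dict[str, phantom.GroundTruth] = {}
    n_capture_records = 0

    for li, entry in enumerate(menu):
        stage = f"phantom:{entry.name}"
        try:
            stack, truth = phantom.generate_phantom(
                lesions=entry.lesions,
                geometry=config.geometry,
                shift_mm=entry.shift_mm,
                noise_sd=config.phantom_noise_sd,
                scalebar=scalebar,
                seed=int(phantom_seeds[li].generate_state(1)[0] % 2**31),
            )
        except Exception as exc:
            raise StudyError(f"[{stage}] {exc}") from exc
        truths[entry.name] = truth
        lesion_masks = [
            phantom.rasterize_lesion(l, config.geometry) for l in entry.lesions
        ]
        logger.info("%s: generated (%s)", stage, truth.severity_label)
        if out_dir:
            phantom.write_phantom(stack, truth, out_dir / entry.name)

        # PACS reference: measure the pristine stack, but still through the
        # scalebar so calibration error is shared with the devices
        try:
            cal = frames.calibrate_scale(stack.pixels[0], scalebar)
            pacs_stack = frames.calibrated_stack(
                phantom.SliceStack(
                    geometry=dataclasses.replace(stack.geometry, mm_per_px=None),
                    pixels=stack.pixels,
                ),
                cal,
            )
            record = _measure_cell(pacs_stack, lesion_masks, entry, truth, "PACS")
        except Exception as exc:
            raise StudyError(f"[measure:{entry.name}:PACS] {exc}") from exc
        rows.append(_row(record, capture_index=-1, seed=-1))

        capture_seeds = phantom_seeds[li].spawn(config.n_captures_per_scan)
        for ci in range(config.n_captures_per_scan):
            device = config.devices[ci % len(config.devices)]
            seed = int(capture_seeds[ci].generate_state(1)[0] % 2**31)
            stage = f"capture:{entry.name}:{device.name}:{ci}"
            try:
                result = capture.simulate_capture(
                    stack, device, seed=seed, phantom_id=entry.name
                )
                if config.keep_frames and out_dir:
                    capture.write_video(
                        result, out_dir / f"{entry.name}_cap{ci}", "frames-dir"
                    )
                frame_arr, _ = frames.extract_frames(result, fps=device.fps)
                rec_stack = frames.deduplicate_slices(
                    frame_arr,
                    slice_thickness_mm=config.geometry.slice_thickness_mm,
                )
                cal = frames.calibrate_scale(rec_stack.pixels[0], scalebar)
                rec_stack = frames.calibrated_stack(rec_stack, cal)
                record = _measure_cell(
                    rec_stack, lesion_masks, entry, truth, device.name
                )
            except Exception as exc:
                raise StudyError(f"[{stage}] {exc}") from exc
            rows.append(_row(record, capture_index=ci, seed=seed))
            n_capture_records += 1
            logger.info("%s: measured", stage)

    measurements = pd.DataFrame(rows)
    reports = _agreement_reports(measurements, config)
    summary = _summary_table(measurements)

    if out_dir:
        measurements.to_csv(out_dir / "measurements.csv", index=False)
        agreement.write_report(list(reports.values()), out_dir / "agreement.json")
        summary.to_csv(out_dir / "summary.csv")
        (out_dir / "config.json").write_text(
            json.dumps(
                {
                    "menu": config.menu,
                    "n_captures_per_scan": config.n_captures_per_scan,
                    "seed": config.seed,
                    "geometry": dataclasses.asdict(config.geometry),
                    "devices": [d.name for d in config.devices],
                },
                indent=2,
            )
        )

    return StudyResult(
        measurements=measurements,
        reports=reports,
        summary=summary,
        truths=truths,
        n_capture_records=n_capture_records,
    )


def _row(record: metrics.MeasurementRecord, capture_index: int, seed: int) -> dict:
    return {
        "lesion_id": record.lesion_id,
        "method": record.device_name if capture_index < 0 else f"cap{capture_index}",
        "device_name": record.device_name,
        "capture_index": capture_index,
        "seed": seed,
        "volume_cc": record.volume_cc,
        "sdh_width_mm": record.sdh_width_mm,
        "midline_shift_mm": record.midline_shift_mm,
        "marshall": record.marshall,
        "cnr": record.cnr,
        "severity": record.severity,
    }


_CONTINUOUS_MEASURES = ["volume_cc", "sdh_width_mm", "midline_shift_mm", "marshall", "cnr"]


def rating_tables(measurements: pd.DataFrame) -> dict[str, agreement.RatingTable]:
    """Pivot the measurement table into subjects × methods matrices.

    Methods are PACS plus the capture slots.  The SDH-width table keeps
    only lesions where the width is defined (pure or mixed subdural)."""
    tables = {}
    for measure in _CONTINUOUS_MEASURES:
        pivot = measurements.pivot_table(
            index="lesion_id", columns="method", values=measure, aggfunc="first"
        )
        pivot = pivot.dropna(axis=0, how="any")
        if pivot.shape[0] < 2:
            continue
        columns = ["PACS"] + sorted(
            (c for c in pivot.columns if c != "PACS"),
            key=lambda c: int(c.removeprefix("cap")),
        )
        pivot = pivot[columns]
        tables[measure] = agreement.RatingTable(
            values=pivot.to_numpy(dtype=float),
            measure_name=measure,
            method_names=list(pivot.columns),
            subject_ids=list(pivot.index),
        )
    return tables


def _agreement_reports(
    measurements: pd.DataFrame, config: StudyConfig
) -> dict[str, agreement.AgreementReport]:
    reports = {}
    for measure, table in rating_tables(measurements).items():
        cd = config.critical_differences.get(measure)
        try:
            reports[measure] = agreement.analyze_table(
                table, critical_difference=cd, reference_method="PACS"
            )
        except agreement.AgreementError as exc:
            logger.warning("agreement for %s skipped: %s", measure, exc)
    return reports


def _summary_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) across methods per lesion, one row per lesion."""
    devices_only = measurements[measurements["capture_index"] >= 0]
    out = {}
    for measure in _CONTINUOUS_MEASURES:
        grouped = devices_only.groupby("lesion_id")[measure]
        out[measure] = grouped.median().round(3).astype(str) + (
            " ("
            + grouped.quantile(0.25).round(3).astype(str)
            + ", "
            + grouped.quantile(0.75).round(3).astype(str)
            + ")"
        )
    return pd.DataFrame(out)
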