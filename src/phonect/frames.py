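"""Turn a screen recording back into a calibrated slice stack.

Three steps: extract frames at a fixed rate (30 fps by default, matching
the conversion rate used for the real videos), collapse the dwell runs —
the consecutive near-identical frames produced while one slice was on
screen — into one representative slice each, and recover the spatial scale
from the burned-in scalebar.  The recovered mm/pixel is what every
downstream measurement uses; the generator's true scale is never consulted,
so calibration errors propagate realistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .capture import FRAMES_DIR_MANIFEST, CaptureResult
from .phantom import ScalebarSpec, SliceStack, StackGeometry


class FrameError(ValueError):
    """Raised for unreadable sources or failed calibration."""


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_frames(
    source: CaptureResult | str | Path,
    fps: int = 30,
    out_tiff: str | Path | None = None,
) -> tuple[np.ndarray, int]:
    """Read frames in temporal order, resampled to ``fps`` frames/second.

    ``source`` may be an in-memory :class:`CaptureResult`, a frames
    directory written by :func:`phonect.capture.write_video`, or a video
    file decodable by imageio.  Resampling picks, for each output
    timestamp, the source frame whose timestamp is nearest (timestamps, not
    indices, drive the contract, so variable-rate containers still work).
    Returns ``(frames, fps)``; optionally writes a multi-page TIFF.
    """
    if isinstance(source, CaptureResult):
        frames, src_fps, duration = source.frames, source.fps, source.duration_s
    else:
        source = Path(source)
        if source.is_dir():
            frames, src_fps, duration = _read_frames_dir(source)
        elif source.exists():
            frames, src_fps, duration = _read_video(source)
        else:
            raise FrameError(f"source {source} does not exist")

    if frames.shape[0] == 0:
        raise FrameError("source contains no frames")

    if fps != src_fps:
        n_out = int(round(duration * fps))
        if n_out < 1:
            raise FrameError("requested fps yields zero frames")
        t_out = (np.arange(n_out) + 0.5) / fps
        t_src = (np.arange(frames.shape[0]) + 0.5) / src_fps
        idx = np.clip(np.searchsorted(t_src, t_out), 0, frames.shape[0] - 1)
        # nearest-timestamp pick
        left = np.clip(idx - 1, 0, frames.shape[0] - 1)
        use_left = np.abs(t_src[left] - t_out) < np.abs(t_src[idx] - t_out)
        idx = np.where(use_left, left, idx)
        frames = frames[idx]

    if out_tiff is not None:
        tifffile.imwrite(Path(out_tiff), frames)
    return frames, fps


def _read_frames_dir(path: Path) -> tuple[np.ndarray, int, float]:
    manifest_path = path / FRAMES_DIR_MANIFEST
    frame_files = sorted(path.glob("frame_*.tif")) + sorted(path.glob("frame_*.png"))
    if not frame_files:
        raise FrameError(f"no frames found in {path}")
    frames = np.stack([_read_frame(p) for p in frame_files])
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        fps = int(manifest["fps"])
        duration = float(manifest["duration_s"])
    else:
        fps = 30
        duration = frames.shape[0] / fps
    return frames, fps, duration


def _read_frame(path: Path) -> np.ndarray:
    if path.suffix == ".tif":
        return tifffile.imread(path).astype(np.float32)
    import imageio.v2 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float32)


def _read_video(path: Path) -> tuple[np.ndarray, int, float]:
    import imageio.v2 as iio

    try:
        reader = iio.get_reader(str(path))
    except Exception as exc:
        raise FrameError(f"cannot decode {path}: {exc}") from exc
    with reader:
        meta = reader.get_meta_data()
        frames = []
        for frame in reader:
            if frame.ndim == 3:
                frame = frame[..., :3].mean(axis=-1)
            frames.append(frame.astype(np.float32))
    if not frames:
        raise FrameError(f"{path} contains no frames")
    arr = np.stack(frames)
    fps = int(round(meta.get("fps", 30)))
    duration = float(meta.get("duration", arr.shape[0] / fps))
    return arr, fps, duration


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate_slices(
    frames: np.ndarray,
    diff_threshold: float | None = None,
    slice_thickness_mm: float = 5.0,
) -> SliceStack:
    """Collapse dwell runs into one representative slice each.

    Consecutive frames whose mean absolute intensity difference is at or
    below ``diff_threshold`` are treated as the same on-screen slice; each
    run is replaced by its pixelwise median (which also suppresses sensor
    noise).  With ``diff_threshold=None`` the threshold is derived from the
    data: consecutive-difference values form two clusters (within-slice
    sensor noise — tight — vs. between-slice content change — higher and
    spread out) and the threshold is placed a robust margin above the
    median difference.  This assumes each slice is on screen for at least
    two frames (true of any screen recording slower than the frame rate),
    so within-run differences are the majority.

    The returned stack's ``mm_per_px`` is ``None`` until calibration.
    """
    if frames.shape[0] < 1:
        raise FrameError("need at least one frame")
    n = frames.shape[0]
    if n == 1:
        reps = frames[:1].astype(np.float32)
    else:
        diffs = np.array(
            [float(np.mean(np.abs(frames[i + 1] - frames[i]))) for i in range(n - 1)]
        )
        if diff_threshold is None:
            diff_threshold = _two_means_threshold(diffs)
        boundaries = np.where(diffs > diff_threshold)[0]
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [n]))
        reps = np.stack(
            [
                np.median(frames[s:e], axis=0).astype(np.float32)
                for s, e in zip(starts, ends)
            ]
        )
    geometry = StackGeometry(
        n_slices=reps.shape[0],
        rows=reps.shape[1],
        cols=reps.shape[2],
        mm_per_px=None,
        slice_thickness_mm=slice_thickness_mm,
    )
    return SliceStack(geometry=geometry, pixels=reps)


def _two_means_threshold(diffs: np.ndarray) -> float:
    """Adaptive dedup threshold: a robust margin above the median difference.

    With at least two frames per dwell run, within-run differences are the
    majority of the sequence, so their level is the median and their
    spread the MAD.  The threshold sits six robust SDs — but no less than
    25% — above the median, which clears the within-run cluster while
    staying below between-slice content changes.  All-zero differences
    (identical frames throughout) yield threshold 0, merging everything.
    """
    med = float(np.median(diffs))
    mad = float(np.median(np.abs(diffs - med)))
    return med + max(6 * 1.4826 * mad, 0.25 * med)


# ---------------------------------------------------------------------------
# scalebar calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Calibration:
    """Recovered spatial scale: mm_per_px = length_mm / scalebar_length_px."""

    mm_per_px: float
    scalebar_length_px: float
    confidence: float

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0 or self.scalebar_length_px <= 0:
            raise FrameError("calibration lengths must be positive")
        if not 0 <= self.confidence <= 1:
            raise FrameError("confidence must be in [0, 1]")


def calibrate_scale(
    frame: np.ndarray,
    scalebar: ScalebarSpec = ScalebarSpec(),
    strip_px: int = 12,
) -> Calibration:
    """Measure the burned-in scalebar and return the recovered mm/pixel.

    The bar is the outermost bright structure on its edge of the frame —
    it sits in the margin, outside the skull — so the search first finds
    the last bright row scanning inward from that edge, then profiles a
    thin ``strip_px``-tall band around it, restricted to the stated
    corner's half of the columns.  The length is measured between the
    half-maximum crossings of the per-column maximum profile, which is
    robust to blur and affine luminance changes.  Raises
    :class:`FrameError` (never a silent default) when no bar-like
    structure is found.
    """
    rows, cols = frame.shape
    vert, horiz = scalebar.position.split("-")
    c0 = cols // 2 if horiz == "right" else 0
    half_frame = frame[:, c0 : c0 + (cols - cols // 2)].astype(np.float64)

    background = float(np.median(half_frame))
    peak_all = float(half_frame.max())
    if peak_all - background < 20.0:
        raise FrameError(
            "scalebar not found: no high-intensity structure in the "
            f"{scalebar.position} corner (peak-background contrast "
            f"{peak_all - background:.1f})"
        )
    bright = half_frame >= (peak_all + background) / 2.0
    has_bright = bright.any(axis=1)
    bright_rows = np.where(has_bright)[0]
    edge_row = bright_rows[-1] if vert == "lower" else bright_rows[0]
    # strip = the contiguous block of bright rows at the frame edge (bar +
    # ticks); the margin gap separates it from the skull, at any resample
    r0 = r1 = edge_row
    while r0 > 0 and has_bright[r0 - 1] and edge_row - r0 < strip_px:
        r0 -= 1
    while r1 < rows - 1 and has_bright[r1 + 1] and r1 - edge_row < strip_px:
        r1 += 1
    region = half_frame[r0 : r1 + 1]

    profile = region.max(axis=0)  # per-column maximum: bar is horizontal
    peak = float(profile.max())
    half = (peak + background) / 2.0
    above = profile >= half
    # longest contiguous run of above-half columns = the bar
    runs = _runs(above)
    if not runs:
        raise FrameError("scalebar not found: no contiguous bright run")
    start, end = max(runs, key=lambda r: r[1] - r[0])
    # sub-pixel edges by linear interpolation of the half-crossing
    left = _half_crossing(profile, start, half, side="left")
    right = _half_crossing(profile, end - 1, half, side="right")
    length_px = right - left
    if length_px < 4:
        raise FrameError("scalebar not found: candidate run too short")

    # confidence: contrast quality x dominance of the main run
    contrast = min(1.0, (peak - background) / 100.0)
    dominance = (end - start) / max(1, int(above.sum()))
    confidence = float(np.clip(contrast * dominance, 0.0, 1.0))
    return Calibration(
        mm_per_px=scalebar.length_mm / length_px,
        scalebar_length_px=float(length_px),
        confidence=confidence,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, mask.size))
    return runs


def _half_crossing(profile: np.ndarray, idx: int, half: float, side: str) -> float:
    """Sub-pixel column where the profile crosses ``half`` next to pixel ``idx``.

    ``idx`` is the first (side='left') or last (side='right') above-half
    pixel of the run; the crossing is linearly interpolated against the
    adjacent below-half neighbour.
    """
    j = idx - 1 if side == "left" else idx + 1
    if j < 0 or j >= profile.size or profile[j] >= half:
        return float(idx - 0.5 if side == "left" else idx + 0.5)
    if side == "left":
        rise = profile[idx] - profile[j]
        frac = (half - profile[j]) / rise if rise > 0 else 0.5
        return float(j + frac)
    fall = profile[idx] - profile[j]
    frac = (profile[idx] - half) / fall if fall > 0 else 0.5
    return float(idx + frac)


def calibrated_stack(stack: SliceStack, calibration: Calibration) -> SliceStack:
    """Attach a recovered mm/pixel to an uncalibrated stack."""
    return SliceStack(
        geometry=stack.geometry.with_scale(calibration.mm_per_px),
        pixels=stack.pixels,
    )
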