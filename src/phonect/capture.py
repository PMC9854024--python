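"""Simulated smartphone video capture of a PACS screen scroll-through.

A capture renders each slice of a stack for ``dwell_s`` seconds at ``fps``
frames per second.  Every frame passes through the device's degradation
chain, in order:

    spatial resample (capture_scale) -> Gaussian blur (blur_sigma_px)
    -> affine luminance (gain, offset; clipped to [0, 255])
    -> intensity quantization (quantization_step)
    -> additive sensor noise (sensor_noise_sd)

Compression artifacts are emulated by quantization + blur rather than a
real codec, keeping the measurement claims codec-independent; actual mp4
encoding is an optional I/O layer.  Per-frame sensor noise varies; the
luminance jitter of one capture (a small multiplicative perturbation of the
gain) is drawn once per capture from the seed, emulating auto-exposure
settling differently on each recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import transform

from .phantom import I_MAX, SliceStack


class CaptureError(ValueError):
    """Raised for degenerate device profiles or unwritable containers."""


@dataclass(frozen=True)
class DeviceProfile:
    """Parameters of one simulated smartphone capture chain."""

    name: str
    capture_scale: float = 1.0
    blur_sigma_px: float = 0.0
    quantization_step: int = 1
    luminance_gain: float = 1.0
    luminance_offset: float = 0.0
    sensor_noise_sd: float = 0.0
    gain_jitter_sd: float = 0.0
    dwell_s: float = 0.5
    fps: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.capture_scale <= 2:
            raise CaptureError("capture_scale must be in (0, 2]")
        if self.blur_sigma_px < 0 or self.sensor_noise_sd < 0:
            raise CaptureError("blur and noise SDs must be >= 0")
        if self.quantization_step < 1:
            raise CaptureError("quantization_step must be a positive integer")
        if self.luminance_gain <= 0:
            raise CaptureError("luminance_gain must be > 0")
        if self.fps < 1 or self.dwell_s <= 0:
            raise CaptureError("fps >= 1 and dwell_s > 0 required")
        if self.dwell_s * self.fps < 1:
            raise CaptureError(
                "degenerate profile: dwell_s * fps < 1 would drop slices"
            )

    @property
    def is_identity(self) -> bool:
        return (
            self.capture_scale == 1.0
            and self.blur_sigma_px == 0.0
            and self.quantization_step == 1
            and self.luminance_gain == 1.0
            and self.luminance_offset == 0.0
            and self.sensor_noise_sd == 0.0
            and self.gain_jitter_sd == 0.0
        )


IDENTITY_PROFILE = DeviceProfile(name="pacs-identity")


def default_device_ladder() -> list[DeviceProfile]:
    """PACS-identity reference plus five progressively degraded phone profiles.

    The ladder mirrors a single user recording with five different phones;
    the optical parameters are assumptions (phone optics were never
    characterized), ordered from a nearly transparent flagship capture to a
    soft, noisy budget-device capture.
    """
    return [
        IDENTITY_PROFILE,
        DeviceProfile(
            name="phone-a",
            capture_scale=1.25,
            blur_sigma_px=0.6,
            quantization_step=2,
            luminance_gain=1.04,
            luminance_offset=2.0,
            sensor_noise_sd=0.5,
            gain_jitter_sd=0.01,
        ),
        DeviceProfile(
            name="phone-b",
            capture_scale=1.1,
            blur_sigma_px=0.8,
            quantization_step=2,
            luminance_gain=0.97,
            luminance_offset=-2.0,
            sensor_noise_sd=0.6,
            gain_jitter_sd=0.01,
        ),
        DeviceProfile(
            name="phone-c",
            capture_scale=1.0,
            blur_sigma_px=1.0,
            quantization_step=4,
            luminance_gain=1.06,
            luminance_offset=4.0,
            sensor_noise_sd=0.7,
            gain_jitter_sd=0.015,
        ),
        DeviceProfile(
            name="phone-d",
            capture_scale=0.85,
            blur_sigma_px=1.0,
            quantization_step=4,
            luminance_gain=0.94,
            luminance_offset=-3.0,
            sensor_noise_sd=0.7,
            gain_jitter_sd=0.015,
        ),
        DeviceProfile(
            name="phone-e",
            capture_scale=0.9,
            blur_sigma_px=1.1,
            quantization_step=6,
            luminance_gain=1.08,
            luminance_offset=5.0,
            sensor_noise_sd=0.8,
            gain_jitter_sd=0.02,
        ),
    ]


@dataclass
class CaptureResult:
    """Frames of one simulated recording plus provenance."""

    frames: np.ndarray  # (n_frames, rows, cols) float32 in [0, I_MAX]
    fps: int
    provenance: tuple[str, str, int]  # (phantom id, device name, seed)
    duration_s: float

    def __post_init__(self) -> None:
        if self.frames.shape[0] != round(self.duration_s * self.fps):
            raise CaptureError("frame count inconsistent with duration * fps")


def degrade_frame(
    frame: np.ndarray, device: DeviceProfile, gain: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply the device chain to one frame.  Identity parameters are no-ops."""
    out = frame.astype(np.float64, copy=True)
    if device.capture_scale != 1.0:
        out = transform.rescale(
            out,
            device.capture_scale,
            order=1,
            anti_aliasing=device.capture_scale < 1.0,
            preserve_range=True,
        )
    if device.blur_sigma_px > 0:
        out = ndimage.gaussian_filter(out, device.blur_sigma_px)
    if gain != 1.0 or device.luminance_offset != 0.0:
        out = np.clip(gain * out + device.luminance_offset, 0.0, I_MAX)
    if device.quantization_step > 1:
        step = device.quantization_step
        out = np.round(out / step) * step
    if device.sensor_noise_sd > 0:
        out = out + rng.normal(0.0, device.sensor_noise_sd, size=out.shape)
    return np.clip(out, 0.0, I_MAX).astype(np.float32)


def simulate_capture(
    stack: SliceStack,
    device: DeviceProfile,
    seed: int = 0,
    phantom_id: str = "phantom",
) -> CaptureResult:
    """Record a scroll-through of ``stack`` with one device.

    Deterministic for fixed (stack, device, seed).  The per-capture
    luminance jitter is drawn once; per-frame sensor noise is fresh for
    every frame.
    """
    if stack.pixels.shape[0] == 0:
        raise CaptureError("empty stack")
    rng = np.random.default_rng(seed)
    gain = device.luminance_gain
    if device.gain_jitter_sd > 0:
        gain *= float(np.exp(rng.normal(0.0, device.gain_jitter_sd)))

    frames_per_slice = int(round(device.dwell_s * device.fps))
    frames = []
    for slice_px in stack.pixels:
        for _ in range(frames_per_slice):
            frames.append(degrade_frame(slice_px, device, gain, rng))
    frames = np.stack(frames)
    n_slices = stack.pixels.shape[0]
    duration_s = n_slices * device.dwell_s
    return CaptureResult(
        frames=frames,
        fps=device.fps,
        provenance=(phantom_id, device.name, seed),
        duration_s=duration_s,
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

FRAMES_DIR_MANIFEST = "capture.json"


def write_video(
    capture: CaptureResult,
    path: str | Path,
    container: Literal["mp4", "avi", "frames-dir"] = "frames-dir",
) -> Path:
    """Write a capture to disk.

    ``frames-dir`` (always available, lossless): a directory of float32
    TIFF frames plus a JSON manifest carrying fps and provenance.  ``mp4``
    and ``avi`` require an ffmpeg-backed imageio plugin; if none is
    installed an explicit :class:`CaptureError` instructs the frames-dir
    fallback rather than failing silently.
    """
    import json

    path = Path(path)
    if container == "frames-dir":
        import tifffile

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(capture.frames):
            tifffile.imwrite(path / f"frame_{i:06d}.tif", frame)
        manifest = {
            "fps": capture.fps,
            "duration_s": capture.duration_s,
            "n_frames": int(capture.frames.shape[0]),
            "provenance": list(capture.provenance),
        }
        (path / FRAMES_DIR_MANIFEST).write_text(json.dumps(manifest, indent=2))
        return path

    if container not in ("mp4", "avi"):
        raise CaptureError(f"unknown container {container!r}")
    try:
        import imageio.v2 as iio

        writer = iio.get_writer(str(path), format="FFMPEG", fps=capture.fps)
    except Exception as exc:  # encoder missing
        raise CaptureError(
            f"no encoder available for {container!r} ({exc}); "
            "use container='frames-dir' instead"
        ) from exc
    with writer:
        for frame in capture.frames:
            writer.append_data(np.clip(frame, 0, 255).astype(np.uint8))
    return path
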