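"""Synthetic head-CT phantoms with known hematoma geometry.

Each phantom is a stack of axial grayscale slices on an 8-bit display scale
(values in [0, 255], brain ~80, blood ~160, skull 255), mimicking a
window/leveled PACS view rather than calibrated Hounsfield units.  The stack
contains an elliptical skull rim, a uniform brain background, a dark midline
structure (ventricle surrogate) that can be displaced laterally, rasterized
hematomas, additive Gaussian noise, and a bright scalebar burned into one
corner.  Every phantom carries a ground-truth sidecar: the exact volume of
the rasterized lesion mask, the ABC/2 volume implied by the generative
dimensions, the maximal subdural width, the midline shift, and a severity
label.

Coordinates: lesion centers are given in mm relative to the stack center
(x = columns, positive rightwards; y = rows, positive downwards; z = slice
axis, positive towards later slices).  Slices sample the volume at their
center plane.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

I_MAX = 255.0
BRAIN_INTENSITY = 80.0
BLOOD_INTENSITY = 160.0
SKULL_INTENSITY = 255.0
MIDLINE_INTENSITY = 20.0

#: outer semi-axes (x, y) in mm of the skull ellipse, and rim thickness in mm
DEFAULT_SKULL = (75.0, 92.0, 6.0)

GROUND_TRUTH_SCHEMA_VERSION = 1


class PhantomError(ValueError):
    """Raised for invalid phantom specifications (lesion outside skull, ...)."""


@dataclass(frozen=True)
class StackGeometry:
    """Spatial geometry of a slice stack.

    ``mm_per_px`` may be ``None`` for a stack reconstructed from a capture
    before scalebar calibration has been applied.
    """

    n_slices: int
    rows: int
    cols: int
    mm_per_px: float | None
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.rows < 1 or self.cols < 1:
            raise PhantomError("geometry dimensions must be positive")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise PhantomError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if not self.slice_thickness_mm > 0:
            raise PhantomError("slice_thickness_mm must be > 0")

    def with_scale(self, mm_per_px: float) -> "StackGeometry":
        return dataclasses.replace(self, mm_per_px=mm_per_px)

    @property
    def voxel_volume_mm3(self) -> float:
        if self.mm_per_px is None:
            raise PhantomError("uncalibrated geometry has no voxel volume")
        return self.mm_per_px**2 * self.slice_thickness_mm


DEFAULT_GEOMETRY = StackGeometry(
    n_slices=28, rows=512, cols=512, mm_per_px=0.45, slice_thickness_mm=5.0
)

#: reduced geometry used by the study orchestrator (same 230 mm field of view)
STUDY_GEOMETRY = StackGeometry(
    n_slices=20, rows=256, cols=256, mm_per_px=0.9, slice_thickness_mm=5.0
)


@dataclass
class SliceStack:
    """Ordered axial grayscale slices plus their geometry."""

    geometry: StackGeometry
    pixels: np.ndarray  # (n_slices, rows, cols) float32 in [0, I_MAX]

    def __post_init__(self) -> None:
        expected = (self.geometry.n_slices, self.geometry.rows, self.geometry.cols)
        if self.pixels.shape != expected:
            raise PhantomError(
                f"pixel shape {self.pixels.shape} inconsistent with geometry {expected}"
            )


@dataclass(frozen=True)
class LesionSpec:
    """Generative description of one hematoma.

    Parenchymal lesions are axis-aligned ellipsoids with ``semi_axes_mm``
    = (a, b, c), so A = 2a, B = 2b, C = 2c in the ABC/2 sense.  Subdural
    lesions are crescents between two equal-radius circles whose centers are
    offset by the maximal width: ``semi_axes_mm`` = (arc_radius,
    max_width / 2, half_extent) where ``half_extent`` is the half z-extent.
    """

    kind: Literal["subdural", "parenchymal"]
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    intensity: float = BLOOD_INTENSITY
    evacuated: bool = False
    side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.kind not in ("subdural", "parenchymal"):
            raise PhantomError(f"unknown lesion kind {self.kind!r}")
        if any(s <= 0 for s in self.semi_axes_mm):
            raise PhantomError("lesion size parameters must be > 0")
        if self.intensity <= BRAIN_INTENSITY:
            raise PhantomError("hyperdense blood must be brighter than brain")

    # --- generative ABC/2 dimensions -------------------------------------
    def abc_mm(self) -> tuple[float, float, float]:
        """(A, B, C) in mm implied by the generative parameters.

        For a crescent, A is the cusp-to-cusp chord 2*sqrt(R^2 - d^2/4) of
        the two-circle construction, B the maximal width d, C the z extent.
        """
        if self.kind == "parenchymal":
            a, b, c = self.semi_axes_mm
            return (2 * a, 2 * b, 2 * c)
        radius, half_width, half_extent = self.semi_axes_mm
        d = 2 * half_width
        if d >= 2 * radius:
            raise PhantomError("crescent width must be < diameter")
        return (2 * np.sqrt(radius**2 - d**2 / 4), d, 2 * half_extent)

    def abc_volume_cc(self) -> float:
        a, b, c = self.abc_mm()
        return a * b * c / 2.0 / 1000.0

    @property
    def max_width_mm(self) -> float:
        """Maximal width of a subdural crescent."""
        if self.kind != "subdural":
            raise PhantomError("max_width_mm is defined for subdural lesions only")
        return 2 * self.semi_axes_mm[1]


@dataclass(frozen=True)
class ScalebarSpec:
    """A bright calibration bar burned into one corner of every slice."""

    length_mm: float = 100.0
    tick_spacing_mm: float = 10.0
    position: Literal["lower-right", "lower-left", "upper-right", "upper-left"] = (
        "lower-right"
    )
    intensity: float = I_MAX

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.tick_spacing_mm <= 0:
            raise PhantomError("scalebar lengths must be positive")
        ratio = self.length_mm / self.tick_spacing_mm
        if abs(ratio - round(ratio)) > 1e-9:
            raise PhantomError("length_mm must be an integer multiple of tick_spacing_mm")


@dataclass(frozen=True)
class GroundTruth:
    """Exact answers implied by the generative lesion parameters."""

    true_volume_cc: float
    abc_volume_cc: float
    sdh_max_width_mm: float | None
    midline_shift_mm: float
    cisterns_effaced: bool
    evacuated: bool
    severity_label: Literal["mild", "moderate", "severe", "none"]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["schema_version"] = GROUND_TRUTH_SCHEMA_VERSION
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        payload.pop("schema_version", None)
        return cls(**payload)


# ---------------------------------------------------------------------------
# severity bins (half-open)
# ---------------------------------------------------------------------------

WIDTH_BIN_EDGES_MM = (5.0, 10.0)  # [0,5) mild, [5,10) moderate, [10,inf) severe
VOLUME_BIN_EDGES_CC = (10.0, 30.0)  # [0,10) mild, [10,30) moderate, [30,inf) severe


def severity_from_width(width_mm: float) -> str:
    if width_mm < WIDTH_BIN_EDGES_MM[0]:
        return "mild"
    if width_mm < WIDTH_BIN_EDGES_MM[1]:
        return "moderate"
    return "severe"


def severity_from_volume(volume_cc: float) -> str:
    if volume_cc < VOLUME_BIN_EDGES_CC[0]:
        return "mild"
    if volume_cc < VOLUME_BIN_EDGES_CC[1]:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _grid_mm(geometry: StackGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center-relative mm coordinates of pixel centers (x cols, y rows, z slices)."""
    g = geometry
    if g.mm_per_px is None:
        raise PhantomError("rasterization requires a calibrated geometry")
    x = (np.arange(g.cols) - (g.cols - 1) / 2.0) * g.mm_per_px
    y = (np.arange(g.rows) - (g.rows - 1) / 2.0) * g.mm_per_px
    z = (np.arange(g.n_slices) + 0.5) * g.slice_thickness_mm - (
        g.n_slices * g.slice_thickness_mm
    ) / 2.0
    return x, y, z


def _skull_masks(
    geometry: StackGeometry, skull: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(rim mask, brain interior mask) for one slice, as 2-D booleans."""
    ax_out, ay_out, thickness = skull
    ax_in, ay_in = ax_out - thickness, ay_out - thickness
    x, y, _ = _grid_mm(geometry)
    xx, yy = np.meshgrid(x, y)
    r_out = (xx / ax_out) ** 2 + (yy / ay_out) ** 2
    r_in = (xx / ax_in) ** 2 + (yy / ay_in) ** 2
    rim = (r_out <= 1.0) & (r_in > 1.0)
    interior = r_in <= 1.0
    return rim, interior


def rasterize_lesion(lesion: LesionSpec, geometry: StackGeometry) -> np.ndarray:
    """Boolean voxel mask of one lesion on the given geometry.

    Slices sample the lesion at their center plane, so the z-extent of the
    mask is the set of slice centers strictly inside the lesion.
    """
    x, y, z = _grid_mm(geometry)
    cx, cy, cz = lesion.center_mm
    mask = np.zeros((geometry.n_slices, geometry.rows, geometry.cols), dtype=bool)
    xx, yy = np.meshgrid(x - cx, y - cy)

    if lesion.kind == "parenchymal":
        a, b, c = lesion.semi_axes_mm
        r2_plane = (xx / a) ** 2 + (yy / b) ** 2
        for k, zk in enumerate(z):
            dz = (zk - cz) / c
            if abs(dz) < 1.0:
                mask[k] = r2_plane <= 1.0 - dz**2
    else:
        radius, half_width, half_extent = lesion.semi_axes_mm
        d = 2 * half_width
        # apex direction: towards the chosen side (left = -x)
        ux = -1.0 if lesion.side == "left" else 1.0
        # outer circle centered at lesion center; inner circle offset by d
        # opposite the apex.  Crescent = inside outer, outside inner.
        r_out2 = xx**2 + yy**2
        r_in2 = (xx + ux * d) ** 2 + yy**2  # inner center shifted away from apex
        plane = (r_out2 <= radius**2) & (r_in2 > radius**2)
        for k, zk in enumerate(z):
            if abs(zk - cz) < half_extent:
                mask[k] = plane
    return mask


def _check_lesion_inside(
    lesion: LesionSpec, skull: tuple[float, float, float]
) -> None:
    ax_out, ay_out, thickness = skull
    ax_in, ay_in = ax_out - thickness, ay_out - thickness
    cx, cy, _ = lesion.center_mm
    if lesion.kind == "parenchymal":
        a, b, _ = lesion.semi_axes_mm
        # conservative bounding-box corner check against the inner ellipse
        for sx in (-1, 1):
            for sy in (-1, 1):
                px, py = cx + sx * a, cy + sy * b
                if (px / ax_in) ** 2 + (py / ay_in) ** 2 > 1.0:
                    raise PhantomError(
                        f"parenchymal lesion at {lesion.center_mm} extends outside "
                        "the inner skull ellipse"
                    )
    else:
        radius = lesion.semi_axes_mm[0]
        reach = np.hypot(cx, cy) + radius
        if reach > min(ax_in, ay_in):
            raise PhantomError(
                f"subdural crescent (radius {radius} mm) does not fit inside the "
                "inner skull ellipse"
            )


def _draw_scalebar(
    slice_px: np.ndarray, geometry: StackGeometry, spec: ScalebarSpec
) -> None:
    """Burn a horizontal bright bar with ticks into the stated corner (in place)."""
    length_px = int(round(spec.length_mm / geometry.mm_per_px))
    # 3.5 mm bar thickness: stays visible after a 0.5x resample plus blur
    bar_height = max(3, int(round(3.5 / geometry.mm_per_px)))
    tick_height = 2 * bar_height
    margin = max(6, int(round(5.0 / geometry.mm_per_px)))
    rows, cols = slice_px.shape
    if length_px + 2 * margin > cols:
        raise PhantomError("scalebar does not fit in the frame")

    vert, horiz = spec.position.split("-")
    c0 = margin if horiz == "left" else cols - margin - length_px
    if vert == "lower":
        r1 = rows - margin
        r0 = r1 - bar_height
        rt0 = r1 - tick_height
        slice_px[r0:r1, c0 : c0 + length_px] = spec.intensity
        n_ticks = int(round(spec.length_mm / spec.tick_spacing_mm))
        for t in range(n_ticks + 1):
            ct = c0 + int(round(t * spec.tick_spacing_mm / geometry.mm_per_px))
            ct = min(ct, c0 + length_px - 1)
            slice_px[rt0:r1, ct : ct + 1] = spec.intensity
    else:
        r0 = margin
        r1 = r0 + bar_height
        rt1 = r0 + tick_height
        slice_px[r0:r1, c0 : c0 + length_px] = spec.intensity
        n_ticks = int(round(spec.length_mm / spec.tick_spacing_mm))
        for t in range(n_ticks + 1):
            ct = c0 + int(round(t * spec.tick_spacing_mm / geometry.mm_per_px))
            ct = min(ct, c0 + length_px - 1)
            slice_px[r0:rt1, ct : ct + 1] = spec.intensity


def generate_phantom(
    lesions: Sequence[LesionSpec],
    geometry: StackGeometry = DEFAULT_GEOMETRY,
    shift_mm: float = 0.0,
    noise_sd: float = 6.0,
    scalebar: ScalebarSpec = ScalebarSpec(),
    seed: int = 0,
    skull: tuple[float, float, float] = DEFAULT_SKULL,
    cisterns_effaced: bool | None = None,
) -> tuple[SliceStack, GroundTruth]:
    """Render a phantom stack and its ground truth.

    Parameters
    ----------
    lesions:
        Hematoma specifications; may be empty.
    shift_mm:
        Lateral displacement of the midline structure towards the right
        (positive x).  The skull itself stays fixed.
    noise_sd:
        SD of additive Gaussian noise, independent per voxel (so adjacent
        slices differ even where the anatomy does not — as real CT noise
        does).
    cisterns_effaced:
        Ground-truth cistern status.  Defaults to ``shift_mm > 5`` (severe
        mass effect) when not given.

    Returns the stack and a :class:`GroundTruth` whose ``true_volume_cc``
    comes from the rasterized mask voxel count and whose ``abc_volume_cc``
    comes from the generative dimensions.
    """
    if shift_mm < 0:
        raise PhantomError("shift_mm must be >= 0")
    if noise_sd < 0:
        raise PhantomError("noise_sd must be >= 0")
    for lesion in lesions:
        _check_lesion_inside(lesion, skull)

    rim, interior = _skull_masks(geometry, skull)
    base = np.full((geometry.rows, geometry.cols), 0.0, dtype=np.float64)
    base[interior] = BRAIN_INTENSITY
    base[rim] = SKULL_INTENSITY

    stack = np.repeat(base[None, :, :], geometry.n_slices, axis=0)

    lesion_union = np.zeros(stack.shape, dtype=bool)
    for lesion in lesions:
        mask = rasterize_lesion(lesion, geometry)
        stack[mask] = lesion.intensity
        lesion_union |= mask

    # midline structure: a dark 2 px line displaced by shift_mm, drawn over
    # the central 60% of the brain's vertical extent on every slice
    shift_px = shift_mm / geometry.mm_per_px
    cx = (geometry.cols - 1) / 2.0 + shift_px
    # the 2 px line straddles cx: first column at cx - 0.5
    c0 = int(round(cx - 0.5))
    _, ay_out, thickness = skull
    half_rows = 0.6 * (ay_out - thickness) / geometry.mm_per_px
    r_mid = (geometry.rows - 1) / 2.0
    r0, r1 = int(round(r_mid - half_rows)), int(round(r_mid + half_rows))
    stack[:, r0:r1, c0 : c0 + 2] = MIDLINE_INTENSITY

    for k in range(geometry.n_slices):
        _draw_scalebar(stack[k], geometry, scalebar)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, I_MAX).astype(np.float32)

    true_volume_cc = float(lesion_union.sum()) * geometry.voxel_volume_mm3 / 1000.0
    abc_volume_cc = float(sum(l.abc_volume_cc() for l in lesions))
    sdh_widths = [l.max_width_mm for l in lesions if l.kind == "subdural"]
    sdh_max_width = max(sdh_widths) if sdh_widths else None

    severity = _severity_label(lesions, abc_volume_cc, sdh_max_width)
    if cisterns_effaced is None:
        cisterns_effaced = shift_mm > 5.0

    truth = GroundTruth(
        true_volume_cc=true_volume_cc,
        abc_volume_cc=abc_volume_cc,
        sdh_max_width_mm=sdh_max_width,
        midline_shift_mm=float(shift_mm),
        cisterns_effaced=bool(cisterns_effaced),
        evacuated=any(l.evacuated for l in lesions),
        severity_label=severity,
    )
    return SliceStack(geometry=geometry, pixels=stack), truth


def _severity_label(
    lesions: Sequence[LesionSpec],
    abc_volume_cc: float,
    sdh_max_width_mm: float | None,
) -> str:
    if not lesions:
        return "none"
    kinds = {l.kind for l in lesions}
    if kinds == {"subdural"} and len(lesions) == 1:
        return severity_from_width(sdh_max_width_mm)
    return severity_from_volume(abc_volume_cc)


# ---------------------------------------------------------------------------
# default lesion menu: the study's 8 index cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MenuEntry:
    name: str
    lesions: tuple[LesionSpec, ...]
    shift_mm: float


def default_lesion_menu() -> list[MenuEntry]:
    """The 8 index configurations spanning the severity design.

    3 isolated subdural crescents with maximal widths in the [0,5), [5,10)
    and [10,inf) mm bins; 2 isolated parenchymal contusions with ABC/2
    volumes in [1,10) and [10,30) cc; 3 multi-compartment combinations
    (subdural + parenchymal) with total ABC/2 volumes in [1,10), [10,30)
    and [30,inf) cc, the last with midline shift > 5 mm.

    Lesion z-centers sit at z = 0 (the boundary between the two central
    slices for an even slice count) and z-extents are even multiples of the
    5 mm default slice thickness, so the slice-count C measurement is exact
    on the default geometries (an odd multiple would put the lesion
    boundary exactly on slice centers and drop one slice).
    """
    sd = lambda r, w, hz, cx=0.0, cy=0.0: LesionSpec(  # noqa: E731
        kind="subdural", center_mm=(cx, cy, 0.0), semi_axes_mm=(r, w / 2, hz)
    )
    par = lambda a, b, c, cx, cy: LesionSpec(  # noqa: E731
        kind="parenchymal", center_mm=(cx, cy, 0.0), semi_axes_mm=(a, b, c)
    )
    return [
        MenuEntry("subdural_mild", (sd(50.0, 4.0, 10.0),), 0.0),
        MenuEntry("subdural_moderate", (sd(55.0, 7.7, 10.0),), 0.0),
        MenuEntry("subdural_severe", (sd(60.0, 12.4, 10.0),), 0.0),
        MenuEntry("parenchymal_mild", (par(15.0, 12.5, 10.0, -30.0, -10.0),), 0.0),
        MenuEntry("parenchymal_moderate", (par(24.0, 21.0, 10.0, -30.0, 5.0),), 0.0),
        # multi-compartment combinations keep a clear gap between the
        # parenchymal mass and the crescent so the compartments stay
        # separable on the degraded captures
        MenuEntry(
            "multi_mild",
            (par(10.0, 9.0, 10.0, -25.0, -5.0), sd(45.0, 3.0, 5.0)),
            0.0,
        ),
        MenuEntry(
            "multi_moderate",
            (par(16.0, 14.0, 10.0, -23.0, 5.0), sd(52.0, 4.0, 10.0)),
            0.0,
        ),
        MenuEntry(
            "multi_severe",
            (par(24.0, 20.0, 15.0, -18.0, 0.0), sd(55.0, 8.0, 10.0)),
            8.0,
        ),
    ]


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def write_phantom(
    stack: SliceStack, truth: GroundTruth, path: str | Path
) -> tuple[Path, Path]:
    """Write ``<path>.tif`` (multi-page float32) and ``<path>.json`` sidecar."""
    path = Path(path)
    tif_path = path.with_suffix(".tif")
    json_path = path.with_suffix(".json")
    g = stack.geometry
    metadata = {
        "mm_per_px": g.mm_per_px,
        "slice_thickness_mm": g.slice_thickness_mm,
    }
    tifffile.imwrite(tif_path, stack.pixels, metadata=metadata)
    json_path.write_text(truth.to_json())
    return tif_path, json_path


def read_phantom(path: str | Path) -> tuple[SliceStack, GroundTruth]:
    path = Path(path)
    tif_path = path.with_suffix(".tif")
    json_path = path.with_suffix(".json")
    with tifffile.TiffFile(tif_path) as tif:
        pixels = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pixels.ndim == 2:
        pixels = pixels[None]
    geometry = StackGeometry(
        n_slices=pixels.shape[0],
        rows=pixels.shape[1],
        cols=pixels.shape[2],
        mm_per_px=meta.get("mm_per_px"),
        slice_thickness_mm=float(meta.get("slice_thickness_mm", 5.0)),
    )
    truth = GroundTruth.from_json(json_path.read_text())
    return SliceStack(geometry=geometry, pixels=pixels.astype(np.float32)), truth
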