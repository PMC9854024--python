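"""Measurement operators on a calibrated slice stack.

These implement the quantities read off each scan: hematoma volume by the
bedside ABC/2 rule (largest in-plane diameter × perpendicular diameter ×
vertical extent, halved — the ellipsoid approximation V ≈ A·B·C/2),
maximal subdural width, midline shift, lesion contrast-to-noise ratio

    CNR = |mean(SI_lesion) - mean(SI_surround)| / SD(SI_surround),

the 6-category Marshall CT classification, and the severity class used to
select the index cases.

Regions of interest are supplied, not segmented: the pipeline measures
given masks (normally the ground-truth masks projected through the capture
transform, standing in for a human rater's tracing), plus a simple
threshold-based fallback for demos.  All mm conversions use the stack's
calibrated geometry — the one recovered from the scalebar — never the
generator's true scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import transform as sk_transform

from .phantom import (
    BRAIN_INTENSITY,
    SKULL_INTENSITY,
    SliceStack,
    severity_from_volume,
    severity_from_width,
)


class MetricError(ValueError):
    """Raised for empty ROIs, undefined statistics, or invalid inputs."""


@dataclass
class LesionROI:
    """Per-slice lesion masks and same-slice surround (brain annulus) masks."""

    lesion: np.ndarray  # (n_slices, rows, cols) bool
    surround: np.ndarray  # same shape, disjoint from lesion

    def __post_init__(self) -> None:
        if self.lesion.shape != self.surround.shape:
            raise MetricError("lesion and surround masks must share a shape")
        if np.any(self.lesion & self.surround):
            raise MetricError("lesion and surround masks overlap")
        both = (self.lesion.any(axis=(1, 2)) & self.surround.any(axis=(1, 2))).any()
        if not both:
            raise MetricError("no slice has both lesion and surround pixels")


@dataclass
class MeasurementRecord:
    """One device's (or the PACS reference's) measurements of one lesion."""

    lesion_id: str
    device_name: str
    volume_cc: float
    sdh_width_mm: float | None
    midline_shift_mm: float
    marshall: int
    cnr: float
    severity: Literal["mild", "moderate", "severe"]

    def __post_init__(self) -> None:
        if self.volume_cc < 0:
            raise MetricError("volume_cc must be >= 0")
        if self.marshall not in range(1, 7):
            raise MetricError("marshall must be in 1..6")


# ---------------------------------------------------------------------------
# ABC/2 volume
# ---------------------------------------------------------------------------


def abc2_volume(a_mm: float, b_mm: float, c_mm: float) -> float:
    """A·B·C/2 in cc, with A, B, C given in mm (1 cc = 1000 mm^3)."""
    if a_mm < 0 or b_mm < 0 or c_mm < 0:
        raise MetricError("ABC/2 dimensions must be non-negative")
    return (a_mm / 10.0) * (b_mm / 10.0) * (c_mm / 10.0) / 2.0


def _boundary_points(mask2d: np.ndarray) -> np.ndarray:
    """(N, 2) array of (row, col) boundary pixel coordinates."""
    eroded = ndimage.binary_erosion(mask2d)
    boundary = mask2d & ~eroded
    return np.argwhere(boundary)


def _longest_chord(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact longest pairwise distance over boundary pixel centers.

    Brute force over all pairs: the masks here are small enough that the
    O(N^2) search is affordable and unambiguous.  Returns (length_px,
    unit direction).
    """
    d = points[:, None, :] - points[None, :, :]
    dist2 = (d**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(dist2), dist2.shape)
    vec = (points[j] - points[i]).astype(float)
    length = float(np.sqrt(dist2[i, j]))
    direction = vec / length if length > 0 else np.array([1.0, 0.0])
    return length, direction


def _longest_perpendicular_chord(
    mask2d: np.ndarray, direction: np.ndarray
) -> float:
    """Longest in-mask chord perpendicular to the A axis, in pixels.

    Every mask pixel is projected onto the A axis (t) and its perpendicular
    (s); within each 1 px bin of t, the chord is the s-extent of the mask.
    Measuring the extent of mask pixels (rather than distances between
    boundary pixels) keeps the chord inside the lesion, which matters for
    concave shapes like subdural crescents: their width, not the sag of
    their arc, is the clinically measured B.
    """
    pts = np.argwhere(mask2d).astype(float)
    t = pts @ direction
    s = pts @ np.array([-direction[1], direction[0]])
    bins = np.round(t).astype(int)
    bins -= bins.min()
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    s_sorted = s[order]
    best = 0.0
    starts = np.searchsorted(bins_sorted, np.arange(bins_sorted[-1] + 1))
    ends = np.append(starts[1:], s_sorted.size)
    for a, b in zip(starts, ends):
        if b > a:
            seg = s_sorted[a:b]
            best = max(best, float(seg.max() - seg.min()))
    return best


def measure_abc(stack: SliceStack, roi: LesionROI) -> tuple[float, float, float]:
    """(A, B, C) in mm from the lesion mask.

    A is the longest in-plane extent (caliper diameter over boundary pixel
    pairs) on the slice of maximal lesion area — the ruler measurement a
    rater makes across the lesion's endpoints; B is the longest in-mask
    chord perpendicular to A on that slice; C is the number of
    lesion-bearing slices times the slice thickness.  The in-plane lengths
    get one pixel added to account for the extent of the boundary pixels
    themselves (center-to-center distance underestimates a mask's physical
    span by one pixel).
    """
    mm_per_px = stack.geometry.mm_per_px
    if mm_per_px is None:
        raise MetricError("stack is not calibrated")
    areas = roi.lesion.sum(axis=(1, 2))
    if areas.sum() == 0:
        raise MetricError("empty lesion ROI")
    k = int(np.argmax(areas))
    points = _boundary_points(roi.lesion[k])
    if points.shape[0] == 1:
        a_px = b_px = 0.0
    else:
        a_px, direction = _longest_chord(points)
        b_px = _longest_perpendicular_chord(roi.lesion[k], direction)
    a_mm = (a_px + 1.0) * mm_per_px
    b_mm = (b_px + 1.0) * mm_per_px
    c_mm = float((areas > 0).sum()) * stack.geometry.slice_thickness_mm
    return a_mm, b_mm, c_mm


def measure_volume(stack: SliceStack, roi: LesionROI) -> float:
    """ABC/2 volume in cc from the measured dimensions."""
    return abc2_volume(*measure_abc(stack, roi))


# ---------------------------------------------------------------------------
# subdural width
# ---------------------------------------------------------------------------


def sdh_max_thickness(
    stack: SliceStack, roi: LesionROI
) -> tuple[float, bool]:
    """Maximal subdural crescent width in mm.

    The mask locates the crescent's widest point (the Euclidean distance
    transform maximum over slices: the center of the largest inscribed
    disc); the width itself is then read off the intensity image, the way
    a rater drags a calibrated ruler across the displayed band: the image
    is sampled along lines through that point at a fan of orientations,
    and the width is the shortest full-width-at-half-maximum of the bright
    band over orientations.  Sampling the image rather than counting mask
    pixels gives sub-pixel precision that survives resampling and blur.
    If no usable intensity profile exists (e.g. the mask does not coincide
    with a bright band), the binary estimate 2·EDT_max − 1 px is used.

    Returns ``(width_mm, low_confidence)``: widths that collapse to about
    one pixel are flagged rather than silently reported as 0.
    """
    mm_per_px = stack.geometry.mm_per_px
    if mm_per_px is None:
        raise MetricError("stack is not calibrated")
    if not roi.lesion.any():
        raise MetricError("empty lesion ROI")
    best = 0.0
    best_k, best_rc = 0, (0, 0)
    for k, mask2d in enumerate(roi.lesion):
        if mask2d.any():
            edt = ndimage.distance_transform_edt(mask2d)
            m = float(edt.max())
            if m > best:
                best = m
                best_k = k
                best_rc = np.unravel_index(int(edt.argmax()), edt.shape)
    low_confidence = best <= 1.0
    width_px = _band_fwhm(stack.pixels[best_k], roi.lesion[best_k], best_rc, best)
    if width_px is None:
        # 2*EDT counts center-to-center distance and overstates a band's
        # physical width by one pixel (cf. the +1 px in measure_abc)
        width_px = max(0.0, 2.0 * best - 1.0)
    return width_px * mm_per_px, low_confidence


def _band_fwhm(
    image: np.ndarray,
    mask2d: np.ndarray,
    center: tuple[int, int],
    inradius_px: float,
) -> float | None:
    """Width (px) of the bright band through ``center``; ``None`` if no
    band-like profile exists.

    The band's normal direction comes from a local principal-component
    analysis of the mask around each sample point (the minor axis of a
    thin band is its normal), refined by choosing the orientation with the
    shortest full-width-at-half-maximum over a small fan.  The width along
    that normal is estimated by fitting a blurred-boxcar model (two erf
    edges with free width, blur, amplitude, center and baseline), which
    removes the upward FWHM bias of narrow blurred bands.  Fits at several
    positions along the band's ridge are averaged: the distance-transform
    maximum preferentially lands where rasterization painted the band
    widest, and averaging over nearby arc positions removes that
    pixel-phase selection bias.
    """
    half_len = max(6.0, 3.0 * inradius_px + 3.0)
    t = np.arange(-half_len, half_len + 0.25, 0.25)
    edt = ndimage.distance_transform_edt(mask2d)

    refined = []
    fallback = None
    # the PCA window must straddle the band to see its anisotropy
    pca_radius = max(7.0, 3.0 * inradius_px)
    theta0 = _local_normal(mask2d, center, radius=pca_radius)
    tan_dr, tan_dc = np.cos(theta0), -np.sin(theta0)
    for offset in (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0):
        p = (center[0] + offset * tan_dr, center[1] + offset * tan_dc)
        p = _snap_to_ridge(edt, p)
        if p is None:
            continue
        theta_local = _local_normal(mask2d, p, radius=pca_radius)
        best = None
        for dtheta in (-np.pi / 12, -np.pi / 24, 0.0, np.pi / 24, np.pi / 12):
            prof = _line_profile(image, p, theta_local + dtheta, t)
            res = _profile_fwhm(prof, t, inradius_px)
            if res is not None and (best is None or res[0] < best[1][0]):
                best = (prof, res)
        if best is None:
            continue
        prof, res = best
        fallback = res[0] if fallback is None else min(fallback, res[0])
        w_fit = _erf_band_fit(prof, t, *res)
        refined.append(w_fit if w_fit is not None else res[0])
    if refined:
        # median over arc positions: robust to an occasional profile that
        # escaped along the band instead of across it
        return float(np.median(refined))
    return fallback


def _local_normal(
    mask2d: np.ndarray, center: tuple[float, float], radius: float = 7.0
) -> float:
    """Orientation of the band's normal at ``center``: the minor principal
    axis of nearby mask pixel coordinates.  Returned as the angle theta
    with direction (sin theta, cos theta) in (row, col) convention."""
    pts = np.argwhere(mask2d).astype(float)
    d2 = ((pts - np.asarray(center)) ** 2).sum(axis=1)
    local = pts[d2 <= radius**2]
    if local.shape[0] < 3:
        return 0.0
    cov = np.cov((local - local.mean(axis=0)).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest-variance axis
    return float(np.arctan2(normal[0], normal[1])) % np.pi


def _snap_to_ridge(
    edt: np.ndarray, p: tuple[float, float], radius: int = 2
) -> tuple[int, int] | None:
    """Move a point to the locally deepest mask pixel (the band's ridge)."""
    r0 = int(round(p[0]))
    c0 = int(round(p[1]))
    r_lo, r_hi = max(0, r0 - radius), min(edt.shape[0], r0 + radius + 1)
    c_lo, c_hi = max(0, c0 - radius), min(edt.shape[1], c0 + radius + 1)
    window = edt[r_lo:r_hi, c_lo:c_hi]
    if window.size == 0 or window.max() <= 0:
        return None
    dr, dc = np.unravel_index(int(window.argmax()), window.shape)
    return (r_lo + int(dr), c_lo + int(dc))


def _line_profile(
    image: np.ndarray, center: tuple[float, float], theta: float, t: np.ndarray
) -> np.ndarray:
    dr, dc = np.sin(theta), np.cos(theta)
    coords = np.stack([center[0] + t * dr, center[1] + t * dc])
    return ndimage.map_coordinates(
        image.astype(np.float64), coords, order=1, mode="nearest"
    )


def _profile_fwhm(
    profile: np.ndarray, t: np.ndarray, inradius_px: float
) -> tuple[float, float, float] | None:
    """(width, lo, hi) at half maximum, or None for unusable profiles."""
    mid = t.size // 2
    core = profile[np.abs(t) <= inradius_px + 1.0]
    peak = float(core.max())
    base = max(float(profile[:mid].min()), float(profile[mid:].min()))
    if peak - base < 40.0:
        # the line never leaves the band on one side (near-tangent
        # orientation): no usable background level
        return None
    half = (peak + base) / 2.0
    lo = _outward_crossing(profile, t, mid, half, step=-1)
    hi = _outward_crossing(profile, t, mid, half, step=+1)
    if lo is None or hi is None:
        return None
    return hi - lo, lo, hi


def _erf_band_fit(
    profile: np.ndarray, t: np.ndarray, width0: float, lo: float, hi: float
) -> float | None:
    """Fit base + A/2·[erf((t−t0+w/2)/σ√2) − erf((t−t0−w/2)/σ√2)]."""
    from scipy.optimize import curve_fit
    from scipy.special import erf

    keep = (t >= lo - 4.0) & (t <= hi + 4.0)
    tt, yy = t[keep], profile[keep]

    def model(t, w, sigma, amp, t0, base):
        s = np.sqrt(2.0) * sigma
        return base + amp / 2.0 * (
            erf((t - t0 + w / 2.0) / s) - erf((t - t0 - w / 2.0) / s)
        )

    center0 = (lo + hi) / 2.0
    p0 = [width0, 0.8, float(yy.max() - yy.min()), center0, float(yy.min())]
    try:
        popt, _ = curve_fit(
            model,
            tt,
            yy,
            p0=p0,
            bounds=(
                [0.3, 0.05, 10.0, center0 - width0, 0.0],
                [4.0 * width0, 5.0, 400.0, center0 + width0, 255.0],
            ),
            maxfev=2000,
        )
    except Exception:
        return None
    w = float(popt[0])
    if not 0.5 * width0 <= w <= 1.5 * width0:
        return None
    return w


def _outward_crossing(
    profile: np.ndarray, t: np.ndarray, mid: int, half: float, step: int
) -> float | None:
    """First sub-sample crossing of ``half`` walking outward from ``mid``."""
    i = mid
    while 0 < i < profile.size - 1:
        j = i + step
        if profile[j] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return float(t[i] + frac * (t[j] - t[i]))
        i = j
    return None


# ---------------------------------------------------------------------------
# midline shift
# ---------------------------------------------------------------------------


def midline_shift(
    stack: SliceStack, skull_threshold: float | None = None
) -> float:
    """Lateral displacement (mm) of the dark midline structure from the
    skull's symmetry axis, at the most displaced slice.

    The ideal midline is the vertical line through the centroid of the
    bright skull rim; the measured midline is the intensity-weighted locus
    of the darkest in-brain column band, refined to sub-pixel precision.
    """
    mm_per_px = stack.geometry.mm_per_px
    if mm_per_px is None:
        raise MetricError("stack is not calibrated")
    if skull_threshold is None:
        skull_threshold = (BRAIN_INTENSITY + SKULL_INTENSITY) / 2.0

    shifts = []
    for slice_px in stack.pixels:
        rim = slice_px >= skull_threshold
        if not rim.any():
            continue
        cols = np.argwhere(rim)[:, 1]
        # drop the scalebar: keep the largest connected component (the rim)
        labels, n = ndimage.label(rim)
        if n > 1:
            sizes = ndimage.sum_labels(rim, labels, index=np.arange(1, n + 1))
            rim = labels == (1 + int(np.argmax(sizes)))
            cols = np.argwhere(rim)[:, 1]
        axis_x = float(cols.mean())

        # search for the dark line inside the central band of the brain
        rows, ncols = slice_px.shape
        r0, r1 = int(rows * 0.35), int(rows * 0.65)
        band = slice_px[r0:r1]
        col_mean = band.mean(axis=0)
        lo = int(ncols * 0.25)
        hi = int(ncols * 0.75)
        seg = col_mean[lo:hi]
        j = int(np.argmin(seg))
        # sub-pixel refinement: intensity-weighted centroid of the dip
        window = seg[max(0, j - 3) : j + 4]
        depth = np.clip(np.median(seg) - window, 0.0, None)
        if depth.sum() <= 0:
            continue
        offsets = np.arange(max(0, j - 3), j + 4) - j
        x = lo + j + float((offsets * depth).sum() / depth.sum())
        shifts.append(abs(x - axis_x))

    if not shifts:
        raise MetricError(
            "midline structure undetectable: no slice produced both a skull "
            "rim and an in-brain intensity dip"
        )
    return max(shifts) * mm_per_px


# ---------------------------------------------------------------------------
# contrast-to-noise ratio
# ---------------------------------------------------------------------------


def cnr(stack: SliceStack, roi: LesionROI) -> float:
    """|mean lesion SI − mean surround SI| / SD of surround SI.

    Pooled over all slices where both masks are nonempty.  The noise SD is
    taken over the surround region — the only defined noise-bearing region.
    Affine luminance changes (positive gain, any offset) cancel exactly.
    """
    both = roi.lesion.any(axis=(1, 2)) & roi.surround.any(axis=(1, 2))
    if not both.any():
        raise MetricError("no slice has both lesion and surround pixels")
    lesion_vals = stack.pixels[both][roi.lesion[both]].astype(np.float64)
    surround_vals = stack.pixels[both][roi.surround[both]].astype(np.float64)
    sd = float(surround_vals.std(ddof=1))
    if sd == 0.0:
        raise MetricError("zero surround variance: CNR undefined")
    return abs(float(lesion_vals.mean()) - float(surround_vals.mean())) / sd


# ---------------------------------------------------------------------------
# Marshall score and severity class
# ---------------------------------------------------------------------------


def marshall_score(
    mass_cc: float,
    shift_mm: float,
    cisterns_effaced: bool,
    evacuated: bool,
    visible_pathology: bool,
) -> int:
    """6-category Marshall CT classification of diffuse head injury.

    Categories: (1) normal for age; (2) visible high/mixed-density mass
    < 25 cc, shift < 5 mm, cisterns preserved; (3) cisterns effaced, mass
    < 25 cc, shift < 5 mm; (4) midline shift > 5 mm; (5) surgically
    evacuated mass > 25 cc; (6) non-evacuated mass > 25 cc.

    The rubric lists categories without a tie-break; this implementation
    applies mass-size rules (5/6) first, then shift (4), then cistern
    status (3), then visible pathology (2).
    """
    if mass_cc < 0 or shift_mm < 0:
        raise MetricError("mass_cc and shift_mm must be >= 0")
    if mass_cc > 25.0:
        return 5 if evacuated else 6
    if shift_mm > 5.0:
        return 4
    if cisterns_effaced:
        return 3
    if visible_pathology:
        return 2
    return 1


def severity_class(
    kind: Literal["subdural", "parenchymal", "multi-compartment"],
    width_mm: float | None = None,
    total_volume_cc: float | None = None,
) -> str:
    """Severity bin: subdural lesions by maximal width ([0,5), [5,10),
    [10,inf) mm), parenchymal and multi-compartment by total ABC/2 volume
    ([0,10), [10,30), [30,inf) cc)."""
    if kind == "subdural":
        if width_mm is None or width_mm < 0:
            raise MetricError("subdural severity needs a non-negative width")
        return severity_from_width(width_mm)
    if kind in ("parenchymal", "multi-compartment"):
        if total_volume_cc is None or total_volume_cc < 0:
            raise MetricError("volume severity needs a non-negative volume")
        return severity_from_volume(total_volume_cc)
    raise MetricError(f"unknown lesion kind {kind!r}")


# ---------------------------------------------------------------------------
# ROI construction
# ---------------------------------------------------------------------------


def roi_from_masks(
    lesion_mask: np.ndarray,
    brain_mask: np.ndarray,
    annulus_px: tuple[int, int] = (2, 8),
) -> LesionROI:
    """Surround = brain-tissue annulus ``annulus_px`` (inner, outer) pixels
    around the lesion, excluding the lesion itself and non-brain structures."""
    inner, outer = annulus_px
    struct = ndimage.generate_binary_structure(2, 1)
    surround = np.zeros_like(lesion_mask)
    for k in range(lesion_mask.shape[0]):
        if not lesion_mask[k].any():
            continue
        near = ndimage.binary_dilation(lesion_mask[k], struct, iterations=outer)
        guard = ndimage.binary_dilation(lesion_mask[k], struct, iterations=inner)
        surround[k] = near & ~guard & brain_mask[k]
    return LesionROI(lesion=lesion_mask, surround=surround)


def project_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Project a per-slice boolean mask through a spatial resample to
    ``shape`` (nearest-neighbour, as a rater's tracing would follow the
    displayed image)."""
    if mask.shape[1:] == shape:
        return mask.copy()
    out = np.zeros((mask.shape[0],) + shape, dtype=bool)
    for k in range(mask.shape[0]):
        out[k] = (
            sk_transform.resize(
                mask[k].astype(float), shape, order=0, preserve_range=True
            )
            > 0.5
        )
    return out


def roi_by_threshold(
    stack: SliceStack,
    blood_threshold: float = 120.0,
    min_area_px: int = 20,
) -> LesionROI:
    """Demo fallback: segment hyperdense (blood-bright) tissue inside the
    brain by a fixed threshold.  Not a substitute for rater-grade ROIs."""
    rim_thresh = (BRAIN_INTENSITY + SKULL_INTENSITY) / 2.0
    lesion = np.zeros(stack.pixels.shape, dtype=bool)
    brain = np.zeros(stack.pixels.shape, dtype=bool)
    for k, slice_px in enumerate(stack.pixels):
        rim = slice_px >= rim_thresh
        labels, n = ndimage.label(rim)
        if n >= 1:
            sizes = ndimage.sum_labels(rim, labels, index=np.arange(1, n + 1))
            rim = labels == (1 + int(np.argmax(sizes)))
        interior = ndimage.binary_fill_holes(rim) & ~rim
        brain[k] = interior
        cand = (slice_px >= blood_threshold) & interior
        labels, n = ndimage.label(cand)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() >= min_area_px:
                lesion[k] |= comp
    if not lesion.any():
        raise MetricError("threshold segmentation found no lesion")
    return roi_from_masks(lesion, brain)


def measure_lesion(
    stack: SliceStack,
    roi: LesionROI,
    lesion_id: str,
    device_name: str,
    kind: Literal["subdural", "parenchymal", "multi-compartment"],
    cisterns_effaced: bool,
    evacuated: bool,
    sdh_roi: LesionROI | None = None,
) -> MeasurementRecord:
    """Full measurement of one lesion on one (possibly degraded) stack.

    ``roi`` covers all compartments (volume and CNR); ``sdh_roi``, when
    given, isolates the subdural compartment for the width measurement.
    """
    volume = measure_volume(stack, roi)
    width: float | None = None
    if kind == "subdural" or sdh_roi is not None:
        width, _ = sdh_max_thickness(stack, sdh_roi or roi)
    shift = midline_shift(stack)
    score = marshall_score(
        mass_cc=volume,
        shift_mm=shift,
        cisterns_effaced=cisterns_effaced,
        evacuated=evacuated,
        visible_pathology=True,
    )
    severity = severity_class(
        kind,
        width_mm=width,
        total_volume_cc=volume,
    )
    return MeasurementRecord(
        lesion_id=lesion_id,
        device_name=device_name,
        volume_cc=volume,
        sdh_width_mm=width,
        midline_shift_mm=shift,
        marshall=score,
        cnr=cnr(stack, roi),
        severity=severity,
    )
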