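# Methods

## The phantom model

Each phantom is a stack of axial slices on an 8-bit *display* scale, not
calibrated Hounsfield units: the pipeline's inputs are window/leveled PACS
renderings, so only displayed intensities are meaningful. Fixed levels:
brain ≈ 80, acute blood ≈ 160, skull 255, midline structure 20, on [0, 255].

Geometry. The default acquisition is 512×512 px at 0.45 mm/px with 5 mm
slices (28 of them); the study orchestrator uses a field-of-view-equivalent
reduced grid of 256×256 px at 0.9 mm/px with 20 slices, which keeps a full
8-lesion × 10-capture study to a couple of minutes on one CPU while leaving
every lesion several pixels across. Slices sample the volume at their
center plane. The skull is an elliptical annulus (outer semi-axes 75×92 mm,
6 mm thick); the brain is its uniform interior.

Lesions. Parenchymal contusions are axis-aligned ellipsoids. Subdural
collections are crescents bounded by two equal-radius circles whose centers
are offset by the maximal width d: the gap tapers as d·cosφ away from the
apex and closes at the cusps, which reproduces the characteristic
crescent-on-CT appearance with an analytically known maximal width, cusp
chord 2√(R²−d²/4), and area ≈ 2Rd per slice. The generative ABC dimensions
of each lesion are therefore exact, and every phantom ships a ground-truth
sidecar with both the voxel-count volume and the generative ABC/2 volume.

Midline. A 2 px dark line (a ventricle surrogate) through the central 60%
of the brain's height, displaced laterally by the configured shift while
the skull stays fixed. The landmark for shift is thus unambiguous: distance
between the line and the skull rim's symmetry axis.

Scalebar. A 100 mm bar with 10 mm ticks burned near the lower-right corner
of every slice at display maximum. It undergoes the same degradation as the
anatomy, so downstream calibration must re-derive mm/px from the image.

Noise. Additive Gaussian noise (default SD 6 display units), drawn
independently per voxel. Independence across slices matters: it is what
distinguishes two adjacent slices of homogeneous anatomy in the
deduplication step, exactly as real CT noise does.

Lesion menu. Eight index configurations span the severity design: three
isolated subdural crescents with maximal widths 4.0 / 7.7 / 12.4 mm
(bins [0,5), [5,10), [10,∞) mm), two parenchymal contusions with ABC/2
volumes 7.5 / 20.2 cc (bins [1,10), [10,30) cc), and three subdural +
parenchymal combinations totalling 3.2 / 13.1 / 37.6 cc, the last with an
8 mm midline shift and effaced cisterns (Marshall-6-eligible). Severity
bins are half-open; volumes below the 1 cc selection floor are still graded
mild. Two deliberate alignment choices make the vertical extent C exactly
recoverable on the default geometries: lesion z-centers sit on the boundary
between the two central slices, and z-extents are even multiples of the
slice thickness. Multi-compartment entries keep >2 mm between compartments
so they remain separable after blur.

## The capture chain

A capture renders each slice for `dwell_s` seconds (default 0.5 s — an
unhurried manual scroll) at `fps` frames/s (default 30, the rate the real
videos were decoded at). Each frame passes through: spatial resample →
Gaussian blur → affine luminance (gain/offset, clipped) → intensity
quantization → additive sensor noise. Compression is emulated by
quantization + blur rather than a real codec so the measurement claims are
codec-independent; actual mp4/avi encoding is an optional I/O layer that
raises an explicit error directing to the lossless frames-dir container
when no encoder is installed. A per-capture multiplicative gain jitter
(drawn once per recording) emulates auto-exposure settling differently
each time.

One subtlety worth knowing: Gaussian blur applied to noise already *in*
the image acts as a denoiser and can raise the downstream CNR even as it
erodes edges. Monotone "more blur, worse CNR" behaviour holds when the
dominant noise enters at the sensor stage, after blur — which is how the
property is tested.

The default ladder is a PACS-identity reference plus five degraded
profiles. The phones' true optics were never characterized, so the ladder
is an assumption, ordered from nearly transparent to soft and noisy.
Capture scales stay in [0.9, 1.25]: a phone filming a PACS viewport
typically *oversamples* it (1080p+ video of a ~512 px image region), and at
scales much below 0.9 the thinnest 3 mm crescent falls under the blur
kernel's width, where no estimator can recover its thickness (a boxcar
narrower than the blur is indistinguishable from a scaled delta).

## Reconstruction

Frames are read from memory, a frames directory, or a video container, and
resampled to the requested rate by nearest timestamp (variable-rate
containers therefore work). Dwell runs — consecutive frames showing the
same slice — are found by thresholding consecutive mean absolute frame
differences. The threshold, when not given, is placed a robust margin
(6 robust SDs, at least 25%) above the median difference: with at least two
frames per dwell run the within-run differences are the majority, tightly
clustered at the sensor-noise level, while between-slice differences sit
higher (blurred phantom noise plus anatomy change) and vary too much for a
variance-based two-cluster split to be reliable. Each run is replaced by
its pixelwise median, which suppresses sensor noise for free. The approach
assumes each slice is on screen for ≥ 2 frames — true of any screen
recording scrolled by hand at 30 fps.

Calibration finds the scalebar as the outermost bright structure on its
edge of the frame (it lies in the margin, outside the skull), then measures
its length between half-maximum crossings of a thin strip's column-maximum
profile, with sub-pixel linear interpolation. Half-maximum extent is
invariant to symmetric blur and to affine luminance changes; across the
default ladder the recovered scale is within 0.5% of truth, and the 2%
contract is property-tested for capture scales in [0.5, 1.5].

## Measurement operators

ROI provenance: the raters of the original workflow measured by hand;
automated segmentation is out of scope. The pipeline therefore measures
ground-truth masks projected through the capture transform
(nearest-neighbour resample to the captured frame grid), plus a
threshold-based fallback (`roi_by_threshold`) for demos. All mm conversions
use the scalebar-derived calibration.

ABC/2. A is the caliper diameter (exact maximum over boundary-pixel pairs,
O(n²) — masks are small enough that brute force is unambiguous) on the
slice of maximal lesion area; B is the longest *in-mask* chord
perpendicular to A on that slice — for concave crescents a boundary-pair
distance would measure the arc's sag, not the collection's width; C counts
lesion-bearing slices × thickness. In-plane lengths get +1 px for the
physical extent of boundary pixels. For subdural compartments the B used
in the volume product is the maximal thickness (below), matching how the
bedside rule is applied to crescents.

SDH width. The mask's distance-transform maximum locates the widest point;
the width itself is read off the intensity image: line profiles through
that point over a fan of orientations, the band's normal taken from a local
PCA of the mask (window scaled to straddle the band), and the shortest
profile width refined by fitting a blurred-boxcar model (two erf edges with
free width, blur, amplitude, center, baseline). The erf fit removes the
upward FWHM bias of narrow blurred bands; the median over seven positions
along the band's ridge removes the pixel-phase selection bias of the
distance-transform maximum (which preferentially lands where rasterization
painted the band widest). Widths that collapse to ~1 px are flagged
low-confidence rather than silently zeroed.

Midline shift. The skull rim (largest bright connected component) gives the
symmetry axis; the measured midline is the intensity-weighted centroid of
the darkest in-brain column dip, per slice, with the maximum displacement
across slices reported. Sub-pixel centroiding keeps the error well under a
pixel; the max-over-slices convention adds a small positive bias (≈1 px at
the default noise level) that stays within the 2 px-equivalent contract.

CNR. |mean lesion SI − mean surround SI| / SD(surround SI), pooled over
slices where both masks are nonempty. The noise SD is taken over the
surround annulus (2–8 px around the lesion, brain tissue only, midline
structure excluded) — the only defined noise-bearing region. Zero surround
variance raises an error rather than returning ∞. Affine luminance
invariance is exact and property-tested.

Marshall. The rubric lists six categories without a tie-break; this
implementation applies mass-size rules first (>25 cc: 5 if evacuated else
6), then shift > 5 mm (4), then effaced cisterns (3), then visible
pathology (2), else 1. The order is oracle-tested against exhaustive
enumeration. Cistern and evacuation status are not measurable on the
phantom images and pass through from ground truth.

## Agreement statistics

ICC(1), one-way random effects: (MSB − MSW)/(MSB + (k−1)·MSW), subjects =
lesions, methods = PACS + capture slots. The 95% CI inverts the exact F
distribution of MSB/MSW with (n−1, n(k−1)) df — the standard interval for
this model. Friedman uses within-subject mid-ranks with the standard tie
correction; fully tied tables report χ² = 0, p = 1. An exact permutation
p-value is available for n·k ≤ 12 and is enumeration-tested. Kendall's
W = χ²/(n(k−1)), clipped to [0, 1].

Bland–Altman runs for the three quantitative measures (volume, SDH width,
midline shift) against the PACS column. The critical differences are fixed
a-priori config values — volume 5 cc, width 2 mm, shift 2 mm — chosen from
the measurement resolution of the default geometry (≈1 px in-plane ≈ 1 mm;
one slice = 5 mm never enters because C is alignment-exact). A
replicate-based derivation was considered and rejected: with ground-truth
ROIs the mask-based measures are deterministic under an identity capture,
so replicate differences have zero SD and define no scale. Marshall
(ordinal) and CNR (quality index with systematic device effects) are
compared by ICC/Friedman only.

Presentation randomization assigns each id a uniform [0,1) draw and sorts
ascending — the same scheme used for the human raters — and is
uniformity-tested over 10,000 seeds.

## What the synthetic study does and does not show

The generator reproduces the *design* of the original experiment (8 index
severities, 10 captures each, a multi-device ladder) with known truth, so
passing tests demonstrate that the measurement operators and statistics are
correct and that the capture chain, as modelled, preserves the clinically
relevant quantities. They do not certify performance on real data: the
phantoms lack gyri, ventricles beyond the midline surrogate, mixed-density
hematomas, beam hardening and dose effects; capture omits perspective,
rolling shutter, moiré and hand shake; and ROIs come from ground truth, not
human tracing, so rater variability is outside the model. Printed agreement
values from the original rater study (ICCs near 0.97–0.998 measured on
real patient scans) are not reproduction targets — the raw rating data were
never published — but the synthetic study lands in the same qualitative
regime: ICC > 0.99 for volume, shift and Marshall, all Bland–Altman
differences within the critical bands, and a significant device effect on
CNR, which is also what the original analysis found.

A known resolution floor: at the reduced study grid the 4 mm crescent is a
~4.4 px band; under the softest device profile (blur 1.1 px, quantization
step 6) its width — and therefore its ABC/2 volume, which is proportional
to it — carries an intrinsic uncertainty of roughly ±10%, because
quantization truncates the blurred band's faint skirt before the erf fit
sees it. Individual captures of the mildest subdural lesion can graze the
10% volume envelope at this geometry; the finer 0.45 mm default geometry
doubles the band's pixel width and removes the marginality at the cost of
~4× runtime.

## Numerical choices and degenerate inputs

- Identity parameters short-circuit each capture stage, so an identity
  profile is bit-exact.
- Deduplication with an all-zero difference sequence merges everything
  (one slice); a capture with one frame per slice is outside the
  documented ≥2-frames-per-run assumption.
- `calibrate_scale` raises (confidence never silently defaulted) when the
  corner holds no structure at ≥20 display units of contrast or the
  candidate run is shorter than 4 px.
- The erf band fit is rejected (fallback: half-maximum width, then the
  binary 2·EDT−1 px estimate) when optimization fails or moves more than
  50% from its initialization.
- ICC with MSW = 0 but subject variance present returns exactly 1.0 with a
  degenerate CI; zero total variance raises.
- Seeds: every stochastic stage derives from `numpy.random.SeedSequence`
  spawns of one root seed; identical configs byte-reproduce all CSV/JSON
  outputs.

## Problem sizes

Defaults were chosen so the complete test suite and the acceptance script
each run in minutes on a single CPU: the study grid is 256×256×20 voxels,
captures are 15 frames per slice (0.5 s dwell at 30 fps), the fine-grid
ellipsoid checks use 300×300×60 at 0.5 mm/px, and the ICC recovery study
uses 500 replicates of a 50×6 table.
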