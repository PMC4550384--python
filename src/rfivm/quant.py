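"""Mask-based quantification of tracer extravasation in IVM time-lapses.

The pipeline follows the global-threshold / binary-mask recipe used for
intravital recordings of tumor perfusion:

1. threshold the constitutive tumor channel to get a tumor mask, then
   dilate/erode to fill holes and smooth edges;
2. threshold the high-intensity tracer signal on a baseline frame (when
   tracer is still purely intravascular) to get a vasculature mask, with
   the same cleanup;
3. combine them — tumor AND NOT vessels — into the extravascular tumor
   region over which tracer migration is quantified.

Derived statistics:

* **PAF** (positive area fraction): fraction of pixels above a
  background threshold — used on end-point images or stained sections.
* **RTDI** (relative tumor dye intensity): region-mean tracer intensity
  per frame, normalised to a baseline window (baseline == 1).
* **RAIF** (relative increase in fluorescence): end-window over
  start-window region-mean ratio, aggregated as mean +/- SD over
  replicate stacks.

Thresholds default to Otsu computed once on the baseline frame and held
fixed across the time-lapse, so temporal trends are not confounded by
per-frame adaptive thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .stack import BinaryMask, ImageStack, ShapeError


class EmptyRegionError(ValueError):
    """Raised when a statistic is requested over an empty mask."""


class DegenerateImageWarning(UserWarning):
    """Emitted when Otsu is asked to threshold a constant image."""


def global_threshold(
    img: np.ndarray, method: str = "otsu", fixed_value: float | None = None
) -> float:
    """Global segmentation threshold for a single-channel image.

    ``method="otsu"`` maximises the between-class variance over the
    intensity histogram; the returned cutoff is then centred between the
    two classes (the highest below-class value and the lowest above-class
    value), which leaves the partition unchanged but places the threshold
    at maximal margin — well-separated two-level images get a cutoff
    strictly between the levels rather than at the lower level's edge.
    ``method="fixed"`` echoes ``fixed_value``.  A constant image has no
    Otsu threshold — the constant itself is returned with a warning
    (documented fallback).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("image is empty")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed_value required for method='fixed'")
        return float(fixed_value)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(img) == 0:
        warnings.warn(
            "constant image: Otsu threshold undefined, returning the constant",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return float(img.flat[0])
    t0 = threshold_otsu(img)
    above = img[img > t0]
    if above.size == 0:
        return float(t0)
    return (float(img[img <= t0].max()) + float(above.min())) / 2.0


def _threshold_and_clean(
    img: np.ndarray,
    source_channel: str,
    method: str,
    fixed_value: float | None,
    dilate_r: int,
    erode_r: int | None,
) -> BinaryMask:
    thr = global_threshold(img, method=method, fixed_value=fixed_value)
    pixels = img > thr
    trace = [f"threshold({method}={thr:.6g})"]
    if erode_r is None:
        erode_r = dilate_r
    if dilate_r > 0:
        pixels = ndimage.binary_dilation(pixels, structure=disk(dilate_r))
        trace.append(f"dilate(disk r={dilate_r})")
    if erode_r > 0:
        # border_value=1 so regions touching the frame edge are not eaten
        # from outside the field of view.
        pixels = ndimage.binary_erosion(pixels, structure=disk(erode_r),
                                        border_value=1)
        trace.append(f"erode(disk r={erode_r})")
    return BinaryMask(pixels=pixels, source_channel=source_channel,
                      threshold_value=thr, morphology_trace=trace)


def tumor_mask(
    stack: ImageStack,
    frame_idx: int = 0,
    dilate_r: int = 2,
    erode_r: int | None = None,
    channel: str = "tumor",
    method: str = "otsu",
    fixed_value: float | None = None,
) -> BinaryMask:
    """Tumor region from the constitutive-fluorophore channel.

    Threshold, then dilate followed by erode (a morphological closing
    with a disc element, radii equal by default) to fill holes smaller
    than the element and smooth the boundary.
    """
    img = stack.frame(frame_idx, channel)
    return _threshold_and_clean(img, channel, method, fixed_value,
                                dilate_r, erode_r)


def vessel_mask(
    stack: ImageStack,
    tracer_channel: str = "albumin",
    frame_idx: int = 0,
    dilate_r: int = 2,
    erode_r: int | None = None,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> BinaryMask:
    """Vasculature from high-intensity tracer signal on a baseline frame.

    The default baseline frame is the first one: at injection time the
    tracer is purely intravascular, so Otsu cleanly separates vessels
    from background before extravasation elevates the tissue signal.
    """
    img = stack.frame(frame_idx, tracer_channel)
    return _threshold_and_clean(img, tracer_channel, method, fixed_value,
                                dilate_r, erode_r)


def extravascular_mask(tumor: BinaryMask, vessels: BinaryMask) -> BinaryMask:
    """Extravascular tumor component: tumor AND NOT vessels.

    Exact set arithmetic — together with ``tumor AND vessels`` it
    partitions the tumor mask pixel-for-pixel.
    """
    if tumor.pixels.shape != vessels.pixels.shape:
        raise ShapeError(
            f"mask shapes differ: {tumor.pixels.shape} vs {vessels.pixels.shape}"
        )
    return BinaryMask(
        pixels=tumor.pixels & ~vessels.pixels,
        source_channel=f"{tumor.source_channel}&~{vessels.source_channel}",
        morphology_trace=["combine(tumor & ~vessels)"],
    )


def _region_mean(img: np.ndarray, region: np.ndarray) -> float:
    """Mean intensity over a region, excluding saturated pixels (dtype
    max for integer images)."""
    vals = img[region]
    if np.issubdtype(img.dtype, np.integer):
        vals = vals[vals < np.iinfo(img.dtype).max]
    if vals.size == 0:
        raise EmptyRegionError("region contains no usable pixels")
    return float(vals.mean())


def rtdi_series(
    stack: ImageStack,
    region: BinaryMask,
    tracer_channel: str = "albumin",
    baseline_frames: tuple[int, ...] | slice = (0,),
) -> np.ndarray:
    """Relative tumor dye intensity: region-mean per frame / baseline mean.

    The baseline window mean defines 1.0; by construction the series
    averaged over the baseline frames is exactly 1.
    """
    if region.area == 0:
        raise EmptyRegionError("RTDI region is empty")
    frames = stack.channel(tracer_channel)
    means = np.array([_region_mean(f, region.pixels) for f in frames])
    if isinstance(baseline_frames, slice):
        base = means[baseline_frames]
    else:
        base = means[list(baseline_frames)]
    if base.size == 0:
        raise ValueError("baseline_frames is empty")
    return means / base.mean()


def paf(img: np.ndarray, background_threshold: float) -> float:
    """Positive area fraction: share of pixels strictly above threshold."""
    img = np.asarray(img)
    return float(np.count_nonzero(img > background_threshold) / img.size)


def raif(
    stack: ImageStack,
    region: BinaryMask,
    tracer_channel: str = "albumin",
    window_start: slice | None = None,
    window_end: slice | None = None,
) -> float:
    """Relative increase in fluorescence over an exposure window.

    Region-mean tracer intensity averaged over the end window divided by
    the start-window average.  Windows default to the first and last 10%
    of frames (at least one frame each) and must not overlap.
    """
    if region.area == 0:
        raise EmptyRegionError("RAIF region is empty")
    n = stack.n_frames
    tenth = max(1, n // 10)
    if window_start is None:
        window_start = slice(0, tenth)
    if window_end is None:
        window_end = slice(n - tenth, n)
    idx = np.arange(n)
    i_start, i_end = idx[window_start], idx[window_end]
    if i_start.size == 0 or i_end.size == 0:
        raise ValueError("RAIF windows must be nonempty")
    if i_end.min() <= i_start.max():
        raise ValueError("RAIF end window must come after the start window")
    frames = stack.channel(tracer_channel)
    start = np.mean([_region_mean(frames[i], region.pixels) for i in i_start])
    end = np.mean([_region_mean(frames[i], region.pixels) for i in i_end])
    return float(end / start)


def aggregate_raif(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Replicate summary (mean, SD) of RAIF values across stacks."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("replicate aggregation needs n >= 2 stacks")
    return float(values.mean()), float(values.std(ddof=1))


@dataclass
class JitterCorrection:
    """Registered stack plus the per-frame (row, col) shifts applied."""

    stack: ImageStack
    shifts_px: np.ndarray


def jitter_correct(
    stack: ImageStack,
    reference_frame: int = 0,
    channel: str | None = None,
    upsample_factor: int = 20,
) -> JitterCorrection:
    """Remove rigid respiration jitter by translation registration.

    Each frame's shift relative to the reference frame is estimated by
    subpixel phase cross-correlation on one registration channel (the
    static tumor channel when present) and undone on every channel.
    Featureless (constant) registration frames trigger a low-confidence
    warning and an identity transform.
    """
    if stack.n_frames < 2:
        raise ValueError("jitter correction needs >= 2 frames")
    if channel is None:
        channel = "tumor" if "tumor" in stack.channel_roles else stack.channel_roles[0]
    reg = stack.channel(channel)
    ref = reg[reference_frame]
    corrected = stack.frames.copy()
    shifts = np.zeros((stack.n_frames, 2))
    ref_flat = np.ptp(ref) == 0
    for i in range(stack.n_frames):
        if i == reference_frame:
            continue
        if ref_flat or np.ptp(reg[i]) == 0:
            warnings.warn(
                f"frame {i}: featureless registration channel, "
                "applying identity transform",
                UserWarning,
                stacklevel=2,
            )
            continue
        shift, _, _ = phase_cross_correlation(
            ref, reg[i], upsample_factor=upsample_factor
        )
        shifts[i] = shift
        for c in range(stack.frames.shape[1]):
            corrected[i, c] = ndimage.shift(
                stack.frames[i, c].astype(float), shift, order=1, mode="nearest"
            )
    corrected = np.clip(corrected, 0.0, None).astype(stack.frames.dtype)
    out = ImageStack(frames=corrected, channel_roles=stack.channel_roles,
                     timestamps_s=stack.timestamps_s.copy())
    return JitterCorrection(stack=out, shifts_px=shifts)


@dataclass
class PerfusionReport:
    """Summary of one quantified time-lapse (plus optional replicates)."""

    paf_endpoint: float
    rtdi: np.ndarray
    raif: float
    times_s: np.ndarray
    tracer_channel: str
    raif_replicates: tuple[float, ...] = ()
    raif_mean: float | None = None
    raif_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.paf_endpoint <= 1.0:
            raise ValueError("PAF must lie in [0, 1]")


def quantify_stack(
    stack: ImageStack,
    tracer_channel: str = "albumin",
    paf_threshold: float | None = None,
    baseline_frames: tuple[int, ...] = (0, 1, 2),
    dilate_r: int = 2,
) -> PerfusionReport:
    """Run the full mask pipeline on one stack and report PAF/RTDI/RAIF.

    ``paf_threshold`` defaults to the baseline tracer background level
    plus three-ish noise SDs, estimated robustly from the first frame's
    sub-vessel-threshold pixels, and is meant to be shared across the
    stacks of a comparison.
    """
    baseline_frames = tuple(i for i in baseline_frames if i < stack.n_frames) or (0,)
    t_mask = tumor_mask(stack, dilate_r=dilate_r)
    v_mask = vessel_mask(stack, tracer_channel=tracer_channel, dilate_r=dilate_r)
    region = extravascular_mask(t_mask, v_mask)
    if paf_threshold is None:
        paf_threshold = default_paf_threshold(stack, tracer_channel)
    series = rtdi_series(stack, region, tracer_channel, baseline_frames)
    return PerfusionReport(
        paf_endpoint=paf(stack.frame(-1, tracer_channel), paf_threshold),
        rtdi=series,
        raif=raif(stack, region, tracer_channel),
        times_s=stack.timestamps_s.copy(),
        tracer_channel=tracer_channel,
    )


def default_paf_threshold(
    stack: ImageStack, tracer_channel: str = "albumin", n_sigma: float = 4.0
) -> float:
    """Background threshold for PAF from the baseline tracer frame.

    Pixels below the baseline Otsu vessel cutoff are background; the
    threshold is their median plus ``n_sigma`` robust SDs (MAD-based),
    i.e. just above the background noise floor.  Compute it once per
    comparison and reuse across conditions.
    """
    img = stack.frame(0, tracer_channel)
    cut = global_threshold(img)
    bg = img[img <= cut]
    if bg.size == 0:
        return float(cut)
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + n_sigma * 1.4826 * mad
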