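"""Cell segmentation and competition-fraction quantification.

Re-implements the classic live-cell counting recipe for phase-contrast
micrographs: a spatial bandpass filter to flatten illumination and suppress
pixel noise, an automatic histogram threshold to separate cells from
background, and a marker-controlled watershed on the Euclidean distance
transform to split touching cells.  Objects are then counted, sized, and —
when a red-fluorescence channel is present — classified as labeled or
unlabeled so that the labeled fraction of a co-culture (competition assay)
can be tracked over time.

The bright-objects-on-dark-background convention is used throughout; pass
``invert=True`` where the dialect is reversed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import DegenerateImageError, ParameterError

__all__ = [
    "ImageFrame",
    "SegmentationConfig",
    "SegmentationResult",
    "CompetitionTrace",
    "bandpass_filter",
    "auto_threshold",
    "watershed_split",
    "measure_objects",
    "segment_frame",
    "estimate_confluency",
    "compute_competition_trace",
]


@dataclass(frozen=True)
class ImageFrame:
    """One timestamped 2-D grayscale image.

    Parameters
    ----------
    pixels : 2-D float array of intensities.
    channel : "phase" or "red".
    time_h : acquisition time in hours (>= 0).
    well : well identifier, free-form.
    pixel_size_um : physical pixel edge length in micrometres, if known.
    """

    pixels: np.ndarray
    channel: str = "phase"
    time_h: float = 0.0
    well: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("pixel grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixel intensities must be finite")
        if self.time_h < 0:
            raise ParameterError("time must be >= 0 hours")
        if self.channel not in ("phase", "red"):
            raise ParameterError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the bandpass → threshold → watershed → measure chain.

    ``small_cutoff``/``large_cutoff`` are the structure sizes (pixels)
    passed to the difference-of-Gaussians bandpass; ``h`` is the h-maxima
    suppression depth (pixels of distance-transform height) used to seed
    the watershed; objects outside ``[min_area, max_area]`` (pixels) are
    discarded; an object is called labeled when its mean red intensity
    exceeds ``red_threshold_factor`` times the median red background.
    """

    small_cutoff: float = 2.0
    large_cutoff: float = 64.0
    threshold_method: str = "otsu"  # or "isodata"
    invert: bool = False
    h: float = 0.5
    min_area: int = 30
    max_area: int = 5000
    red_threshold_factor: float = 2.0


def bandpass_filter(
    frame: ImageFrame, small_cutoff: float, large_cutoff: float
) -> ImageFrame:
    """Suppress structures smaller than ``small_cutoff`` and larger than
    ``large_cutoff`` pixels.

    Implemented as a difference of two Gaussian blurs with sigmas of half
    the respective cutoff.  The zero-mean result is re-offset so the
    minimum is 0.
    """
    if not (0 < small_cutoff < large_cutoff):
        raise ParameterError("need 0 < small_cutoff < large_cutoff")
    if large_cutoff >= min(frame.shape):
        raise ParameterError("large_cutoff must be smaller than the image")
    img = frame.pixels
    lo = ndi.gaussian_filter(img, sigma=small_cutoff / 2.0, mode="reflect")
    hi = ndi.gaussian_filter(img, sigma=large_cutoff / 2.0, mode="reflect")
    out = lo - hi
    out -= out.min()
    return replace(frame, pixels=out)


def auto_threshold(
    frame: ImageFrame, method: str = "otsu", invert: bool = False
) -> tuple[np.ndarray, float]:
    """Binary foreground mask by automatic histogram thresholding.

    Uses Otsu's between-class-variance criterion on a 256-bin histogram
    (or the IsoData iterative intermeans variant).  Returns ``(mask,
    threshold)``; with ``invert`` the dark side of the threshold becomes
    foreground.
    """
    img = frame.pixels
    if np.ptp(img) == 0:
        raise DegenerateImageError("constant image has no threshold")
    if method == "otsu":
        thr = float(threshold_otsu(img, nbins=256))
    elif method == "isodata":
        thr = float(threshold_isodata(img, nbins=256))
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    mask = img < thr if invert else img > thr
    return mask, thr


def watershed_split(
    mask: np.ndarray, h: float = 0.5, smooth_sigma: float = 0.5
) -> np.ndarray:
    """Split touching objects in a binary mask along watershed lines.

    The negated Euclidean distance transform is flooded from markers
    placed at its h-maxima (maxima whose height above the surrounding
    plateau is at least ``h`` pixels).  The distance map is first smoothed
    with a ``smooth_sigma``-pixel Gaussian so pixelation plateaus of a
    single convex object do not seed twice.  Components too shallow to
    hold a marker fall back to their connected-component label, so every
    input component keeps at least one label and every output label is a
    connected subset of exactly one input component.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    if smooth_sigma > 0:
        dist = ndi.gaussian_filter(dist, smooth_sigma)
    peaks = h_maxima(dist, h)
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    labels = watershed(-dist, markers=markers, mask=mask).astype(np.int32)
    # rescue components whose distance peak was below h
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan, structure=np.ones((3, 3), dtype=int))
        labels[orphan] = extra[orphan] + labels.max()
    return labels


def _relabel_consecutive(labels: np.ndarray, keep: Iterable[int]) -> np.ndarray:
    keep = sorted(keep)
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return out


@dataclass
class SegmentationResult:
    """Label mask plus per-object measurements and the applied parameters.

    ``objects`` has one row per retained object: id, centroid_row,
    centroid_col, area_px, mean_phase, mean_red, is_labeled (mean_red and
    is_labeled are NaN/absent when no red channel was supplied).
    """

    label_mask: np.ndarray
    objects: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.objects)

    @property
    def labeled_count(self) -> int:
        if "is_labeled" not in self.objects:
            return 0
        return int(self.objects["is_labeled"].sum())


def measure_objects(
    labels: np.ndarray,
    phase: ImageFrame,
    red: ImageFrame | None = None,
    min_area: int = 30,
    max_area: int = 5000,
    red_threshold_factor: float = 2.0,
    params: dict | None = None,
) -> SegmentationResult:
    """Count and size labeled objects; classify red-labeled cells.

    Objects with area outside ``[min_area, max_area]`` are discarded and
    the mask relabeled with consecutive ids.  The red background level is
    the median red intensity over background (label 0) pixels; an object
    is flagged labeled when its mean red intensity exceeds
    ``red_threshold_factor`` times that level.
    """
    labels = np.asarray(labels)
    if labels.shape != phase.shape:
        raise ParameterError("label mask and phase frame differ in shape")
    if red is not None and red.shape != phase.shape:
        raise ParameterError("red frame differs in shape")

    props = regionprops(labels, intensity_image=phase.pixels)
    kept = [p for p in props if min_area <= p.area <= max_area]
    new_labels = _relabel_consecutive(labels, [p.label for p in kept])

    rows = []
    red_bg = np.nan
    if red is not None:
        bg_pixels = red.pixels[labels == 0]
        red_bg = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    for new_id, p in enumerate(sorted(kept, key=lambda q: q.label), start=1):
        row = {
            "id": new_id,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "area_px": int(p.area),
            "mean_phase": float(p.intensity_mean),
        }
        if red is not None:
            mean_red = float(red.pixels[labels == p.label].mean())
            row["mean_red"] = mean_red
            row["is_labeled"] = bool(
                mean_red > red_threshold_factor * max(red_bg, 1e-12)
            )
        rows.append(row)
    cols = ["id", "centroid_row", "centroid_col", "area_px", "mean_phase"]
    if red is not None:
        cols += ["mean_red", "is_labeled"]
    objects = pd.DataFrame(rows, columns=cols)
    info = dict(params or {})
    info.update(
        min_area=min_area,
        max_area=max_area,
        red_threshold_factor=red_threshold_factor,
        red_background=red_bg,
    )
    return SegmentationResult(label_mask=new_labels, objects=objects, params=info)


def segment_frame(
    phase: ImageFrame,
    red: ImageFrame | None = None,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Full chain: bandpass → auto-threshold → watershed → measure."""
    cfg = config or SegmentationConfig()
    filtered = bandpass_filter(phase, cfg.small_cutoff, cfg.large_cutoff)
    mask, thr = auto_threshold(filtered, method=cfg.threshold_method, invert=cfg.invert)
    labels = watershed_split(mask, h=cfg.h)
    return measure_objects(
        labels,
        phase,
        red,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        red_threshold_factor=cfg.red_threshold_factor,
        params={
            "small_cutoff": cfg.small_cutoff,
            "large_cutoff": cfg.large_cutoff,
            "threshold_method": cfg.threshold_method,
            "threshold_value": thr,
            "h": cfg.h,
        },
    )


def estimate_confluency(
    frames: ImageFrame | Sequence[ImageFrame],
    small_cutoff: float = 2.0,
    large_cutoff: float | None = None,
    contrast_gate: float = 4.0,
) -> float:
    """Percent of image area covered by cells.

    Confluency = 100 × foreground pixels / total pixels, with foreground
    from the bandpass + automatic-threshold chain.  By default the
    high-pass side of the bandpass is taken in its infinite-cutoff limit
    (subtracting the global mean rather than a large-scale blur), so a
    confluent sheet covering most of the well is not suppressed as
    "background structure"; pass an explicit ``large_cutoff`` to restore
    the finite high-pass.  Several frames from one well/timepoint are
    averaged.

    An automatic threshold always bisects a histogram, so a field with no
    cells must be recognised explicitly: when the foreground/background
    mean separation is below ``contrast_gate`` × the pooled within-class
    standard deviation the frame is treated as empty (0%, with a warning).
    """
    if isinstance(frames, ImageFrame):
        frames = [frames]
    vals = []
    for frame in frames:
        if np.ptp(frame.pixels) == 0:
            warnings.warn("constant frame: confluency reported as 0")
            vals.append(0.0)
            continue
        if large_cutoff is None:
            smoothed = ndi.gaussian_filter(
                frame.pixels, sigma=small_cutoff / 2.0, mode="reflect"
            )
            px = smoothed - smoothed.mean()
            filtered = replace(frame, pixels=px - px.min())
        else:
            filtered = bandpass_filter(frame, small_cutoff, large_cutoff)
        mask, _ = auto_threshold(filtered)
        fg = filtered.pixels[mask]
        bg = filtered.pixels[~mask]
        if fg.size == 0 or bg.size == 0:
            vals.append(0.0)
            continue
        pooled_sd = np.sqrt((fg.var() + bg.var()) / 2.0)
        if pooled_sd > 0 and (fg.mean() - bg.mean()) < contrast_gate * pooled_sd:
            warnings.warn("no separable foreground: confluency reported as 0")
            vals.append(0.0)
            continue
        vals.append(100.0 * mask.mean())
    return float(np.mean(vals))


@dataclass
class CompetitionTrace:
    """Labeled-fraction trajectory of a co-culture competition assay."""

    times_h: np.ndarray
    labeled: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        self.times_h = t
        self.labeled = np.asarray(self.labeled, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if np.any(self.labeled > self.total):
            raise ParameterError("labeled count exceeds total count")

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.total > 0, self.labeled / self.total, np.nan)
        return f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "labeled_count": self.labeled.astype(int),
                "total_count": self.total.astype(int),
                "labeled_fraction": self.fraction,
            }
        )


def compute_competition_trace(
    series: Sequence[tuple[float, ImageFrame, ImageFrame]],
    config: SegmentationConfig | None = None,
) -> CompetitionTrace:
    """Segment every timepoint of a phase+red image series and return the
    labeled-over-total cell fraction per time.

    ``series`` is an iterable of ``(time_h, phase_frame, red_frame)``.
    Timepoints with zero detected objects get fraction NaN.
    """
    if len(series) == 0:
        raise ParameterError("need at least one timepoint")
    times, labeled, total = [], [], []
    for t, phase, red in sorted(series, key=lambda x: x[0]):
        if red is None:
            raise ParameterError("red channel required for competition trace")
        result = segment_frame(phase, red, config)
        times.append(t)
        labeled.append(result.labeled_count)
        total.append(result.count)
    return CompetitionTrace(
        times_h=np.array(times), labeled=np.array(labeled), total=np.array(total)
    )
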