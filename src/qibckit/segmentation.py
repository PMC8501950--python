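"""Nuclei segmentation: two-class Otsu thresholding plus watershed splitting.

The operator chain is ``binarize`` (Gaussian smoothing, Otsu, hole filling)
-> ``watershed_split`` (seeds from distance-transform maxima, watershed on
the negative distance transform) -> ``filter_labels`` (size bounds, border
exclusion, gap-free renumbering). Otsu uses a fixed 256-bin histogram for
either bit depth, with ties broken toward the lower threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import DegenerateHistogramError, ValidationError
from .images import ChannelImage, FieldOfView, LabelMask

OTSU_BINS = 256


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable cleanup around the fixed Otsu+watershed core.

    Defaults target ~20x-magnification nuclei (area 100..10000 px^2, seed
    separation 10 px); all are overridable.
    """

    smoothing_sigma: float = 1.0
    min_area: int = 100
    max_area: int = 10000
    min_seed_distance: int = 10
    fill_holes: bool = True
    clear_border: bool = True
    #: compute the Otsu split on log1p intensities (applied as an equivalent
    #: raw-intensity threshold); keeps dim large-G1 nuclei when background
    #: dominates the histogram
    log_transform: bool = True
    #: a two-class split calling more than this fraction of pixels foreground
    #: indicates thresholding failure on a nucleus-free image -> empty mask
    max_foreground_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (0 <= self.min_area <= self.max_area):
            raise ValidationError("require 0 <= min_area <= max_area")
        if self.smoothing_sigma < 0:
            raise ValidationError("smoothing_sigma must be >= 0")
        if self.min_seed_distance < 1:
            raise ValidationError("min_seed_distance must be >= 1")


def otsu_threshold(image: ChannelImage) -> float:
    """Between-class-variance-maximising threshold on a 256-bin histogram.

    Returns the centre of the optimal background/foreground boundary bin;
    the foreground is ``pixels > threshold``. Ties take the lowest
    threshold. Raises :class:`DegenerateHistogramError` on constant images.
    """
    pixels = np.asarray(image.pixels, dtype=np.float64).ravel()
    lo = pixels.min()
    hi = pixels.max()
    if lo == hi:
        raise DegenerateHistogramError(
            f"cannot threshold constant image (all pixels = {lo})"
        )
    hist, edges = np.histogram(pixels, bins=OTSU_BINS, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0

    # single pass over running (count, mass) prefixes in exact rational
    # arithmetic: near-tied splits are compared exactly, so the documented
    # "lowest threshold wins ties" rule is not at the mercy of float
    # summation order (256 bins make this cheap)
    total_weight = int(hist.sum())
    total_mass = sum(int(h) * Fraction(c) for h, c in zip(hist, centers))
    weight0 = 0
    mass0 = Fraction(0)
    best_k = 0
    best_score = Fraction(-1)
    # candidate k: background = bins 0..k, foreground = bins k+1..255
    for k in range(OTSU_BINS - 1):
        weight0 += int(hist[k])
        mass0 += int(hist[k]) * Fraction(centers[k])
        weight1 = total_weight - weight0
        if weight0 == 0 or weight1 == 0:
            continue
        mu0 = mass0 / weight0
        mu1 = (total_mass - mass0) / weight1
        score = Fraction(weight0 * weight1) * (mu0 - mu1) ** 2
        if score > best_score:  # strict: first maximiser = lowest threshold
            best_score = score
            best_k = k
    return float(centers[best_k])


def binarize(image: ChannelImage, params: SegmentationParams) -> np.ndarray:
    """Smooth, Otsu-threshold and (optionally) fill holes; returns a bool mask.

    With ``log_transform`` (default) the split is found on the log1p
    histogram. A split calling more than ``max_foreground_fraction`` of the
    image foreground is treated as thresholding failure (no nuclei present)
    and yields an empty mask with a warning.
    """
    pixels = np.asarray(image.pixels, dtype=np.float64)
    if params.smoothing_sigma > 0:
        pixels = ndi.gaussian_filter(pixels, sigma=params.smoothing_sigma)
    domain = np.log1p(pixels) if params.log_transform else pixels
    threshold = otsu_threshold(
        ChannelImage(domain, image.channel_name, image.bit_depth)
    )
    mask = domain > threshold
    if mask.mean() > params.max_foreground_fraction:
        warnings.warn(
            f"Otsu split calls {mask.mean():.0%} of pixels foreground "
            f"(> {params.max_foreground_fraction:.0%}); treating the image "
            "as nucleus-free",
            stacklevel=2,
        )
        return np.zeros(mask.shape, dtype=bool)
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    return mask


def watershed_split(binary: np.ndarray, params: SegmentationParams) -> LabelMask:
    """Split fused blobs by watershed on the negative distance transform.

    Seeds are distance-transform local maxima at least ``min_seed_distance``
    apart within each connected component; every non-empty component yields
    at least one label. An empty mask yields 0 objects.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return LabelMask(np.zeros(binary.shape, dtype=np.int32))

    distance = ndi.distance_transform_edt(binary)
    blobs, n_blobs = ndi.label(binary)
    markers = np.zeros(binary.shape, dtype=np.int32)
    next_marker = 1
    for blob_id, slc in enumerate(ndi.find_objects(blobs), start=1):
        if slc is None:
            continue
        region = blobs[slc] == blob_id
        local_distance = np.where(region, distance[slc], 0.0)
        peaks = peak_local_max(
            local_distance,
            min_distance=params.min_seed_distance,
            exclude_border=False,
            labels=region.astype(np.int32),
        )
        if len(peaks) == 0:  # tiny/flat blob: seed at its distance argmax
            peaks = np.array([np.unravel_index(np.argmax(local_distance), region.shape)])
        for pr, pc in peaks:
            markers[slc][pr, pc] = next_marker
            next_marker += 1

    segmented = watershed(-distance, markers=markers, mask=binary)
    return LabelMask.from_labels(segmented)


def filter_labels(mask: LabelMask, params: SegmentationParams) -> LabelMask:
    """Drop objects outside the area bounds and, optionally, border-touchers."""
    areas = mask.areas()
    keep = np.zeros(mask.n_objects + 1, dtype=bool)
    labels_idx = np.arange(mask.n_objects + 1)
    keep[1:] = (areas[1:] >= params.min_area) & (areas[1:] <= params.max_area)
    if params.clear_border and mask.n_objects:
        border = np.concatenate(
            [
                mask.labels[0, :],
                mask.labels[-1, :],
                mask.labels[:, 0],
                mask.labels[:, -1],
            ]
        )
        keep[np.unique(border)] = False
        keep[0] = False
    filtered = np.where(keep[mask.labels], mask.labels, 0)
    del labels_idx
    return LabelMask.from_labels(filtered)


def segment_nuclei(field: FieldOfView, params: SegmentationParams | None = None) -> LabelMask:
    """Full pipeline on the DAPI channel: binarize -> watershed -> filter."""
    params = params or SegmentationParams()
    binary = binarize(field.dapi, params)
    mask = watershed_split(binary, params)
    return filter_labels(mask, params)
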