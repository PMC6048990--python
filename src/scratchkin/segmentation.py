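"""Nuclei segmentation for fluorescence time-lapse frames.

Four stages, applied independently to every frame of a series:

1. illumination-function estimation — per-block minimum intensities,
   upsampled and Gaussian-smoothed, capture the slowly varying background;
2. background subtraction (clamped at zero);
3. object identification — global Otsu threshold, watershed declumping
   seeded from smoothed-intensity local maxima (nuclei are brighter toward
   their interior than toward their edges), then an equivalent-diameter
   band-pass filter;
4. per-object feature extraction (centroid, area, eccentricity, mean
   intensity).

Coordinates are 0-based with row 0 at the image top.  Objects touching the
image border are retained: for gap-infiltration counting, completeness of
the count outweighs shape fidelity of edge objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ObjectMap",
    "NucleusRecord",
    "compute_illumination_function",
    "subtract_background",
    "otsu_threshold",
    "identify_primary_objects",
    "extract_features",
    "segment_series",
]


@dataclass
class ObjectMap:
    """Labeled objects: 0 = background, labels 1..n_objects consecutive."""

    labels: np.ndarray
    n_objects: int


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus in one frame."""

    frame_index: int
    object_id: int
    centroid_row: float
    centroid_col: float
    area: int
    eccentricity: float
    mean_intensity: float


def compute_illumination_function(
    image: np.ndarray, block_size: int, sigma: float | None = None
) -> np.ndarray:
    """Estimate the smooth illumination background of one frame.

    The image is tiled into ``block_size`` x ``block_size`` blocks (partial
    blocks allowed at the bottom/right edges); each block contributes its
    minimum intensity, the block grid is upsampled back to full resolution
    by nearest neighbor and smoothed with a Gaussian of width ``sigma``
    (default: ``block_size`` pixels).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("illumination expects a 2-D image")
    if block_size < 2:
        raise ValidationError(f"block_size must be >= 2, got {block_size}")
    h, w = img.shape
    if block_size > h or block_size > w:
        raise ValidationError(
            f"block_size {block_size} exceeds image dimensions {h}x{w}"
        )
    if sigma is None:
        sigma = float(block_size)

    # pad with edge values to a block multiple; replicated pixels never
    # change a partial block's minimum
    ph = (-h) % block_size
    pw = (-w) % block_size
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    nh, nw = padded.shape[0] // block_size, padded.shape[1] // block_size
    mins = padded.reshape(nh, block_size, nw, block_size).min(axis=(1, 3))
    up = np.repeat(np.repeat(mins, block_size, axis=0), block_size, axis=1)
    up = up[:h, :w]
    return ndimage.gaussian_filter(up, sigma=sigma, mode="nearest")


def subtract_background(image: np.ndarray, illumination: np.ndarray) -> np.ndarray:
    """Subtract the illumination function, clamping at zero."""
    img = np.asarray(image, dtype=float)
    illum = np.asarray(illumination, dtype=float)
    if img.shape != illum.shape:
        raise ValidationError(
            f"shape mismatch: image {img.shape} vs illumination {illum.shape}"
        )
    return np.maximum(img - illum, 0.0)


def otsu_threshold(image: np.ndarray) -> float:
    """Global Otsu threshold over a 256-bin histogram of the observed range.

    Pixels strictly above the returned value are foreground.
    """
    img = np.asarray(image, dtype=float)
    if img.min() == img.max():
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(threshold_otsu(img, nbins=256))


def identify_primary_objects(corrected: np.ndarray, params) -> ObjectMap:
    """Segment nuclei in a background-corrected frame.

    Foreground is the global-Otsu mask.  Touching nuclei are declumped by a
    watershed on the inverted smoothed intensity, seeded at local maxima
    (smoothing sigma = min_diameter/2, minimum seed separation =
    min_diameter); a connected component that received no seed keeps its
    brightest pixel as seed so no foreground is dropped.  Components whose
    equivalent diameter 2*sqrt(area/pi) falls outside
    [min_diameter, max_diameter] (inclusive) are removed and the remaining
    labels renumbered consecutively.  A blank frame yields n_objects = 0.
    """
    img = np.asarray(corrected, dtype=float)
    if not (0 < params.min_diameter < params.max_diameter):
        raise ValidationError("require 0 < min_diameter < max_diameter")
    empty = ObjectMap(labels=np.zeros(img.shape, dtype=np.int32), n_objects=0)
    if img.min() == img.max():
        return empty
    mask = img > otsu_threshold(img)
    if not mask.any():
        return empty

    smoothed = gaussian(img, sigma=params.min_diameter / 2.0, preserve_range=True)
    peaks = peak_local_max(
        smoothed,
        min_distance=max(int(params.min_diameter), 1),
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)

    # every 4-connected foreground component must own at least one seed
    comps, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
    seeded = set(np.unique(comps[markers > 0])) - {0}
    next_id = len(peaks) + 1
    for c in range(1, n_comp + 1):
        if c not in seeded:
            flat = np.where(comps.ravel() == c)[0]
            best = flat[np.argmax(smoothed.ravel()[flat])]
            markers.ravel()[best] = next_id
            next_id += 1

    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=1)

    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    next_label = 1
    for region in regionprops(labels):
        eq_diam = 2.0 * np.sqrt(region.area / np.pi)
        if params.min_diameter <= eq_diam <= params.max_diameter:
            lut[region.label] = next_label
            next_label += 1
    return ObjectMap(labels=lut[labels], n_objects=next_label - 1)


def extract_features(
    objects: ObjectMap, corrected: np.ndarray, frame_index: int
) -> list[NucleusRecord]:
    """Measure centroid, area, eccentricity and mean intensity per object."""
    img = np.asarray(corrected, dtype=float)
    if objects.labels.shape != img.shape:
        raise ValidationError("label map and image shapes differ")
    records = []
    for region in regionprops(objects.labels, intensity_image=img):
        r, c = region.centroid
        records.append(
            NucleusRecord(
                frame_index=frame_index,
                object_id=int(region.label),
                centroid_row=float(r),
                centroid_col=float(c),
                area=int(region.area),
                eccentricity=float(region.eccentricity),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return records


def segment_frame(image: np.ndarray, params, frame_index: int = 0) -> list[NucleusRecord]:
    """Full single-frame pipeline: illumination -> subtraction -> objects
    -> features."""
    illum = compute_illumination_function(image, params.block_size)
    corrected = subtract_background(image, illum)
    objects = identify_primary_objects(corrected, params)
    return extract_features(objects, corrected, frame_index)


def segment_series(stack, params) -> list[list[NucleusRecord]]:
    """Segment every frame of an image series with identical parameters.

    Frames are processed independently; the result is deterministic given
    the inputs.  Frame-level errors are re-raised with the frame index
    attached.
    """
    per_frame: list[list[NucleusRecord]] = []
    for k in range(stack.n_frames):
        try:
            per_frame.append(segment_frame(stack.frames[k], params, frame_index=k))
        except (DegenerateInputError, ValidationError) as exc:
            raise type(exc)(f"frame {k}: {exc}") from exc
    return per_frame
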