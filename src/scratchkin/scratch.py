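"""Scratch-band detection and inside/outside cell enumeration.

The scratch is found once, from nucleus positions at the first timepoint:
centroid rows are histogrammed into fixed-height bins and the largest run
of empty bins is taken as the cell-free band (scratches are introduced
mid-well, so ties between equal runs go to the one nearest the vertical
image center).  Because a few cells may be left inside the scratched area,
nearby empty runs separated from the band only by sparse "straggler" bins
are absorbed iteratively, outward above and below, until no merge applies.
The band is then held fixed and every frame's nuclei are classified inside
or outside it by centroid row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import ScratchDetectionError, ValidationError

__all__ = [
    "ScratchBand",
    "InfiltrationSeries",
    "rotate_stack",
    "y_frequency",
    "detect_scratch_band",
    "count_in_out",
    "build_infiltration_series",
]


@dataclass
class ScratchBand:
    """Detected cell-free band, half-open in pixel rows [y_low, y_high)."""

    y_low: int
    y_high: int
    bin_height: int
    merged_gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def height(self) -> int:
        return self.y_high - self.y_low


@dataclass
class InfiltrationSeries:
    """Per-well counts of nuclei inside/outside the band over time."""

    well_id: str
    times: np.ndarray  # minutes, times[0] == 0, strictly increasing
    inside: np.ndarray  # integer counts
    outside: np.ndarray


def rotate_stack(stack, degrees_clockwise: float):
    """Rotate every frame clockwise so the scratch lies horizontal.

    Multiples of 90 degrees are pure pixel permutations (lossless); other
    angles use bilinear interpolation with zero fill, the output enlarged
    to contain the whole rotated frame.
    """
    from .plate_io import ImageStack  # local import: plate_io imports us not

    if not math.isfinite(degrees_clockwise):
        raise ValidationError("rotation must be finite")
    deg = float(degrees_clockwise) % 360.0
    if deg == 0.0:
        return ImageStack(frames=stack.frames.copy())
    if deg % 90.0 == 0.0:
        k = int(deg // 90)  # clockwise quarter turns
        frames = np.stack([np.rot90(f, k=-k) for f in stack.frames])
        return ImageStack(frames=frames)
    rotated = [
        _sk_rotate(
            f, -deg, resize=True, order=1, cval=0.0, preserve_range=True
        )
        for f in stack.frames
    ]
    return ImageStack(frames=np.stack(rotated))


def y_frequency(nuclei_t0, height: int, bin_height: int) -> np.ndarray:
    """Histogram of nucleus centroid rows in half-open ``bin_height`` bins.

    Bin b counts nuclei with floor(centroid_row / bin_height) == b; the
    last bin may be shorter than ``bin_height``.
    """
    if bin_height < 1:
        raise ValidationError("bin_height must be >= 1")
    n_bins = math.ceil(height / bin_height)
    counts = np.zeros(n_bins, dtype=np.int64)
    for nuc in nuclei_t0:
        b = int(nuc.centroid_row // bin_height)
        if 0 <= b < n_bins:
            counts[b] += 1
    return counts


def _zero_runs(hist: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of zero bins."""
    runs = []
    start = None
    for i, v in enumerate(hist):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(hist)))
    return runs


def detect_scratch_band(
    histogram: np.ndarray,
    bin_height: int,
    height: int,
    merge_span_bins: int = 6,
    straggler_max: int = 4,
) -> ScratchBand:
    """Locate the scratch band in a first-frame positional histogram.

    The main gap is the longest run of zero bins (ties: nearest the image
    center, then topmost).  A neighboring zero run is absorbed when it is
    separated from the current band by at most ``merge_span_bins`` bins
    each holding at most ``straggler_max`` cells; merging iterates outward
    above and below until stable.  ``merge_span_bins=0`` disables merging.
    """
    hist = np.asarray(histogram)
    if hist.size == 0:
        raise ValidationError("empty histogram")
    runs = _zero_runs(hist)
    if not runs:
        raise ScratchDetectionError("no cell-free area found")

    center = (height / bin_height) / 2.0
    best = min(
        runs,
        key=lambda r: (-(r[1] - r[0]), abs((r[0] + r[1]) / 2.0 - center), r[0]),
    )
    lo, hi = best
    merged: list[tuple[int, int]] = []

    def try_merge_below(lo: int) -> int | None:
        # scan upward (towards row 0) from the band's lower bin index
        span = 0
        i = lo - 1
        while i >= 0 and hist[i] != 0:
            if hist[i] > straggler_max or span >= merge_span_bins:
                return None
            span += 1
            i -= 1
        if i < 0 or span == 0:
            return None  # no zero run beyond the stragglers
        j = i
        while j >= 0 and hist[j] == 0:
            j -= 1
        merged.append((j + 1, i + 1))
        return j + 1

    def try_merge_above(hi: int) -> int | None:
        span = 0
        i = hi
        while i < hist.size and hist[i] != 0:
            if hist[i] > straggler_max or span >= merge_span_bins:
                return None
            span += 1
            i += 1
        if i >= hist.size or span == 0:
            return None
        j = i
        while j < hist.size and hist[j] == 0:
            j += 1
        merged.append((i, j))
        return j

    changed = True
    while changed:
        changed = False
        new_lo = try_merge_below(lo)
        if new_lo is not None:
            lo, changed = new_lo, True
        new_hi = try_merge_above(hi)
        if new_hi is not None:
            hi, changed = new_hi, True

    return ScratchBand(
        y_low=lo * bin_height,
        y_high=min(hi * bin_height, height),
        bin_height=bin_height,
        merged_gaps=[
            (a * bin_height, min(b * bin_height, height)) for a, b in merged
        ],
    )


def count_in_out(nuclei, band: ScratchBand) -> tuple[int, int]:
    """Count nuclei with centroid row in [y_low, y_high) vs the rest."""
    inside = sum(1 for n in nuclei if band.y_low <= n.centroid_row < band.y_high)
    return inside, len(nuclei) - inside


def build_infiltration_series(
    per_frame_nuclei, band: ScratchBand, interval_min: float, well_id: str = ""
) -> InfiltrationSeries:
    """Classify every frame against the fixed band detected at t0."""
    if len(per_frame_nuclei) < 2:
        raise ValidationError("a time series requires at least 2 frames")
    if interval_min <= 0:
        raise ValidationError("interval_min must be positive")
    inside = []
    outside = []
    for nuclei in per_frame_nuclei:
        i, o = count_in_out(nuclei, band)
        inside.append(i)
        outside.append(o)
    times = np.arange(len(per_frame_nuclei), dtype=float) * float(interval_min)
    return InfiltrationSeries(
        well_id=well_id,
        times=times,
        inside=np.asarray(inside, dtype=np.int64),
        outside=np.asarray(outside, dtype=np.int64),
    )
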