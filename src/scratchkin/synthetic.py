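"""Ground-truthed synthetic scratch-assay data.

Two levels of fixture are generated, both fully deterministic per seed:

* count level — infiltration count series drawn from a known modified
  Gompertz curve plus Gaussian noise (optionally with a post-plateau
  exponential decline emulating a cytotoxic exposure);
* image level — rendered TIFF plates: a confluent nuclear-stained
  monolayer (jittered grid outside a horizontal cell-free band) whose
  band fills up over time according to the per-well truth curve.  Nuclei
  are isotropic Gaussian spots over a background with a vertical
  illumination ramp, so the full segmentation pipeline is exercised.

Defaults emulate the acquisition the toolkit targets: 600x800 px fields,
a band of 200 rows (the proportions of a 0.3 mm scratch imaged at 4x),
16 timepoints 20 minutes apart.  Outside-band nuclei stay fixed across
frames (the monolayer is treated as static); only the inside-band
population grows, and infiltrated cells persist, so per-frame ground
truth positions are exactly nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import DegenerateInputError, ValidationError
from .kinetics import GompertzParams, gompertz
from .plate_io import SegmentationParams, WellRecord, serialize_index
from .scratch import InfiltrationSeries, ScratchBand

__all__ = [
    "PlateSpec",
    "default_truths",
    "simulate_count_series",
    "simulate_adverse_series",
    "plant_monolayer",
    "plant_infiltration",
    "render_frame",
    "simulate_plate",
]

DEFAULT_TIMES = np.arange(16, dtype=float) * 20.0  # minutes, 0..300


def default_truths(n_wells: int) -> list[GompertzParams]:
    """Per-well truth parameters spanning realistic assay kinetics:
    plateaus of 300-600 cells, rates of 2-8 cells/min, lags of 10-60 min."""
    base = [
        GompertzParams(A=500.0, mu_m=2.0, lam=30.0),
        GompertzParams(A=300.0, mu_m=4.0, lam=60.0),
        GompertzParams(A=600.0, mu_m=8.0, lam=20.0),
        GompertzParams(A=400.0, mu_m=3.0, lam=45.0),
        GompertzParams(A=550.0, mu_m=6.0, lam=10.0),
        GompertzParams(A=350.0, mu_m=5.0, lam=40.0),
    ]
    return [base[i % len(base)] for i in range(n_wells)]


@dataclass
class PlateSpec:
    """Everything needed to render a ground-truthed plate."""

    n_wells: int = 6
    height: int = 600
    width: int = 800
    band: ScratchBand = field(
        default_factory=lambda: ScratchBand(y_low=220, y_high=420, bin_height=1)
    )
    nucleus_diameter: int = 12
    density_outside: float = 0.003  # nuclei per px^2 outside the band
    truth: list[GompertzParams] = field(default_factory=lambda: default_truths(6))
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    noise_sd: float = 20.0  # pixel intensity noise
    background: tuple[float, float] = (300.0, 200.0)  # (offset, vertical ramp)
    spot_amplitude: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.band.y_low < self.band.y_high <= self.height):
            raise ValidationError("band must lie within the frame")
        if len(self.truth) != self.n_wells:
            raise ValidationError("one truth parameter set per well required")
        spacing = 1.0 / math.sqrt(self.density_outside)
        if spacing < 1.2 * self.nucleus_diameter:
            raise ValidationError(
                "density_outside too high for non-overlapping placement; "
                f"grid spacing {spacing:.1f} px < 1.2 x diameter"
            )

    @property
    def seg_params(self) -> SegmentationParams:
        # block larger than a nucleus so block minima see true background;
        # wide diameter band-pass around the rendered spot size
        return SegmentationParams(
            block_size=max(16, self.nucleus_diameter + 4),
            min_diameter=max(3, self.nucleus_diameter // 3),
            max_diameter=2 * self.nucleus_diameter,
        )


def simulate_count_series(
    truth: GompertzParams, times, noise_sd: float, seed: int, well_id: str = "SIM"
) -> InfiltrationSeries:
    """Noisy counts from the truth curve: max(0, round(N(t) + eps))."""
    times = np.asarray(times, dtype=float)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    model = gompertz(times, truth)
    noisy = model + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else model
    inside = np.maximum(0, np.rint(noisy)).astype(np.int64)
    return InfiltrationSeries(
        well_id=well_id,
        times=times,
        inside=inside,
        outside=np.zeros_like(inside),
    )


def simulate_adverse_series(
    truth: GompertzParams,
    decline_start: float,
    decline_rate: float,
    times,
    seed: int,
    noise_sd: float = 0.0,
    well_id: str = "ADV",
) -> InfiltrationSeries:
    """Rise-then-decline counts: the truth curve until ``decline_start``,
    then multiplied by exp(-decline_rate * (t - decline_start)) — the
    signature of cell death after an initially rapid infiltration."""
    times = np.asarray(times, dtype=float)
    if not (times.min() <= decline_start <= times.max()):
        raise ValidationError("decline_start must lie within the time range")
    rng = np.random.default_rng(seed)
    model = gompertz(times, truth)
    decay = np.where(
        times > decline_start,
        np.exp(-decline_rate * (times - decline_start)),
        1.0,
    )
    model = model * decay
    noisy = model + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else model
    inside = np.maximum(0, np.rint(noisy)).astype(np.int64)
    return InfiltrationSeries(
        well_id=well_id,
        times=times,
        inside=inside,
        outside=np.zeros_like(inside),
    )


def plant_monolayer(spec: PlateSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid nucleus centers outside the band (fixed monolayer).

    Grid spacing 1/sqrt(density); jitter is bounded so pairwise center
    distances always exceed the nucleus diameter.
    """
    s = 1.0 / math.sqrt(spec.density_outside)
    jitter = 0.45 * (s - spec.nucleus_diameter)
    rows = np.arange(s / 2, spec.height - 1, s)
    cols = np.arange(s / 2, spec.width - 1, s)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 1.0, spec.height - 2.0)
    pts[:, 1] = np.clip(pts[:, 1], 1.0, spec.width - 2.0)
    margin = spec.nucleus_diameter / 2.0
    keep = (pts[:, 0] < spec.band.y_low - margin) | (pts[:, 0] >= spec.band.y_high + margin)
    return pts[keep]


def plant_infiltration(
    spec: PlateSpec, n_max: int, existing: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Master sequence of ``n_max`` non-overlapping positions inside the band.

    Frame k uses the first n_k points, so infiltrated cells persist across
    frames.  Rejection sampling; fails loudly if the band cannot hold the
    requested count at the given diameter.
    """
    d = float(spec.nucleus_diameter)
    pts: list[np.ndarray] = []
    placed = existing.copy() if existing.size else np.empty((0, 2))
    margin = 2.0
    attempts = 0
    max_attempts = 400 * max(n_max, 1)
    while len(pts) < n_max:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                f"cannot place {n_max} non-overlapping nuclei of diameter "
                f"{d:g} px in the band; lower the density or plateau"
            )
        cand = np.array(
            [
                rng.uniform(spec.band.y_low + margin, spec.band.y_high - margin),
                rng.uniform(margin, spec.width - margin),
            ]
        )
        if placed.size:
            if np.min(np.hypot(*(placed - cand).T)) <= d:
                continue
        pts.append(cand)
        placed = np.vstack([placed, cand])
    return np.array(pts) if pts else np.empty((0, 2))


def render_frame(positions, spec: PlateSpec, seed: int) -> np.ndarray:
    """Render one 16-bit-range frame: Gaussian nuclei (sigma = diameter/4)
    over offset + vertical-ramp background + Gaussian pixel noise."""
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    offset, ramp = spec.background
    img = np.empty((h, w), dtype=float)
    img[:] = offset + ramp * (np.arange(h, dtype=float) / max(h - 1, 1))[:, None]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))

    sigma = spec.nucleus_diameter / 4.0
    half = int(math.ceil(4 * sigma))
    for r, c in np.asarray(positions, dtype=float).reshape(-1, 2):
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"nucleus position ({r:.1f},{c:.1f}) outside frame")
        r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
        yy = np.arange(r0, r1, dtype=float)[:, None] - r
        xx = np.arange(c0, c1, dtype=float)[None, :] - c
        img[r0:r1, c0:c1] += spec.spot_amplitude * np.exp(
            -(yy**2 + xx**2) / (2 * sigma**2)
        )
    return np.clip(img, 0, 65535)


def simulate_plate(spec: PlateSpec, out_dir) -> dict:
    """Write a full ground-truthed plate to disk.

    Produces per-well folders of 16-bit TIFFs (frame files ``t00.tif`` ...),
    an ``index.tsv`` parseable by the I/O layer, and ground-truth tables:
    ``truth_params.tsv`` (per-well A, mu_m, lambda) and
    ``truth_positions.tsv`` (well, frame, region, row, col).  Returns a
    summary dict with the index path and per-well truths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_rng = np.random.default_rng(spec.seed)
    records = []
    truth_rows = []
    pos_lines = ["well\tframe\tregion\trow\tcol"]
    interval = float(spec.times[1] - spec.times[0]) if len(spec.times) > 1 else 20.0

    for w_idx in range(spec.n_wells):
        well_id = f"W{w_idx + 1:02d}"
        truth = spec.truth[w_idx]
        rng = np.random.default_rng(master_rng.integers(0, 2**31 - 1))
        outside_pts = plant_monolayer(spec, rng)
        n_per_frame = [
            int(np.rint(gompertz(t, truth))) for t in spec.times
        ]
        n_max = max(n_per_frame)
        if not np.all(np.diff(n_per_frame) >= 0):
            raise DegenerateInputError("infiltration counts must be non-decreasing")
        inside_master = plant_infiltration(spec, n_max, outside_pts, rng)

        well_dir = out / well_id
        well_dir.mkdir(exist_ok=True)
        for k, n_k in enumerate(n_per_frame):
            inside_pts = inside_master[:n_k]
            positions = (
                np.vstack([outside_pts, inside_pts]) if n_k else outside_pts
            )
            frame = render_frame(
                positions, spec, seed=int(rng.integers(0, 2**31 - 1))
            )
            tifffile.imwrite(
                well_dir / f"t{k:02d}.tif", frame.astype(np.uint16)
            )
            for r, c in outside_pts:
                pos_lines.append(f"{well_id}\t{k}\toutside\t{r:.3f}\t{c:.3f}")
            for r, c in inside_pts:
                pos_lines.append(f"{well_id}\t{k}\tinside\t{r:.3f}\t{c:.3f}")

        records.append(
            WellRecord(
                well_id=well_id,
                source=well_id,
                rotation_deg=0.0,
                interval_min=interval,
                seg_params=spec.seg_params,
            )
        )
        truth_rows.append(
            f"{well_id}\t{truth.A:g}\t{truth.mu_m:g}\t{truth.lam:g}"
        )

    index_path = out / "index.tsv"
    serialize_index(records, index_path)
    (out / "truth_params.tsv").write_text(
        "well\tA\tmu_m\tlambda\n" + "\n".join(truth_rows) + "\n", encoding="utf-8"
    )
    (out / "truth_positions.tsv").write_text(
        "\n".join(pos_lines) + "\n", encoding="utf-8"
    )
    return {
        "index": str(index_path),
        "wells": [r.well_id for r in records],
        "truth": {r.well_id: spec.truth[i] for i, r in enumerate(records)},
    }
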