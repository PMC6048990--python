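"""Plate-level I/O: index-file parsing, TIFF series loading, result writing.

The index file is a UTF-8, tab-separated table with one row per well and a
header ``well	folder	rotation_deg	interval_min	block_size	min_diameter
max_diameter``; lines starting with ``#`` are ignored.  ``rotation_deg``
(default 0) and ``block_size`` (default 10) are optional columns; the
diameter bounds must be explicit because no default is safe across cell
types.  Each well's images are single-page grayscale TIFFs whose
lexicographic filename order encodes acquisition time; a well source may be
a folder or a folder inside a ZIP archive.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import IndexFormatError, ValidationError

__all__ = [
    "SegmentationParams",
    "WellRecord",
    "ImageStack",
    "parse_index",
    "serialize_index",
    "load_stack",
    "filter_index",
    "write_results",
]

INDEX_COLUMNS = [
    "well",
    "folder",
    "rotation_deg",
    "interval_min",
    "block_size",
    "min_diameter",
    "max_diameter",
]
_MANDATORY = {"well", "folder", "interval_min", "min_diameter", "max_diameter"}
_DEFAULTS = {"rotation_deg": 0.0, "block_size": 10}

FEATURE_COLUMNS = [
    "frame",
    "object_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "eccentricity",
    "mean_intensity",
]
COUNTS_COLUMNS = ["well", "frame", "time_min", "inside", "outside", "total"]
PARAMS_COLUMNS = [
    "well",
    "A",
    "mu_m",
    "lambda",
    "r_squared",
    "rmse",
    "converged",
    "flagged",
]


@dataclass(frozen=True)
class SegmentationParams:
    block_size: int
    min_diameter: int
    max_diameter: int

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValidationError(f"block_size must be >= 2, got {self.block_size}")
        if not (0 < self.min_diameter < self.max_diameter):
            raise ValidationError(
                f"need 0 < min_diameter < max_diameter, got "
                f"{self.min_diameter}..{self.max_diameter}"
            )


@dataclass(frozen=True)
class WellRecord:
    well_id: str
    source: str
    rotation_deg: float
    interval_min: float
    seg_params: SegmentationParams
    included: bool = True

    def __post_init__(self) -> None:
        if not (self.interval_min > 0):
            raise ValidationError(
                f"well {self.well_id}: interval_min must be positive"
            )
        if not np.isfinite(self.rotation_deg):
            raise ValidationError(f"well {self.well_id}: rotation must be finite")


@dataclass
class ImageStack:
    """Time-ordered grayscale frames of identical shape, as (n, h, w)."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValidationError("time series required (>= 2 frames, same shape)")
        if self.frames.min() < 0:
            raise ValidationError("negative intensities are not allowed")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])


def _parse_num(value: str, column: str, line_no: int, caster):
    try:
        return caster(value)
    except ValueError:
        raise IndexFormatError(
            f"line {line_no}: column '{column}' has non-numeric value {value!r}"
        ) from None


def parse_index(index_path) -> list[WellRecord]:
    """Read the plate index file into one WellRecord per data row."""
    path = Path(index_path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [
        (i + 1, line)
        for i, line in enumerate(lines)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise IndexFormatError("index file has no header row")
    header = rows[0][1].rstrip("\n").split("\t")
    unknown = set(header) - set(INDEX_COLUMNS)
    if unknown:
        raise IndexFormatError(f"unknown column(s): {sorted(unknown)}")
    missing = _MANDATORY - set(header)
    if missing:
        raise IndexFormatError(f"missing mandatory column(s): {sorted(missing)}")

    records: list[WellRecord] = []
    seen: set[str] = set()
    for line_no, line in rows[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise IndexFormatError(
                f"line {line_no}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, (f.strip() for f in fields)))
        well = row["well"]
        if well in seen:
            raise ValidationError(f"duplicate well_id {well!r} in index")
        seen.add(well)
        rotation = (
            _parse_num(row["rotation_deg"], "rotation_deg", line_no, float)
            if "rotation_deg" in row
            else _DEFAULTS["rotation_deg"]
        )
        block = (
            _parse_num(row["block_size"], "block_size", line_no, int)
            if "block_size" in row
            else _DEFAULTS["block_size"]
        )
        records.append(
            WellRecord(
                well_id=well,
                source=row["folder"],
                rotation_deg=rotation,
                interval_min=_parse_num(row["interval_min"], "interval_min", line_no, float),
                seg_params=SegmentationParams(
                    block_size=block,
                    min_diameter=_parse_num(row["min_diameter"], "min_diameter", line_no, int),
                    max_diameter=_parse_num(row["max_diameter"], "max_diameter", line_no, int),
                ),
            )
        )
    return records


def serialize_index(records: list[WellRecord], out_path) -> None:
    """Write records back to the index dialect (round-trips parse_index)."""
    lines = ["\t".join(INDEX_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.well_id,
                    r.source,
                    f"{r.rotation_deg:g}",
                    f"{r.interval_min:g}",
                    str(r.seg_params.block_size),
                    str(r.seg_params.min_diameter),
                    str(r.seg_params.max_diameter),
                ]
            )
        )
    Path(out_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _to_gray(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 2:
        img = arr
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
        img = arr[..., :3].mean(axis=-1)  # defensive: accept RGB by channel mean
    else:
        raise ValidationError(f"{name}: unsupported TIFF layout {arr.shape}")
    return np.asarray(img, dtype=float)


def load_stack(record: WellRecord, root) -> ImageStack:
    """Load one well's TIFF series, frames in lexicographic filename order.

    ``record.source`` resolved against ``root`` may be a directory of .tif
    files or a ZIP archive (optionally ``archive.zip/inner/folder``).
    """
    root = Path(root)
    src = root / record.source
    frames: list[tuple[str, np.ndarray]] = []

    if src.is_dir():
        for p in sorted(src.iterdir()):
            if p.suffix.lower() in (".tif", ".tiff"):
                try:
                    arr = tifffile.imread(p)
                except Exception as exc:
                    raise IOError(f"cannot read TIFF {p}: {exc}") from exc
                frames.append((p.name, _to_gray(arr, str(p))))
    else:
        zip_path, inner = _resolve_zip(src)
        with zipfile.ZipFile(zip_path) as zf:
            members = [
                m
                for m in zf.namelist()
                if m.lower().endswith((".tif", ".tiff"))
                and (not inner or m.startswith(inner.rstrip("/") + "/"))
            ]
            for m in sorted(members, key=lambda m: m.rsplit("/", 1)[-1]):
                try:
                    arr = tifffile.imread(io.BytesIO(zf.read(m)))
                except Exception as exc:
                    raise IOError(f"cannot read TIFF {m} in {zip_path}: {exc}") from exc
                frames.append((m, _to_gray(arr, m)))

    if len(frames) < 2:
        raise ValidationError(
            f"well {record.well_id}: time series required (>= 2 frames, "
            f"found {len(frames)})"
        )
    shapes = {f.shape for _, f in frames}
    if len(shapes) != 1:
        raise ValidationError(
            f"well {record.well_id}: frames have mismatched shapes {shapes}"
        )
    return ImageStack(frames=np.stack([f for _, f in frames]))


def _resolve_zip(src: Path) -> tuple[Path, str]:
    if src.suffix.lower() == ".zip" and src.exists():
        return src, ""
    for parent in src.parents:
        if parent.suffix.lower() == ".zip" and parent.exists():
            return parent, str(src.relative_to(parent))
    raise IOError(f"source {src} is neither a directory nor a zip archive")


def filter_index(records: list[WellRecord], excluded) -> list[WellRecord]:
    """Return a copy of the index with excluded wells marked included=False."""
    excluded = set(excluded)
    known = {r.well_id for r in records}
    unknown = excluded - known
    if unknown:
        raise ValidationError(f"unknown well_id(s) in exclusion set: {sorted(unknown)}")
    return [
        replace(r, included=False) if r.well_id in excluded else replace(r)
        for r in records
    ]


# ---------------------------------------------------------------------------
# output writing


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def _write_tsv(path: Path, columns: list[str], rows: list[list]) -> None:
    lines = ["\t".join(columns)]
    lines += ["\t".join(_fmt(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_features_tsv(well, out_dir) -> Path:
    """Write one well's per-frame nucleus features to features_<well>.tsv."""
    rows = [
        [
            n.frame_index,
            n.object_id,
            n.centroid_row,
            n.centroid_col,
            n.area,
            n.eccentricity,
            n.mean_intensity,
        ]
        for frame in well.nuclei
        for n in frame
    ]
    path = Path(out_dir) / f"features_{well.well_id}.tsv"
    _write_tsv(path, FEATURE_COLUMNS, rows)
    return path


def write_counts_tsv(wells, out_dir) -> Path:
    """Write the plate-wide inside/outside count table to counts.tsv."""
    rows = []
    for well in wells:
        if well.series is None:
            continue
        s = well.series
        for k in range(len(s.times)):
            rows.append(
                [
                    well.well_id,
                    k,
                    float(s.times[k]),
                    int(s.inside[k]),
                    int(s.outside[k]),
                    int(s.inside[k]) + int(s.outside[k]),
                ]
            )
    path = Path(out_dir) / "counts.tsv"
    _write_tsv(path, COUNTS_COLUMNS, rows)
    return path


def write_parameters_tsv(wells, out_dir) -> Path:
    """Write the plate-wide kinetic-parameter table to parameters.tsv."""
    rows = []
    for well in wells:
        if well.fit is None:
            continue
        f = well.fit
        p = f.params
        rows.append(
            [
                well.well_id,
                p.A if p else float("nan"),
                p.mu_m if p else float("nan"),
                p.lam if p else float("nan"),
                f.r_squared,
                f.rmse,
                bool(f.converged),
                bool(f.flagged),
            ]
        )
    path = Path(out_dir) / "parameters.tsv"
    _write_tsv(path, PARAMS_COLUMNS, rows)
    return path


def write_results(plate, out_dir) -> dict:
    """Write all tabular and graphical outputs for a plate.

    Produces per-well feature TSVs, ``counts.tsv``, ``parameters.tsv``,
    per-well fitted-curve PNGs, an HTML summary and a ``manifest.json``
    listing every written file.  Reruns overwrite previous outputs.
    """
    from .report import plot_well_curve, render_html_report

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    manifest = {"tables": [], "plots": [], "report": None}

    for well in plate.wells:
        manifest["tables"].append(str(write_features_tsv(well, out)))
    manifest["tables"].append(str(write_counts_tsv(plate.wells, out)))
    manifest["tables"].append(str(write_parameters_tsv(plate.wells, out)))

    for well in plate.wells:
        if well.series is None or well.fit is None:
            continue
        ppath = out / f"curve_{well.well_id}.png"
        plot_well_curve(well, ppath)
        manifest["plots"].append(str(ppath))

    report_path = out / "report.html"
    report_path.write_text(render_html_report(plate, manifest), encoding="utf-8")
    manifest["report"] = str(report_path)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
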