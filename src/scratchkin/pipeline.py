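"""Plate-level orchestration: load -> rotate -> segment -> detect band ->
count -> fit -> flag, per included well, with per-well fault isolation."""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

from . import __version__
from .errors import ScratchkinError
from .kinetics import fit_gompertz, flag_fit
from .plate_io import WellRecord, filter_index, load_stack, parse_index, write_results
from .results import PlateResult, WellResult
from .scratch import (
    build_infiltration_series,
    detect_scratch_band,
    rotate_stack,
    y_frequency,
)
from .segmentation import segment_series

__all__ = ["process_well", "run_pipeline"]


def process_well(
    record: WellRecord,
    root,
    bin_height: int | None = None,
    merge_span_bins: int = 6,
    straggler_max: int = 4,
    r2_threshold: float = 0.9,
) -> WellResult:
    """Run the full analysis for one well.

    The scratch band is detected from the first frame's nucleus rows
    (bin height defaults to the well's min_diameter) and held fixed for
    the whole series.
    """
    result = WellResult(well_id=record.well_id)
    stack = load_stack(record, root)
    stack = rotate_stack(stack, record.rotation_deg)
    nuclei = segment_series(stack, record.seg_params)
    result.nuclei = nuclei

    bh = bin_height if bin_height is not None else record.seg_params.min_diameter
    hist = y_frequency(nuclei[0], height=stack.height, bin_height=bh)
    band = detect_scratch_band(
        hist,
        bin_height=bh,
        height=stack.height,
        merge_span_bins=merge_span_bins,
        straggler_max=straggler_max,
    )
    if band.height < 2 * record.seg_params.max_diameter:
        result.warnings.append(
            f"well {record.well_id}: detected band height {band.height} px is "
            f"below 2x max_diameter; scratch detection may have failed"
        )
    result.band = band
    result.series = build_infiltration_series(
        nuclei, band, record.interval_min, well_id=record.well_id
    )
    result.fit = fit_gompertz(result.series)
    result.fit.flagged = flag_fit(result.fit, r2_threshold)
    return result


def run_pipeline(
    index_path,
    root,
    out_dir,
    overrides: dict | None = None,
    excluded=(),
) -> PlateResult:
    """Analyze a whole plate and write all outputs.

    ``overrides`` may set ``bin_height``, ``merge_span_bins`` and
    ``straggler_max`` globally.  A failing well is recorded with its error
    and the run continues; fit flags are warnings, not errors.
    """
    overrides = overrides or {}
    records = parse_index(index_path)
    if excluded:
        records = filter_index(records, set(excluded))

    plate = PlateResult(
        metadata={
            "version": __version__,
            "index": str(index_path),
            "root": str(root),
            "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
            "overrides": {k: v for k, v in overrides.items()},
        }
    )
    plate.excluded = [r.well_id for r in records if not r.included]

    for record in records:
        if not record.included:
            continue
        try:
            well = process_well(
                record,
                root,
                bin_height=overrides.get("bin_height"),
                merge_span_bins=overrides.get("merge_span_bins", 6),
                straggler_max=overrides.get("straggler_max", 4),
                r2_threshold=overrides.get("r2_threshold", 0.9),
            )
        except (ScratchkinError, IOError) as exc:
            well = WellResult(well_id=record.well_id, error=str(exc))
        plate.wells.append(well)
        plate.warnings.extend(well.warnings)

    Path(out_dir).mkdir(parents=True, exist_ok=True)
    write_results(plate, out_dir)
    return plate
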