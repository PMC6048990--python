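"""Result containers shared by the I/O layer and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .kinetics import KineticFit
from .scratch import InfiltrationSeries, ScratchBand
from .segmentation import NucleusRecord


@dataclass
class WellResult:
    """Everything computed for one well."""

    well_id: str
    band: Optional[ScratchBand] = None
    series: Optional[InfiltrationSeries] = None
    fit: Optional[KineticFit] = None
    nuclei: list[list[NucleusRecord]] = field(default_factory=list)
    error: Optional[str] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class PlateResult:
    """All per-well results plus run metadata for one plate."""

    wells: list[WellResult] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
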