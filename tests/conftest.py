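import numpy as np
import pytest

from scratchkin.kinetics import GompertzParams
from scratchkin.scratch import ScratchBand
from scratchkin.synthetic import PlateSpec, simulate_plate

#: acquisition schedule used throughout: 16 frames, 20 minutes apart
TIMES = np.arange(16, dtype=float) * 20.0

#: parameter grid spanning slow/fast wells for identity and recovery checks
PARAM_GRID = [
    GompertzParams(A=a, mu_m=m, lam=l)
    for a in (100.0, 500.0, 2000.0)
    for m in (0.5, 2.0, 8.0)
    for l in (-10.0, 0.0, 40.0)
]


def small_plate_spec(seed: int = 7, n_wells: int = 2) -> PlateSpec:
    """A reduced plate (2 wells, 320x400 px, 8 frames) for pipeline tests."""
    truths = [
        GompertzParams(A=150.0, mu_m=2.0, lam=30.0),
        GompertzParams(A=120.0, mu_m=4.0, lam=50.0),
    ][:n_wells]
    return PlateSpec(
        n_wells=n_wells,
        height=320,
        width=400,
        band=ScratchBand(y_low=110, y_high=210, bin_height=1),
        nucleus_diameter=12,
        density_outside=0.003,
        truth=truths,
        times=np.arange(8, dtype=float) * 20.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_plate(tmp_path_factory):
    """One rendered small plate on disk, shared across pipeline tests."""
    out = tmp_path_factory.mktemp("plate")
    spec = small_plate_spec()
    info = simulate_plate(spec, out)
    return {"dir": out, "spec": spec, "info": info}
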