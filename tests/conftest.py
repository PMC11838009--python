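import numpy as np
import pandas as pd
import pytest

from microconstrict import ConstrictionGeometry, DeformationTrace, ShellParams


@pytest.fixture
def default_params() -> ShellParams:
    # reference mouse-oocyte shell: tension 1 nN/um, modulus 1.5 kPa,
    # thickness 24.4 um, diameter 74.4 um
    return ShellParams(tau0=1.0, E=1.5, th=24.4, D0=74.4)


@pytest.fixture
def default_geometry() -> ConstrictionGeometry:
    return ConstrictionGeometry(d=50.0, alpha_deg=9.0)


def make_trace(
    time, pressure, x_front, x_rear, aspect_ratio=None, d_um=50.0, spindle=None, **meta
) -> DeformationTrace:
    """Hand-built trace helper for fixture-free tests."""
    n = len(time)
    data = {
        "time_s": np.asarray(time, dtype=float),
        "pressure_mbar": np.asarray(pressure, dtype=float),
        "x_front_um": np.asarray(x_front, dtype=float),
        "x_rear_um": np.asarray(x_rear, dtype=float),
        "aspect_ratio": np.ones(n) if aspect_ratio is None else np.asarray(aspect_ratio, float),
    }
    if spindle is not None:
        data["spindle_len_um"] = np.asarray(spindle[0], dtype=float)
        data["spindle_angle_deg"] = np.asarray(spindle[1], dtype=float)
    metadata = {"d_um": d_um, "oocyte_id": "t-000", "group": "control",
                "experiment_id": "exp-1"}
    metadata.update(meta)
    return DeformationTrace(data=pd.DataFrame(data), metadata=metadata)
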