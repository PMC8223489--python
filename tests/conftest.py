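"""Shared fixtures: small synthetic scenes reused across test modules.

All scenes are generated by the package's own simulator in the high-SNR
benchmarking regime (1 nm localization precision, full frame budget, no
background unless stated) with fixed seeds, so every test is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hexpaint.designs import get_design
from hexpaint.loc_io import LocalizationTable
from hexpaint.paint_sim import (
    AcquisitionParams,
    expected_locs_per_site,
    fov_for,
    high_snr_params,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def w16_scene():
    """120 fully occupied W16 structures, high-SNR regime."""
    design = get_design("W16")
    acq = AcquisitionParams(fov_px=fov_for(120))
    kin = high_snr_params()
    table, truth = simulate_acquisition(design, 120, 1.0, acq, kin, seed=7)
    return {
        "design": design,
        "acq": acq,
        "kin": kin,
        "table": table,
        "truth": truth,
        "expected_per_site": expected_locs_per_site(acq, kin),
    }


@pytest.fixture(scope="session")
def drifted_scene():
    """40 fully occupied W16 structures with linear drift of 0.002 px/frame
    in x and -0.001 px/frame in y (end-to-end ~24 and ~12 px)."""
    design = get_design("W16")
    acq = AcquisitionParams(fov_px=(64, 64))
    px = acq.camera_pixel_nm
    kin = high_snr_params(drift_nm_per_frame=(0.002 * px, -0.001 * px))
    table, truth = simulate_acquisition(design, 40, 1.0, acq, kin, seed=3)
    return {"design": design, "acq": acq, "kin": kin, "table": table, "truth": truth}


def make_table(
    frame, x, y, photons=None, sx=None, sy=None, precision=None, ellipticity=None, **metadata
) -> LocalizationTable:
    """Hand-build a small localization table with sensible defaults."""
    frame = np.asarray(frame, dtype=np.int64)
    n = frame.size
    df = pd.DataFrame(
        {
            "frame": frame,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons, float),
            "sx": np.full(n, 1.3) if sx is None else np.asarray(sx, float),
            "sy": np.full(n, 1.3) if sy is None else np.asarray(sy, float),
            "precision": np.full(n, 0.01) if precision is None else np.asarray(precision, float),
        }
    )
    if ellipticity is None:
        df["ellipticity"] = np.minimum(df.sx, df.sy) / np.maximum(df.sx, df.sy)
    else:
        df["ellipticity"] = np.asarray(ellipticity, dtype=float)
    return LocalizationTable(df, metadata)
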