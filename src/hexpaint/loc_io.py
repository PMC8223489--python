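"""Localization-table container and Picasso-style HDF5 / CSV I/O.

The canonical in-memory object is :class:`LocalizationTable`: a pandas
DataFrame of single-molecule localizations plus a metadata dict.  Coordinate
conventions, stated once and used everywhere:

* ``x``, ``y`` are in camera pixels; ``camera_pixel_nm`` in the metadata
  (default 87 nm) converts to physical units at analysis boundaries only.
* ``frame`` is 0-based; valid frames are ``0 <= frame < n_frames``.
* Coordinates refer to pixel centres; the field of view is the half-open
  square ``[0, width_px) x [0, height_px)``.

Columns
-------
frame : int           acquisition frame index
x, y : float          fitted position, camera px
photons : float       photon count of the fitted spot
sx, sy : float        fitted Gaussian widths, camera px
precision : float     per-localization precision, camera px (opaque quality
                      number in the Picasso spirit; no estimator is implied)
ellipticity : float   min(sx, sy) / max(sx, sy), in (0, 1]

On disk the HDF5 layout mirrors the Picasso "locs" convention: a single
structured dataset named ``locs`` with one field per column, and a YAML
sidecar (same path, ``.yaml`` suffix) holding the metadata.  The CSV dialect
is a plain header-row CSV with the same columns and the same YAML sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = ["LocalizationTable", "read_localizations", "write_localizations", "COLUMNS"]

COLUMNS = ["frame", "x", "y", "photons", "sx", "sy", "precision", "ellipticity"]
_REQUIRED = ["frame", "x", "y", "photons", "sx", "sy"]

DEFAULT_CAMERA_PIXEL_NM = 87.0


@dataclass
class LocalizationTable:
    """Localizations with quality metrics, in camera-pixel units."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("camera_pixel_nm", DEFAULT_CAMERA_PIXEL_NM)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def camera_pixel_nm(self) -> float:
        return float(self.metadata["camera_pixel_nm"])

    @property
    def n_frames(self) -> int:
        if "n_frames" in self.metadata:
            return int(self.metadata["n_frames"])
        if len(self.df) == 0:
            return 0
        return int(self.df["frame"].max()) + 1

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), dict(self.metadata))

    def validate(self) -> None:
        """Check the table invariants; raise ValueError on violation."""
        df = self.df
        for col in COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column: {col}")
        if len(df) == 0:
            return
        if (df["frame"] < 0).any() or (df["frame"] >= self.n_frames).any():
            raise ValueError("frame indices outside [0, n_frames)")
        if (df["photons"] <= 0).any():
            raise ValueError("photons must be positive")
        if (df["precision"] <= 0).any():
            raise ValueError("precision must be positive")
        ell = df["ellipticity"]
        if (ell <= 0).any() or (ell > 1).any():
            raise ValueError("ellipticity must lie in (0, 1]")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Fill in derivable columns and enforce dtypes."""
    df = df.copy()
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"localization table is missing required column: {col}")
    if "precision" not in df.columns:
        # Picasso stores per-axis precisions lpx/lpy; fold them into one number.
        if "lpx" in df.columns and "lpy" in df.columns:
            df["precision"] = np.sqrt(df["lpx"].to_numpy() * df["lpy"].to_numpy())
        else:
            raise ValueError(
                "localization table is missing required column: precision "
                "(or lpx/lpy to derive it)"
            )
    if "ellipticity" not in df.columns:
        sx = df["sx"].to_numpy(dtype=float)
        sy = df["sy"].to_numpy(dtype=float)
        df["ellipticity"] = np.minimum(sx, sy) / np.maximum(sx, sy)
    df = df[COLUMNS]
    return df.astype(
        {"frame": np.int64, **{c: np.float64 for c in COLUMNS if c != "frame"}}
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return "hdf5"
    return "csv"


def read_localizations(path: str | Path, format: str | None = None) -> LocalizationTable:
    """Read a localization table from HDF5 (Picasso-style) or CSV.

    Missing optional columns are derived (``ellipticity`` from ``sx``/``sy``,
    ``precision`` from ``lpx``/``lpy``); a missing required column raises a
    ``ValueError`` naming the column.  If no metadata sidecar is found, the
    87 nm camera-pixel default is assumed with a warning.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            recs = f["locs"][()]
        df = pd.DataFrame({name: recs[name] for name in recs.dtype.names})
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format: {fmt!r} (expected 'hdf5' or 'csv')")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        metadata = yaml.safe_load(sidecar.read_text()) or {}
    else:
        warnings.warn(
            f"no metadata sidecar found at {sidecar}; assuming camera pixels "
            f"with {DEFAULT_CAMERA_PIXEL_NM} nm pixel size",
            stacklevel=2,
        )
        metadata = {"camera_pixel_nm": DEFAULT_CAMERA_PIXEL_NM}
    return LocalizationTable(_normalize_columns(df), metadata)


def write_localizations(
    table: LocalizationTable, path: str | Path, format: str | None = None
) -> Path:
    """Write a localization table plus its YAML metadata sidecar.

    Output is bit-stable for a fixed input table.  Returns the data path.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    df = _normalize_columns(table.df) if len(table.df) else _empty_frame()
    if fmt == "hdf5":
        recs = df.to_records(index=False)
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=recs)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format: {fmt!r} (expected 'hdf5' or 'csv')")
    meta = {k: _plain(v) for k, v in sorted(table.metadata.items())}
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            c: pd.Series(dtype=(np.int64 if c == "frame" else np.float64))
            for c in COLUMNS
        }
    )


def _plain(value):
    """Convert numpy scalars/arrays to plain Python for YAML round-trips."""
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    return value
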