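"""Quality filtering and drift correction of localization tables.

Three quality rules, applied simultaneously against the statistics of the
input table (the step is one pass, not a sequence):

* low-precision localizations: ``precision > precision_max_px`` (default
  0.03 camera pixels);
* asymmetric localizations: ``ellipticity < ellipticity_min`` (default 0.1,
  with ellipticity = minor/major width ratio);
* multi-emitter localizations: ``photons > mean + photon_z * SD`` where mean
  and SD are computed over the *input* photon counts (default z = 2).

Drift correction implements redundant cross-correlation (RCC): the
acquisition is cut into temporal fragments (default 200 frames), each
fragment is rendered into a super-resolved 2D histogram, relative offsets
are measured by cross-correlating *all* fragment pairs, and the redundant
set of pairwise offsets is solved in least squares for one offset per
fragment.  The per-fragment offsets are interpolated to a per-frame drift
trace and gauge-fixed to zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d

from .loc_io import LocalizationTable

__all__ = [
    "FilterParams",
    "FilterReport",
    "filter_localizations",
    "remove_fiducials",
    "estimate_drift",
    "apply_drift",
]


@dataclass(frozen=True)
class FilterParams:
    precision_max_px: float = 0.03
    ellipticity_min: float = 0.1
    photon_z: float = 2.0
    drift_segment_frames: int = 200

    def __post_init__(self) -> None:
        if min(self.precision_max_px, self.ellipticity_min, self.photon_z) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class FilterReport:
    """Per-rule removal counts (a row can trip several rules; ``n_removed``
    counts each row once) plus the photon statistics the photon rule used."""

    n_input: int
    n_removed: int
    n_retained: int
    removed_low_precision: int
    removed_asymmetric: int
    removed_multilocalization: int
    photon_mean: float
    photon_sd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_localizations(
    table: LocalizationTable,
    params: FilterParams | None = None,
    photon_stats: tuple[float, float] | None = None,
) -> tuple[LocalizationTable, FilterReport]:
    """Apply the three quality rules; survivors keep their order and values.

    ``photon_stats`` (mean, sd) overrides the statistics used by the photon
    rule; passing the stats recorded in a previous report makes the filter
    idempotent.
    """
    params = params or FilterParams()
    df = table.df
    n = len(df)
    if photon_stats is None:
        photon_mean = float(df["photons"].mean()) if n else float("nan")
        # sample SD (ddof=1), matching the usual convention for this cut
        photon_sd = float(df["photons"].std(ddof=1)) if n > 1 else 0.0
    else:
        photon_mean, photon_sd = photon_stats
    if n == 0:
        report = FilterReport(0, 0, 0, 0, 0, 0, photon_mean, photon_sd)
        return table.copy(), report

    low_precision = df["precision"].to_numpy() > params.precision_max_px
    asymmetric = df["ellipticity"].to_numpy() < params.ellipticity_min
    multiloc = df["photons"].to_numpy() > photon_mean + params.photon_z * photon_sd
    removed = low_precision | asymmetric | multiloc

    out = LocalizationTable(df.loc[~removed].reset_index(drop=True), dict(table.metadata))
    out.metadata["quality_filtered"] = True
    report = FilterReport(
        n_input=n,
        n_removed=int(removed.sum()),
        n_retained=int((~removed).sum()),
        removed_low_precision=int(low_precision.sum()),
        removed_asymmetric=int(asymmetric.sum()),
        removed_multilocalization=int(multiloc.sum()),
        photon_mean=photon_mean,
        photon_sd=photon_sd,
    )
    return out, report


def remove_fiducials(
    table: LocalizationTable, positions_px: np.ndarray, radius_px: float = 2.0
) -> LocalizationTable:
    """Drop localizations within ``radius_px`` of any fiducial position
    (simulator-declared or user-supplied picks)."""
    positions_px = np.atleast_2d(np.asarray(positions_px, dtype=float))
    if positions_px.size == 0 or len(table) == 0:
        return table.copy()
    xy = table.df[["x", "y"]].to_numpy()
    keep = np.ones(len(table), dtype=bool)
    for p in positions_px:
        keep &= np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) > radius_px
    out = LocalizationTable(table.df.loc[keep].reset_index(drop=True), dict(table.metadata))
    out.metadata["fiducials_removed"] = True
    return out


# ---------------------------------------------------------------------------
# RCC drift correction
# ---------------------------------------------------------------------------


def _render_segment(x, y, bounds, oversampling) -> np.ndarray:
    (x0, x1), (y0, y1) = bounds
    nx = max(1, int(np.ceil((x1 - x0) * oversampling)))
    ny = max(1, int(np.ceil((y1 - y0) * oversampling)))
    img, _, _ = np.histogram2d(
        x, y, bins=(nx, ny), range=((x0, x0 + nx / oversampling), (y0, y0 + ny / oversampling))
    )
    return img


def _xcorr_offset(fa: np.ndarray, fb_conj: np.ndarray, shape) -> np.ndarray:
    """Sub-pixel offset of image b relative to image a from their FFTs.

    The correlation peak is located on the grid, then refined by an
    intensity-weighted centroid over a 3x3 window around the peak.
    """
    corr = np.fft.irfft2(fa * fb_conj, s=shape)
    corr = np.fft.fftshift(corr)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    window = corr[
        max(peak[0] - 1, 0) : peak[0] + 2, max(peak[1] - 1, 0) : peak[1] + 2
    ]
    window = np.maximum(window - window.min(), 0.0)
    total = window.sum()
    if total > 0:
        gi, gj = np.mgrid[0 : window.shape[0], 0 : window.shape[1]]
        di = (window * gi).sum() / total - (peak[0] - max(peak[0] - 1, 0))
        dj = (window * gj).sum() / total - (peak[1] - max(peak[1] - 1, 0))
    else:
        di = dj = 0.0
    center = np.array([corr.shape[0] // 2, corr.shape[1] // 2], dtype=float)
    return np.array([peak[0] + di, peak[1] + dj]) - center


def estimate_drift(
    table: LocalizationTable,
    segment_frames: int = 200,
    oversampling: int = 4,
    smooth_sigma_bins: float = 1.0,
) -> np.ndarray:
    """Estimate a per-frame 2D drift trace by RCC.

    Returns an ``(n_frames, 2)`` array of offsets in camera pixels with zero
    mean over frames (gauge fixed).  Deterministic.

    Raises
    ------
    ValueError
        If fewer than two full fragments fit in the acquisition, or some
        fragment holds too few localizations to correlate.
    """
    n_frames = table.n_frames
    if n_frames < 2 * segment_frames:
        raise ValueError(
            "acquisition too short for drift estimation: need at least two "
            f"fragments of {segment_frames} frames; use smaller fragments"
        )
    df = table.df
    frames = df["frame"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    n_seg = n_frames // segment_frames
    seg_of_frame = np.minimum(frames // segment_frames, n_seg - 1)

    x1 = max(np.ceil(x.max() + 1), 1) if x.size else 1.0
    y1 = max(np.ceil(y.max() + 1), 1) if y.size else 1.0
    fov = table.metadata.get("fov_px")
    if fov is not None:
        x1, y1 = max(x1, fov[0]), max(y1, fov[1])
    bounds = ((0.0, float(x1)), (0.0, float(y1)))

    imgs = []
    for s in range(n_seg):
        sel = seg_of_frame == s
        if sel.sum() < 10:
            raise ValueError(
                f"fragment {s} holds only {int(sel.sum())} localizations; "
                "use larger fragments"
            )
        img = _render_segment(x[sel], y[sel], bounds, oversampling)
        if smooth_sigma_bins > 0:
            img = ndimage.gaussian_filter(img, smooth_sigma_bins)
        imgs.append(img)

    shape = imgs[0].shape
    ffts = [np.fft.rfft2(img) for img in imgs]
    pairs = [(i, j) for i in range(n_seg) for j in range(i + 1, n_seg)]
    # Offsets in render bins: measurement for pair (i, j) is d_j - d_i.
    A = np.zeros((len(pairs), n_seg))
    B = np.zeros((len(pairs), 2))
    for row, (i, j) in enumerate(pairs):
        off = _xcorr_offset(ffts[i], np.conj(ffts[j]), shape)
        A[row, i] = -1.0
        A[row, j] = 1.0
        B[row] = -off  # correlation peak sits at a - b; negate for b - a
    seg_offsets, *_ = np.linalg.lstsq(A, B, rcond=None)
    seg_offsets /= oversampling  # bins -> camera px

    midpoints = (np.arange(n_seg) + 0.5) * segment_frames
    midpoints[-1] = (n_seg - 1) * segment_frames + (n_frames - (n_seg - 1) * segment_frames) / 2.0
    f = interp1d(midpoints, seg_offsets, axis=0, fill_value="extrapolate")
    trace = f(np.arange(n_frames))
    trace -= trace.mean(axis=0, keepdims=True)
    return trace


def apply_drift(table: LocalizationTable, trace: np.ndarray) -> LocalizationTable:
    """Subtract a per-frame drift trace from the coordinates.

    ``trace`` must cover every frame present in the table; frames outside its
    range raise ``ValueError``.  Applying the negated trace undoes the
    correction exactly.
    """
    trace = np.asarray(trace, dtype=float)
    df = table.df
    frames = df["frame"].to_numpy()
    if len(df) and (frames.min() < 0 or frames.max() >= len(trace)):
        raise ValueError("drift trace does not cover all frames in the table")
    out = df.copy()
    if len(df):
        out["x"] = out["x"].to_numpy() - trace[frames, 0]
        out["y"] = out["y"].to_numpy() - trace[frames, 1]
    meta = dict(table.metadata)
    meta["drift_corrected"] = True
    return LocalizationTable(out, meta)
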