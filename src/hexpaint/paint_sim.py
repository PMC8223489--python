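"""Synthetic DNA-PAINT acquisition simulator with ground truth.

Generates localization tables that emulate a DNA-PAINT experiment on
surface-immobilized DNA origami: structures are scattered over the field of
view with random in-plane rotations, each of their six docking sites is
present with a configurable per-site occupancy, and present sites blink
according to an alternating renewal process driven by imager binding
kinetics.  Each bright frame of a site contributes one localization at the
site position plus isotropic Gaussian localization noise.  Nonspecific
background localizations, always-on fiducial markers, and linear stage drift
can be added.  Every emitted localization is labelled in a ground-truth
record, so downstream detection and quantification can be scored exactly.

Kinetic model
-------------
The simulator works at frame resolution (no sub-frame photophysics).  A site
alternates between a dark state, with exponential waiting times at rate
``dark_rate_per_nM_per_s * imager_conc_nM`` (the pseudo-first-order imager
on-rate), and a bright state lasting a geometric number of frames with mean
``mean_bright_frames``.  The steady-state bright fraction is therefore

    rho = t_bright / (t_bright + t_dark)

with both times in frames, and a present site emits on average
``n_frames * rho`` localizations (see :func:`expected_locs_per_site`).

Default kinetics correspond to a typical 8-10 nt DNA-PAINT duplex imaged at
10 nM imager and 300 ms frames: on-rate coefficient 1e-3 /nM/s (i.e.
k_on = 1e6 /M/s), bright times of ~0.75 s (2.5 frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignSpec, hexagon_coords
from .loc_io import DEFAULT_CAMERA_PIXEL_NM, LocalizationTable

__all__ = [
    "AcquisitionParams",
    "KineticsNoiseParams",
    "GroundTruth",
    "place_structures",
    "simulate_acquisition",
    "expected_locs_per_site",
    "high_snr_params",
    "fov_for",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/acquisition settings (defaults mirror the imaging protocol:
    12000 frames at 300 ms exposure, 87 nm pixels, 10 nM imager)."""

    n_frames: int = 12000
    exposure_s: float = 0.3
    camera_pixel_nm: float = DEFAULT_CAMERA_PIXEL_NM
    fov_px: tuple[int, int] = (64, 64)
    imager_conc_nM: float = 10.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.camera_pixel_nm <= 0:
            raise ValueError("camera_pixel_nm must be positive")
        if min(self.fov_px) <= 0:
            raise ValueError("fov_px must be positive")


@dataclass(frozen=True)
class KineticsNoiseParams:
    """Blinking kinetics, localization noise and nuisance-signal settings.

    ``loc_precision_nm`` is the standard deviation of the isotropic Gaussian
    error added to each site localization.  The per-row ``precision`` column
    is synthesized with the usual sigma/sqrt(photons) scaling so that its
    typical magnitude matches ``loc_precision_nm`` at the mean photon count;
    it is a plausible quality number, not a claim about any estimator.
    """

    mean_bright_frames: float = 2.5
    dark_rate_per_nM_per_s: float = 1e-3
    loc_precision_nm: float = 1.0
    photon_mean: float = 3000.0
    photon_sd: float = 800.0
    bg_rate_per_um2_per_frame: float = 0.0
    drift_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    n_fiducials: int = 0
    fiducial_photon_factor: float = 20.0
    psf_sigma_px: float = 1.3
    psf_sigma_jitter_px: float = 0.04
    junk_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_bright_frames < 0 or self.dark_rate_per_nM_per_s < 0:
            raise ValueError("kinetic rates must be >= 0")
        if self.loc_precision_nm < 0 or self.bg_rate_per_um2_per_frame < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.junk_fraction <= 1:
            raise ValueError("junk_fraction must lie in [0, 1]")


def high_snr_params(**overrides) -> KineticsNoiseParams:
    """Kinetics/noise preset for the high-SNR benchmarking regime:
    1 nm localization precision, no drift, no background, no fiducials."""
    base = dict(
        loc_precision_nm=1.0,
        bg_rate_per_um2_per_frame=0.0,
        drift_nm_per_frame=(0.0, 0.0),
        n_fiducials=0,
        junk_fraction=0.0,
    )
    base.update(overrides)
    return KineticsNoiseParams(**base)


@dataclass
class GroundTruth:
    """Simulator-side record of the true scene.

    ``structures``: one row per structure (structure_id, cx_px, cy_px,
    rotation_rad, design, site_present_0..5).  ``sources``: one row per
    emitted localization, aligned with the table rows, with columns
    ``kind`` ('site' | 'background' | 'fiducial'), ``structure_id`` and
    ``site_index`` (-1 where not applicable).
    """

    structures: pd.DataFrame
    sources: pd.DataFrame
    fiducials_px: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def write(self, directory: str | Path, stem: str = "ground_truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.structures.to_csv(directory / f"{stem}_structures.csv", index=False)
        self.sources.to_csv(directory / f"{stem}_sources.csv", index=False)


def expected_locs_per_site(acq: AcquisitionParams, kin: KineticsNoiseParams) -> float:
    """Expected localizations emitted by one present site over the run.

    Steady-state bright fraction of the alternating renewal process times the
    number of frames.
    """
    event_rate_per_s = kin.dark_rate_per_nM_per_s * acq.imager_conc_nM
    if event_rate_per_s == 0 or kin.mean_bright_frames == 0:
        return 0.0
    mean_dark_frames = 1.0 / (event_rate_per_s * acq.exposure_s)
    rho = kin.mean_bright_frames / (kin.mean_bright_frames + mean_dark_frames)
    return acq.n_frames * rho


def fov_for(
    n_structures: int,
    min_sep_nm: float = 500.0,
    camera_pixel_nm: float = DEFAULT_CAMERA_PIXEL_NM,
    fill: float = 0.2,
    margin_px: float = 2.0,
) -> tuple[int, int]:
    """Square field of view large enough to place ``n_structures`` comfortably.

    Sizes the inset area so exclusion disks of diameter ``min_sep_nm`` cover
    at most ``fill`` of it (rejection sampling stays fast well below the
    ~0.55 jamming coverage of random sequential adsorption).
    """
    disk_area = np.pi * (min_sep_nm / 2.0) ** 2
    area_nm2 = n_structures * disk_area / fill
    side_px = int(np.ceil(np.sqrt(area_nm2) / camera_pixel_nm + 2 * margin_px))
    return (side_px, side_px)


def place_structures(
    n: int,
    fov_px: tuple[int, int],
    min_sep_nm: float,
    seed: int,
    camera_pixel_nm: float = DEFAULT_CAMERA_PIXEL_NM,
    margin_px: float = 2.0,
    max_tries: int = 100000,
) -> list[tuple[np.ndarray, float]]:
    """Scatter structure centres uniformly with a minimum separation.

    Centres are uniform in the field of view inset by ``margin_px`` on each
    side; rotations i.i.d. uniform on [0, 2*pi).  Placement is by rejection
    sampling; an infeasible packing raises ``RuntimeError`` after
    ``max_tries`` proposals.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    min_sep_px = min_sep_nm / camera_pixel_nm
    lo = np.array([margin_px, margin_px])
    hi = np.array([fov_px[0] - margin_px, fov_px[1] - margin_px])
    if np.any(hi <= lo):
        raise RuntimeError("field of view too small for the requested margin")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} structures at min separation "
                f"{min_sep_nm} nm after {max_tries} proposals; enlarge the "
                "field of view or reduce the separation"
            )
        tries += 1
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(cand - c)) >= min_sep_px for c in centers):
            centers.append(cand)
    rotations = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return [(c, float(r)) for c, r in zip(centers, rotations)]


def _site_bright_frames(
    rng: np.random.Generator,
    n_frames: int,
    mean_dark_frames: float,
    mean_bright_frames: float,
) -> np.ndarray:
    """Frame indices in which one site is bright (alternating renewal)."""
    frames: list[np.ndarray] = []
    t = rng.exponential(mean_dark_frames)
    p_end = 1.0 / mean_bright_frames
    while t < n_frames:
        n_bright = rng.geometric(min(1.0, p_end))
        start = int(np.floor(t))
        stop = min(start + n_bright, n_frames)
        frames.append(np.arange(start, stop))
        t = stop + rng.exponential(mean_dark_frames)
    if not frames:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(frames)


def simulate_acquisition(
    designs: list[DesignSpec] | DesignSpec,
    n_structures: int,
    occupancy: float,
    acq: AcquisitionParams | None = None,
    kin: KineticsNoiseParams | None = None,
    seed: int = 0,
    min_sep_nm: float = 500.0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate one DNA-PAINT acquisition of patterned origami.

    Structures cycle through ``designs`` (round-robin); each of a structure's
    6 sites is independently present with probability ``occupancy``.  The
    returned table is sorted by frame; ground-truth sources are row-aligned
    with it.  Fully deterministic per seed.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy must lie in [0, 1], got {occupancy}")
    acq = acq or AcquisitionParams()
    kin = kin or KineticsNoiseParams()
    if isinstance(designs, DesignSpec):
        designs = [designs]
    rng = np.random.default_rng(seed)
    px_nm = acq.camera_pixel_nm

    poses = place_structures(
        n_structures,
        acq.fov_px,
        min_sep_nm,
        seed=int(rng.integers(2**31)),
        camera_pixel_nm=px_nm,
    )

    event_rate_per_s = kin.dark_rate_per_nM_per_s * acq.imager_conc_nM
    mean_dark_frames = (
        np.inf
        if event_rate_per_s == 0
        else 1.0 / (event_rate_per_s * acq.exposure_s)
    )

    x_parts, y_parts, frame_parts = [], [], []
    kind_parts, sid_parts, site_parts = [], [], []
    struct_rows = []

    for sid, (design, (center, rot)) in enumerate(
        (designs[i % len(designs)], pose) for i, pose in enumerate(poses)
    ):
        present = rng.random(design.n_sites) < occupancy
        sites_px = center + hexagon_coords(design.nominal_edge_nm, rot) / px_nm
        struct_rows.append(
            {
                "structure_id": sid,
                "cx_px": center[0],
                "cy_px": center[1],
                "rotation_rad": rot,
                "design": design.name,
                **{f"site_present_{k}": bool(present[k]) for k in range(6)},
            }
        )
        if kin.mean_bright_frames == 0 or not np.isfinite(mean_dark_frames):
            continue
        for k in np.flatnonzero(present):
            frames = _site_bright_frames(
                rng, acq.n_frames, mean_dark_frames, kin.mean_bright_frames
            )
            if frames.size == 0:
                continue
            noise = rng.normal(0.0, kin.loc_precision_nm / px_nm, size=(frames.size, 2))
            x_parts.append(sites_px[k, 0] + noise[:, 0])
            y_parts.append(sites_px[k, 1] + noise[:, 1])
            frame_parts.append(frames)
            kind_parts.append(np.full(frames.size, "site"))
            sid_parts.append(np.full(frames.size, sid))
            site_parts.append(np.full(frames.size, k))

    # Nonspecific background: homogeneous Poisson in space-time.
    fov_um2 = (acq.fov_px[0] * px_nm / 1000.0) * (acq.fov_px[1] * px_nm / 1000.0)
    n_bg = rng.poisson(kin.bg_rate_per_um2_per_frame * fov_um2 * acq.n_frames)
    if n_bg > 0:
        x_parts.append(rng.random(n_bg) * acq.fov_px[0])
        y_parts.append(rng.random(n_bg) * acq.fov_px[1])
        frame_parts.append(rng.integers(0, acq.n_frames, size=n_bg))
        kind_parts.append(np.full(n_bg, "background"))
        sid_parts.append(np.full(n_bg, -1))
        site_parts.append(np.full(n_bg, -1))

    # Fiducials emit in every frame.
    fid_px = np.zeros((0, 2))
    if kin.n_fiducials > 0:
        fid_px = np.column_stack(
            [
                2.0 + rng.random(kin.n_fiducials) * (acq.fov_px[0] - 4.0),
                2.0 + rng.random(kin.n_fiducials) * (acq.fov_px[1] - 4.0),
            ]
        )
        for fx, fy in fid_px:
            frames = np.arange(acq.n_frames)
            noise = rng.normal(0.0, kin.loc_precision_nm / px_nm, size=(acq.n_frames, 2))
            x_parts.append(fx + noise[:, 0])
            y_parts.append(fy + noise[:, 1])
            frame_parts.append(frames)
            kind_parts.append(np.full(acq.n_frames, "fiducial"))
            sid_parts.append(np.full(acq.n_frames, -1))
            site_parts.append(np.full(acq.n_frames, -1))

    if x_parts:
        x = np.concatenate(x_parts)
        y = np.concatenate(y_parts)
        frame = np.concatenate(frame_parts).astype(np.int64)
        kind = np.concatenate(kind_parts)
        src_sid = np.concatenate(sid_parts).astype(np.int64)
        src_site = np.concatenate(site_parts).astype(np.int64)
    else:
        x = y = np.empty(0)
        frame = src_sid = src_site = np.empty(0, dtype=np.int64)
        kind = np.empty(0, dtype="U10")

    n = x.size
    is_fid = kind == "fiducial"
    photons = np.maximum(rng.normal(kin.photon_mean, kin.photon_sd, size=n), 1.0)
    photons[is_fid] *= kin.fiducial_photon_factor

    sx = kin.psf_sigma_px + rng.normal(0.0, kin.psf_sigma_jitter_px, size=n)
    sy = kin.psf_sigma_px + rng.normal(0.0, kin.psf_sigma_jitter_px, size=n)
    sx = np.maximum(sx, 0.2)
    sy = np.maximum(sy, 0.2)
    # A configurable fraction of background rows gets strongly asymmetric
    # widths so the downstream ellipticity filter has something to reject.
    if kin.junk_fraction > 0 and n_bg > 0:
        bg_idx = np.flatnonzero(kind == "background")
        junk = bg_idx[rng.random(bg_idx.size) < kin.junk_fraction]
        sy[junk] = sx[junk] / rng.uniform(0.02, 0.08, size=junk.size)

    precision = (kin.loc_precision_nm / px_nm) * np.sqrt(kin.photon_mean / photons)

    # Cumulative linear drift, applied to all emitted positions.
    drift = np.asarray(kin.drift_nm_per_frame, dtype=float) / px_nm
    x = x + frame * drift[0]
    y = y + frame * drift[1]

    order = np.argsort(frame, kind="stable")
    df = pd.DataFrame(
        {
            "frame": frame[order],
            "x": x[order],
            "y": y[order],
            "photons": photons[order],
            "sx": sx[order],
            "sy": sy[order],
            "precision": precision[order],
            "ellipticity": np.minimum(sx, sy)[order] / np.maximum(sx, sy)[order],
        }
    )
    sources = pd.DataFrame(
        {
            "kind": kind[order],
            "structure_id": src_sid[order],
            "site_index": src_site[order],
        }
    )
    metadata = {
        "camera_pixel_nm": px_nm,
        "n_frames": acq.n_frames,
        "fov_px": list(acq.fov_px),
        "source": "hexpaint.paint_sim synthetic acquisition",
        "seed": seed,
        "occupancy": occupancy,
        "designs": [d.name for d in designs],
    }
    truth = GroundTruth(pd.DataFrame(struct_rows), sources, fid_px)
    return LocalizationTable(df, metadata), truth
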