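"""Per-ROI peptide-site calling and pattern statistics.

For each origami ROI the member localizations are rendered into a
high-resolution image at the design's oversampling factor, the image is
normalized to [0, 1] and Gaussian-smoothed, and strict 8-neighbourhood local
maxima above a relative intensity threshold are taken as candidate site
positions (refined to sub-pixel accuracy by an intensity-weighted centroid
over a 3x3 window).  Maxima closer than half the designed site distance are
merged; a single-linkage clustering then keeps only the central cluster so
stray maxima from neighbouring structures or residual background do not
inflate the count.  Surviving maxima are the detected peptide sites, from
which per-ROI site counts and the mean nearest-neighbour distance (mean
NND) are computed.  For a complete regular hexagon the mean NND equals the
edge length, so the per-dataset mean-NND distribution measures the realized
pattern size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .designs import DesignSpec
from .loc_io import LocalizationTable
from .roi_detect import OrigamiROI

__all__ = [
    "SiteParams",
    "SiteDetection",
    "PatternSummary",
    "detect_sites",
    "merge_maxima",
    "select_central_cluster",
    "mean_nnd",
    "summarize_patterns",
]


@dataclass(frozen=True)
class SiteParams:
    """Site-calling settings.

    smoothing_sigma_px:
        Gaussian smoothing of the rendered ROI, in super-resolution pixels,
        so the physical smoothing scale follows the per-design oversampling.
    merge_factor:
        Maxima closer than ``merge_factor * nominal_edge_nm`` are merged.
    cluster_link_factor:
        Single-linkage cutoff as a fraction of the design edge.  The default
        2.1 exceeds the hexagon diameter (2 edges = the distance between
        opposite vertices), so *any* subset of a partially occupied hexagon
        stays one cluster; smaller values (e.g. 1.5) split alternate-vertex
        patterns, whose pairwise distances reach sqrt(3)..2 edges, and bias
        site counts low at partial occupancy.
    maxima_rel_threshold:
        Local maxima below this fraction of the smoothed-image maximum are
        ignored as background.
    """

    smoothing_sigma_px: float = 1.0
    merge_factor: float = 0.5
    cluster_link_factor: float = 2.1
    maxima_rel_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.merge_factor < 1:
            raise ValueError("merge_factor must lie in (0, 1)")


@dataclass
class SiteDetection:
    """Called sites for one ROI, in an ROI-local nm frame (origin at the ROI
    centre).  ``mean_nnd_nm`` is None when fewer than two sites were found."""

    roi_id: int
    site_coords_nm: np.ndarray
    n_sites: int
    mean_nnd_nm: float | None


@dataclass
class PatternSummary:
    design: str
    n_rois: int
    sites_per_roi: dict[int, int]
    occupancy_estimate: float
    mean_nnd_values_nm: np.ndarray
    mean_nnd_nm: float
    mean_nnd_sd_nm: float

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_rois": self.n_rois,
            "sites_per_roi": dict(self.sites_per_roi),
            "occupancy_estimate": self.occupancy_estimate,
            "mean_nnd_nm": self.mean_nnd_nm,
            "mean_nnd_sd_nm": self.mean_nnd_sd_nm,
        }


def mean_nnd(points_nm: np.ndarray) -> float:
    """Mean over points of the distance to the nearest other point.

    Requires at least two points (``ValueError`` otherwise).  For the six
    vertices of a regular hexagon with edge *e* this equals *e*; for three
    alternating vertices it equals *e*·sqrt(3).
    """
    pts = np.asarray(points_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("mean_nnd requires at least two points")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def merge_maxima(
    points_nm: np.ndarray,
    min_dist_nm: float,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively merge maxima closer than ``min_dist_nm``.

    The closest violating pair is replaced by its intensity-weighted
    centroid (weights add) until all pairwise distances are >= the
    threshold.  Returns (points, weights).
    """
    if min_dist_nm <= 0:
        raise ValueError("min_dist_nm must be positive")
    pts = np.asarray(points_nm, dtype=float).reshape(-1, 2).copy()
    w = (
        np.ones(len(pts))
        if weights is None
        else np.asarray(weights, dtype=float).copy()
    )
    while len(pts) > 1:
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= min_dist_nm:
            break
        merged = (w[i] * pts[i] + w[j] * pts[j]) / (w[i] + w[j])
        keep = np.ones(len(pts), dtype=bool)
        keep[[i, j]] = False
        pts = np.vstack([pts[keep], merged])
        w = np.append(w[keep], w[i] + w[j])
    return pts, w


def select_central_cluster(
    points_nm: np.ndarray,
    roi_center_nm: np.ndarray | tuple[float, float],
    link_dist_nm: float,
) -> np.ndarray:
    """Keep the largest single-linkage cluster of maxima.

    Clusters are formed with cutoff ``link_dist_nm``; the cluster with the
    most members wins, ties going to the cluster whose centroid is closest
    to ``roi_center_nm``.
    """
    pts = np.asarray(points_nm, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("select_central_cluster requires at least one point")
    if len(pts) == 1:
        return pts.copy()
    center = np.asarray(roi_center_nm, dtype=float)
    labels = fcluster(linkage(pts, method="single"), t=link_dist_nm, criterion="distance")
    best_label, best_key = None, None
    for lab in np.unique(labels):
        members = pts[labels == lab]
        key = (-len(members), float(np.hypot(*(members.mean(axis=0) - center))))
        if best_key is None or key < best_key:
            best_key, best_label = key, lab
    return pts[labels == best_label].copy()


def _local_maxima(img: np.ndarray, rel_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Strict 8-neighbourhood local maxima above ``rel_threshold * img.max()``.

    Returns sub-pixel (row, col) positions (3x3 intensity-weighted centroid)
    and peak intensities.
    """
    if img.max() <= 0:
        return np.zeros((0, 2)), np.zeros(0)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant")
    peaks = (img > neighbor_max) & (img >= rel_threshold * img.max())
    rows, cols = np.nonzero(peaks)
    coords = np.zeros((rows.size, 2))
    for k, (r, c) in enumerate(zip(rows, cols)):
        r0, r1 = max(r - 1, 0), min(r + 2, img.shape[0])
        c0, c1 = max(c - 1, 0), min(c + 2, img.shape[1])
        window = img[r0:r1, c0:c1]
        total = window.sum()
        gi, gj = np.mgrid[r0:r1, c0:c1]
        coords[k] = [(window * gi).sum() / total, (window * gj).sum() / total]
    return coords, img[rows, cols]


def detect_sites(
    table: LocalizationTable,
    roi: OrigamiROI,
    design: DesignSpec,
    params: SiteParams | None = None,
) -> SiteDetection:
    """Call peptide sites in one origami ROI.

    Renders the ROI members at ``design.oversampling``, smooths, finds local
    maxima, merges sub-resolution duplicates, keeps the central cluster and
    reports site coordinates (nm, relative to the ROI centre) and the mean
    nearest-neighbour distance.  An ROI without member localizations raises
    ``ValueError``; a single detected site yields ``mean_nnd_nm = None``.
    """
    params = params or SiteParams()
    members = roi.member_indices
    if members.size == 0:
        raise ValueError(f"ROI {roi.roi_id} has no member localizations")
    px_nm = table.camera_pixel_nm
    bin_nm = px_nm / design.oversampling

    x = table.df["x"].to_numpy()[members] - (roi.center_px[0] - roi.half_width_px)
    y = table.df["y"].to_numpy()[members] - (roi.center_px[1] - roi.half_width_px)
    n_bins = int(np.ceil(2 * roi.half_width_px * design.oversampling))
    img, _, _ = np.histogram2d(
        x,
        y,
        bins=(n_bins, n_bins),
        range=((0, n_bins / design.oversampling), (0, n_bins / design.oversampling)),
    )
    img /= img.max()  # normalize intensity to [0, 1]
    img = ndimage.gaussian_filter(img, params.smoothing_sigma_px)

    coords_bins, intensities = _local_maxima(img, params.maxima_rel_threshold)
    if len(coords_bins) == 0:
        return SiteDetection(roi.roi_id, np.zeros((0, 2)), 0, None)

    # bin indices -> nm in the ROI-local frame (origin at ROI centre)
    half_nm = roi.half_width_px * px_nm
    pts_nm = (coords_bins + 0.5) * bin_nm - half_nm

    pts_nm, weights = merge_maxima(
        pts_nm, params.merge_factor * design.nominal_edge_nm, intensities
    )
    pts_nm = select_central_cluster(
        pts_nm, (0.0, 0.0), params.cluster_link_factor * design.nominal_edge_nm
    )
    n_sites = len(pts_nm)
    nnd = mean_nnd(pts_nm) if n_sites >= 2 else None
    return SiteDetection(roi.roi_id, pts_nm, n_sites, nnd)


def summarize_patterns(
    detections: list[SiteDetection], design: DesignSpec
) -> PatternSummary:
    """Aggregate per-ROI detections into the pattern-level distributions.

    ``occupancy_estimate`` is the mean detected-site count, capped at the
    six designed sites, divided by six; the mean-NND distribution collects
    per-ROI values where at least two sites were found.
    """
    if not detections:
        raise ValueError("summarize_patterns requires at least one detection")
    counts = np.array([d.n_sites for d in detections])
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    occupancy = float(np.minimum(counts, design.n_sites).mean() / design.n_sites)
    nnds = np.array([d.mean_nnd_nm for d in detections if d.mean_nnd_nm is not None])
    return PatternSummary(
        design=design.name,
        n_rois=len(detections),
        sites_per_roi=hist,
        occupancy_estimate=occupancy,
        mean_nnd_values_nm=nnds,
        mean_nnd_nm=float(nnds.mean()) if nnds.size else math.nan,
        mean_nnd_sd_nm=float(nnds.std(ddof=0)) if nnds.size else math.nan,
    )
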