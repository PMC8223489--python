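"""Gel-dosimetry occupancy and cell-viability arithmetic.

Two small, exactly specified calculations used alongside the imaging
pipeline:

* Gel-based peptide quantification: band intensities on a silver-stained
  protein gel are converted to peptide amounts against a peptide-only
  reference lane, and then to a per-lane protrusion-site occupation
  percentage::

      peptide_amount = known_peptide_amount * band_intensity / reference_intensity
      occupation_%   = 100 * peptide_amount / (origami_amount * n_sites)

  Amount units only need to be mutually consistent.  Occupancies above
  100% are reported as-is (with a warning) since intensity noise can
  exceed the bound.

* Viability normalization of a luminescence assay::

      % viable = 100 * (lum_sample - lum_background) / (lum_pbs - lum_background)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "GelLane",
    "ViabilityReading",
    "gel_occupancy",
    "viability_percent",
    "percent_increase",
]


@dataclass(frozen=True)
class GelLane:
    """One gel lane: either the peptide-only reference or an origami sample."""

    label: str
    band_intensity: float
    n_sites: int = 0
    origami_amount: float = 0.0
    is_peptide_reference: bool = False
    known_peptide_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.band_intensity < 0:
            raise ValueError("band_intensity must be >= 0")


def gel_occupancy(lanes: list[GelLane]) -> dict[str, dict[str, float]]:
    """Per-lane peptide amount and protrusion-site occupation percentage.

    Exactly one lane must be the peptide-only reference, with positive band
    intensity; every sample lane needs ``n_sites >= 1`` and a positive
    origami amount.  Returns ``{label: {"peptide_amount": ..,
    "occupancy_percent": ..}}`` for the sample lanes.
    """
    refs = [lane for lane in lanes if lane.is_peptide_reference]
    if len(refs) != 1:
        raise ValueError(f"expected exactly one reference lane, got {len(refs)}")
    ref = refs[0]
    if ref.band_intensity <= 0:
        raise ZeroDivisionError("reference lane band intensity must be positive")
    out: dict[str, dict[str, float]] = {}
    for lane in lanes:
        if lane.is_peptide_reference:
            continue
        if lane.n_sites < 1:
            raise ValueError(
                f"sample lane {lane.label!r} must have n_sites >= 1"
            )
        if lane.origami_amount <= 0:
            raise ValueError(
                f"sample lane {lane.label!r} must have a positive origami amount"
            )
        peptide = ref.known_peptide_amount * lane.band_intensity / ref.band_intensity
        occupancy = 100.0 * peptide / (lane.origami_amount * lane.n_sites)
        if occupancy > 100.0:
            warnings.warn(
                f"lane {lane.label!r}: occupancy {occupancy:.1f}% exceeds 100% "
                "(intensity noise); reported unclipped",
                stacklevel=2,
            )
        out[lane.label] = {
            "peptide_amount": peptide,
            "occupancy_percent": occupancy,
        }
    return out


@dataclass(frozen=True)
class ViabilityReading:
    lum_sample: float
    lum_background: float
    lum_pbs: float

    def __post_init__(self) -> None:
        if self.lum_pbs <= self.lum_background:
            raise ValueError("PBS luminescence must exceed the background")


def viability_percent(reading: ViabilityReading) -> float:
    """Background-subtracted luminescence as percent of the PBS control."""
    return (
        100.0
        * (reading.lum_sample - reading.lum_background)
        / (reading.lum_pbs - reading.lum_background)
    )


def percent_increase(before: float, after: float) -> float:
    """Percent increase from ``before`` to ``after`` (e.g. molecular weight
    5.02 -> 5.06 MDa gives 0.80%)."""
    if before <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (after - before) / before
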