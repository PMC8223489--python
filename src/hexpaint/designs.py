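"""Registry of hexagonal peptide-pattern designs and hexagon geometry.

Each design places six peptide/docking sites on the vertices of a regular
hexagon.  A design's nominal edge length is the mean nucleotide-to-nucleotide
distance of the six hexagon edges as realized on the origami; the registry
models every pattern as a *regular* hexagon with that mean edge, which is the
stated design intent (per-edge deviations are not part of the registry).

Coordinates are in nanometres, in a pattern-local frame centred on the
hexagon centre.  For a regular hexagon the circumradius equals the edge
length, so every vertex lies at ``nominal_edge_nm`` from the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DesignSpec",
    "get_design",
    "list_designs",
    "hexagon_coords",
    "analysis_oversampling",
    "export_registry",
    "import_registry",
]


def hexagon_coords(edge_nm: float, rotation: float = 0.0) -> np.ndarray:
    """Vertices of a regular hexagon centred at the origin.

    Parameters
    ----------
    edge_nm:
        Edge length in nm.  For a regular hexagon this equals the
        circumradius, so all six vertices lie at this distance from the
        centre and adjacent vertices are this distance apart.
    rotation:
        Rigid rotation of the hexagon, radians, counter-clockwise.

    Returns
    -------
    (6, 2) float array of vertex coordinates in nm.
    """
    if edge_nm <= 0:
        raise ValueError(f"hexagon edge length must be positive, got {edge_nm}")
    angles = rotation + np.arange(6) * (math.pi / 3.0)
    return edge_nm * np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass(frozen=True)
class DesignSpec:
    """One registered hexagonal pattern design.

    Attributes
    ----------
    name:
        Registered identifier (e.g. ``"W16"``).
    nominal_edge_nm:
        Mean edge length of the hexagon, nm; also the designed
        nearest-neighbour site distance.
    oversampling:
        Super-resolution rendering factor used when quantifying sites of
        this design (rendering bin = camera pixel / oversampling).
    n_sites:
        Number of designed protrusion sites (always 6).
    """

    name: str
    nominal_edge_nm: float
    oversampling: int
    n_sites: int = 6
    site_coords_nm: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.site_coords_nm is None:
            object.__setattr__(
                self, "site_coords_nm", hexagon_coords(self.nominal_edge_nm)
            )
        coords = np.asarray(self.site_coords_nm, dtype=float)
        coords.setflags(write=False)
        object.__setattr__(self, "site_coords_nm", coords)
        if coords.shape != (self.n_sites, 2):
            raise ValueError("site_coords_nm must be (n_sites, 2)")


# Nominal edges as printed in the pattern names; oversampling follows the
# per-size rendering classes (37->60x, 28->60x, 19->100x, 16->120x, 9->120x,
# 5->150x), with class membership by nearest nominal size.  L6 falls in the
# 5 nm class and L11 in the 9 nm class.
_REGISTRY: dict[str, DesignSpec] = {
    spec.name: spec
    for spec in [
        DesignSpec("W6", 5.7, 150),
        DesignSpec("W9", 9.43, 120),
        DesignSpec("W16", 15.8, 120),
        DesignSpec("W19", 18.8, 100),
        DesignSpec("W26", 25.5, 60),
        DesignSpec("L6", 6.3, 150),
        DesignSpec("L11", 11.1, 120),
        DesignSpec("W37", 37.0, 60),
    ]
}


def list_designs() -> list[str]:
    """Names of all registered designs."""
    return sorted(_REGISTRY)


def get_design(name: str) -> DesignSpec:
    """Look up a registered design by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists valid names.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; valid names: {', '.join(list_designs())}"
        ) from None


def analysis_oversampling(name: str) -> int:
    """Super-resolution rendering factor for a registered design."""
    return get_design(name).oversampling


def export_registry(path: str | Path) -> None:
    """Write the design registry to a YAML file.

    Schema: a mapping ``designs`` of name -> {nominal_edge_nm, oversampling,
    n_sites}.  Site coordinates are not serialized; they are regenerated as a
    regular hexagon on import.
    """
    payload = {
        "designs": {
            d.name: {
                "nominal_edge_nm": d.nominal_edge_nm,
                "oversampling": d.oversampling,
                "n_sites": d.n_sites,
            }
            for d in _REGISTRY.values()
        }
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def import_registry(path: str | Path) -> dict[str, DesignSpec]:
    """Read a design registry written by :func:`export_registry`."""
    payload = yaml.safe_load(Path(path).read_text())
    return {
        name: DesignSpec(
            name,
            float(entry["nominal_edge_nm"]),
            int(entry["oversampling"]),
            n_sites=int(entry.get("n_sites", 6)),
        )
        for name, entry in payload["designs"].items()
    }
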