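#!/usr/bin/env python
"""Worked gel-dosimetry and viability examples, plus the mass-change check.

Runs the printed wet-lab arithmetic on hand-checkable inputs: a peptide-only
reference lane plus three sample lanes, three luminescence readings, and the
origami mass increase on peptide decoration (5.02 -> 5.06 MDa).  Writes
results/wetlab_arithmetic.json.
"""

import json
from pathlib import Path

from hexpaint.wetlab_calc import (
    GelLane,
    ViabilityReading,
    gel_occupancy,
    percent_increase,
    viability_percent,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lanes = [
        GelLane("P", 200.0, is_peptide_reference=True, known_peptide_amount=120.0),
        GelLane("I", 100.0, n_sites=6, origami_amount=10.0),
        GelLane("II", 150.0, n_sites=6, origami_amount=15.0),
        GelLane("C", 0.0, n_sites=6, origami_amount=10.0),
    ]
    gel = gel_occupancy(lanes)

    readings = {
        "untreated_control": ViabilityReading(10500.0, 500.0, 10500.0),
        "treated_half": ViabilityReading(5500.0, 500.0, 10500.0),
        "fully_killed": ViabilityReading(500.0, 500.0, 10500.0),
    }
    viability = {k: viability_percent(r) for k, r in readings.items()}

    out = {
        "gel_occupancy": gel,
        "viability_percent": viability,
        "mw_increase_percent": round(percent_increase(5.02, 5.06), 2),
    }
    (RESULTS / "wetlab_arithmetic.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
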