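"""Published four-cohort counts from the reference NPC cohort (n = 545).

The originating clinical study reported, for the cross of thyroid volume
(cut 20 cm^3) with V_30,60 (cut 80%), the per-cohort patient and 2-year
hypothyroidism event counts.  This module rebuilds a synthetic row-level
dataset carrying exactly those counts — each row gets a representative
volume and band value on the correct side of its cohort's cuts — so the
stratification arithmetic (incidence percentages, merges, totals) can be
validated against the published numbers without the restricted patient
data.  Only the counts are real; the row-level values are placeholders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import TwoYearDataset

__all__ = ["REFERENCE_COUNTS", "REFERENCE_CUTS", "reference_counts_dataset",
           "EXPECTED_INCIDENCE_PCT"]

#: (n, events) per cohort of the volume x band cross, as published
REFERENCE_COUNTS = {
    "cohort1": (50, 4),     # volume > 20 cm^3, V_30,60 <= 80%
    "cohort2": (87, 12),    # volume > 20 cm^3, V_30,60 > 80%
    "cohort3": (166, 33),   # volume <= 20 cm^3, V_30,60 <= 80%
    "cohort4": (242, 89),   # volume <= 20 cm^3, V_30,60 > 80%
}

REFERENCE_CUTS = {"volume_cm3": 20.0, "v30_60": 80.0}

#: published one-decimal incidences: four cohorts, the merged low-risk pair, whole cohort
EXPECTED_INCIDENCE_PCT = {
    "cohort1": 8.0,
    "cohort2": 13.8,
    "cohort3": 19.9,
    "cohort4": 36.8,
    "cohort1+cohort2": 11.7,
    "overall": 25.3,
}

# representative (volume, band) placeholder values per cohort
_PLACEHOLDERS = {
    "cohort1": (25.0, 70.0),
    "cohort2": (25.0, 90.0),
    "cohort3": (15.0, 70.0),
    "cohort4": (15.0, 90.0),
}


def reference_counts_dataset() -> TwoYearDataset:
    """Row-level dataset reproducing the published per-cohort counts."""
    rows = []
    idx = 0
    for label, (n, events) in REFERENCE_COUNTS.items():
        vol, band = _PLACEHOLDERS[label]
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "id": f"R{idx:04d}",
                    "volume_cm3": vol,
                    "v30_60": band,
                    "ht_within_2y": i < events,
                }
            )
    frame = pd.DataFrame(rows)
    # shuffle deterministically so nothing depends on construction order
    frame = frame.sample(frac=1.0, random_state=20_545).reset_index(drop=True)
    return TwoYearDataset(frame=frame, n_excluded=0)
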