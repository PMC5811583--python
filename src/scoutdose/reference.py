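"""Reference cohort of extrahepatic holmium-166 scout-dose depositions.

Six depositions observed after ~250 MBq scout-dose administrations, with
volume measured by the 30%-of-maximum threshold and activity by
un-thresholded margin-ROI summation. The reported dose column is the value
as published at one-decimal precision; recomputing the dose from the
(rounded) printed volume and activity reproduces four rows exactly at one
decimal and the two largest-activity rows within 0.2 Gy, consistent with
the original calculation having used unrounded inputs.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort"]

_ROWS = [
    # patient, location, volume_ml, activity_mbq, reported_dose_gy
    (1, "duodenum", 13.9, 1.3, 1.4),
    (2, "lesser curvature of stomach", 35.5, 33.1, 13.8),
    (3, "duodenum", 15.4, 2.3, 2.2),
    (4, "duodenum", 15.3, 3.7, 3.6),
    (5, "gastric fundus", 9.6, 7.4, 11.7),
    (6, "falciform ligament", 9.2, 0.2, 0.3),
]


def reference_cohort() -> pd.DataFrame:
    """The six-deposition reference cohort as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["patient", "location", "volume_ml", "activity_mbq", "reported_dose_gy"],
    )
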