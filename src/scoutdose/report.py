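"""Human- and machine-readable cohort reporting."""

from __future__ import annotations

import pandas as pd

from .dosimetry import CohortSummary, DepositionRecord, cohort_summary

__all__ = ["render_cohort_table", "cohort_frame"]


def cohort_frame(records: list[DepositionRecord]) -> pd.DataFrame:
    """One row per deposition, values at full precision."""
    return pd.DataFrame(
        {
            "volume_ml": [r.volume_ml for r in records],
            "activity_mbq": [r.activity_mbq for r in records],
            "dose_gy": [r.dose_gy for r in records],
            "threshold_fraction": [r.threshold_fraction for r in records],
            "mask_label": [r.mask_label for r in records],
        }
    )


def render_cohort_table(records: list[DepositionRecord]) -> str:
    """Cohort table at one-decimal display precision plus summary rows.

    Columns: Volume (ml), Activity (MBq), Estimated dose (Gy). The summary
    block reports min, max, and the three even-n median conventions (lower,
    standard, upper); small published cohorts differ in which convention
    their printed medians follow, so all three are shown.
    """
    if not records:
        raise ValueError("no records to render")
    summary: CohortSummary = cohort_summary(records)
    header = f"{'':14s} {'Volume (ml)':>12s} {'Activity (MBq)':>15s} {'Dose (Gy)':>10s}"
    lines = [header, "-" * len(header)]
    for i, r in enumerate(records, start=1):
        lines.append(
            f"{'record ' + str(i):14s} {r.volume_ml:12.1f} {r.activity_mbq:15.1f} "
            f"{r.dose_gy:10.1f}"
        )
    lines.append("-" * len(header))
    for stat in ("min", "lower_median", "median", "upper_median", "max"):
        lines.append(
            f"{stat:14s} {summary['volume_ml'][stat]:12.1f} "
            f"{summary['activity_mbq'][stat]:15.1f} {summary['dose_gy'][stat]:10.1f}"
        )
    return "\n".join(lines)
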