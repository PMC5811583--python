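"""Phantom calibration of the volume-delineation threshold.

The delineation threshold (a fraction of the maximum voxel value inside the
margin ROI) is calibrated on an image-quality phantom with spheres of known
volume and activity concentration: candidate thresholds are swept, each
sphere's volume and dose are estimated at each threshold, and the selected
threshold is the smallest one at which no sphere at or above a minimum
volume is over-estimated. Smaller thresholds give less volume
underestimation, so the smallest admissible one is the least conservative
choice that still guarantees the dose is never underestimated for objects
above the minimum volume. The smallest phantom sphere (0.5 ml) is excluded
by the default 1 ml minimum: at clinically negligible volumes both volume
and activity are underestimated and the dose guarantee does not hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DoseConstants, RoiMask, VoxelImage
from .dosimetry import absorbed_dose, estimate_activity, estimate_volume
from .synthetic import PhantomSpec, generate_phantom, sphere_margin_masks

__all__ = [
    "DEFAULT_THRESHOLD_GRID",
    "ThresholdSweepResult",
    "sweep_thresholds",
    "select_threshold",
    "calibrate_phantom",
]

#: Candidate threshold fractions, 0.05 to 0.95 in steps of 0.05.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class ThresholdSweepResult:
    """Per-sphere volume and dose estimates on a grid of thresholds.

    Attributes
    ----------
    thresholds : array, shape (T,)
    est_volume_ml, est_dose_gy : arrays, shape (S, T)
    est_activity_mbq, true_volume_ml, true_activity_mbq, true_dose_gy :
        arrays, shape (S,)
    selected_threshold : float or None
        Populated by :func:`select_threshold`.
    """

    thresholds: np.ndarray
    est_volume_ml: np.ndarray
    est_dose_gy: np.ndarray
    est_activity_mbq: np.ndarray
    true_volume_ml: np.ndarray
    true_activity_mbq: np.ndarray
    true_dose_gy: np.ndarray
    selected_threshold: float | None = None

    @property
    def n_spheres(self) -> int:
        return len(self.true_volume_ml)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (sphere, threshold)."""
        rows = []
        for s in range(self.n_spheres):
            for t, thr in enumerate(self.thresholds):
                rows.append(
                    {
                        "sphere": s,
                        "threshold_fraction": float(thr),
                        "est_volume_ml": float(self.est_volume_ml[s, t]),
                        "est_dose_gy": float(self.est_dose_gy[s, t]),
                        "true_volume_ml": float(self.true_volume_ml[s]),
                        "true_activity_mbq": float(self.true_activity_mbq[s]),
                        "true_dose_gy": float(self.true_dose_gy[s]),
                        "volume_ratio": float(self.est_volume_ml[s, t] / self.true_volume_ml[s]),
                        "dose_ratio": float(self.est_dose_gy[s, t] / self.true_dose_gy[s])
                        if self.true_dose_gy[s] > 0
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Threshold sweep over {len(self.thresholds)} fractions, "
            f"{self.n_spheres} spheres",
        ]
        if self.selected_threshold is not None:
            lines.append(f"selected threshold: {self.selected_threshold:.2f} of max voxel")
        for s in range(self.n_spheres):
            lines.append(
                f"  sphere {s}: true V {self.true_volume_ml[s]:.1f} ml, "
                f"true D {self.true_dose_gy[s]:.2f} Gy"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Volume- and dose-ratio curves vs threshold (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4))
        for s in range(self.n_spheres):
            lbl = f"{self.true_volume_ml[s]:.1f} ml"
            ax[0].plot(self.thresholds, self.est_volume_ml[s] / self.true_volume_ml[s], label=lbl)
            if self.true_dose_gy[s] > 0:
                ax[1].plot(self.thresholds, self.est_dose_gy[s] / self.true_dose_gy[s], label=lbl)
        for a, ylab in zip(ax, ("estimated / true volume", "estimated / true dose")):
            a.axhline(1.0, color="k", lw=0.8, ls="--")
            if self.selected_threshold is not None:
                a.axvline(self.selected_threshold, color="r", lw=0.8)
            a.set_xlabel("threshold (fraction of max voxel)")
            a.set_ylabel(ylab)
        ax[0].legend(fontsize=7)
        return ax


def sweep_thresholds(
    phantom_image: VoxelImage,
    sphere_masks: tuple[RoiMask, ...],
    truth_table: pd.DataFrame,
    grid=DEFAULT_THRESHOLD_GRID,
    constants: DoseConstants = DoseConstants(),
) -> ThresholdSweepResult:
    """Estimate every sphere's volume and dose at every candidate threshold.

    ``truth_table`` must carry one row per margin mask with
    ``true_volume_ml`` and ``true_activity_mbq`` columns (the phantom
    ground truth); true dose is the known activity booked to the known
    volume.
    """
    if len(sphere_masks) != len(truth_table):
        raise ValueError(
            f"{len(sphere_masks)} margin masks but {len(truth_table)} ground-truth rows"
        )
    thresholds = np.asarray(sorted(float(t) for t in grid))
    if thresholds.size == 0 or thresholds[0] <= 0 or thresholds[-1] > 1:
        raise ValueError("threshold grid must be nonempty with fractions in (0, 1]")
    S, T = len(sphere_masks), thresholds.size
    est_v = np.empty((S, T))
    est_d = np.empty((S, T))
    est_a = np.empty(S)
    true_v = truth_table["true_volume_ml"].to_numpy(dtype=float)
    true_a = truth_table["true_activity_mbq"].to_numpy(dtype=float)
    true_d = np.array([absorbed_dose(a, v, constants) for a, v in zip(true_a, true_v)])
    for s, mask in enumerate(sphere_masks):
        est_a[s] = estimate_activity(phantom_image, mask)
        for t, thr in enumerate(thresholds):
            est_v[s, t] = estimate_volume(phantom_image, mask, float(thr))
            est_d[s, t] = absorbed_dose(est_a[s], est_v[s, t], constants)
    return ThresholdSweepResult(
        thresholds=thresholds,
        est_volume_ml=est_v,
        est_dose_gy=est_d,
        est_activity_mbq=est_a,
        true_volume_ml=true_v,
        true_activity_mbq=true_a,
        true_dose_gy=true_d,
    )


def select_threshold(
    sweep: ThresholdSweepResult,
    min_volume_ml: float = 1.0,
    rel_tol: float = 0.0,
) -> float:
    """Smallest grid threshold that never over-estimates a sphere's volume.

    Only spheres with true volume >= ``min_volume_ml`` participate in the
    criterion (default 1 ml). ``rel_tol`` optionally admits estimates up to
    ``true * (1 + rel_tol)``; the default is the strict reading. Raises if
    no grid fraction qualifies, listing the offending spheres at the
    largest threshold.
    """
    eligible = sweep.true_volume_ml >= min_volume_ml
    if not np.any(eligible):
        raise ValueError(f"no sphere has true volume >= {min_volume_ml} ml")
    limit = sweep.true_volume_ml[eligible, None] * (1.0 + rel_tol)
    ok_per_threshold = np.all(sweep.est_volume_ml[eligible, :] <= limit, axis=0)
    hits = np.flatnonzero(ok_per_threshold)
    if hits.size == 0:
        worst = np.flatnonzero(
            sweep.est_volume_ml[:, -1] > sweep.true_volume_ml * (1.0 + rel_tol)
        )
        raise ValueError(
            "no threshold on the grid avoids volume over-estimation; "
            f"offending sphere indices at the largest threshold: {worst.tolist()}"
        )
    selected = float(sweep.thresholds[hits[0]])
    sweep.selected_threshold = selected
    return selected


def calibrate_phantom(
    spec: PhantomSpec | None = None,
    grid=DEFAULT_THRESHOLD_GRID,
    min_volume_ml: float = 1.0,
    constants: DoseConstants = DoseConstants(),
) -> ThresholdSweepResult:
    """Generate the phantom, sweep thresholds, and select one, end to end."""
    spec = spec or PhantomSpec()
    image, truth = generate_phantom(spec)
    masks = sphere_margin_masks(spec)
    sweep = sweep_thresholds(image, masks, truth, grid=grid, constants=constants)
    select_threshold(sweep, min_volume_ml=min_volume_ml)
    return sweep
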