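"""Lung shunt fraction from anterior/posterior planar scintigraphy.

The lung shunt fraction (LSF) is the fraction of administered activity that
bypasses the liver to the lungs. It is computed from lung and liver ROI
count sums on conjugate planar views via the geometric mean, which cancels
a depth-dependent exponential attenuation factor common to both views:

    LSF = sqrt(L_ant * L_post) / (sqrt(L_ant * L_post) + sqrt(H_ant * H_post))

with L the lung and H the liver ROI counts. The result is a fraction in
[0, 1]; percentage formatting belongs to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import PlanarImage, RoiMask, mask_sum

__all__ = ["LsfInputs", "lung_shunt_fraction", "lsf_from_planar"]


@dataclass(frozen=True)
class LsfInputs:
    """The four planar ROI count sums entering the LSF equation."""

    lungs_anterior: float
    lungs_posterior: float
    liver_anterior: float
    liver_posterior: float

    def __post_init__(self) -> None:
        for name in ("lungs_anterior", "lungs_posterior", "liver_anterior", "liver_posterior"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def lung_geometric_mean(self) -> float:
        return math.sqrt(self.lungs_anterior * self.lungs_posterior)

    @property
    def liver_geometric_mean(self) -> float:
        return math.sqrt(self.liver_anterior * self.liver_posterior)


def lung_shunt_fraction(inputs: LsfInputs) -> float:
    """Geometric-mean lung shunt fraction, in [0, 1].

    One organ's geometric mean may be zero (LSF 0 or 1); both zero leaves
    the fraction undefined and raises ``ValueError``.
    """
    lung = inputs.lung_geometric_mean
    liver = inputs.liver_geometric_mean
    denom = lung + liver
    if denom == 0:
        raise ValueError(
            "lung shunt fraction undefined: both lung and liver geometric means are zero"
        )
    return lung / denom


def lsf_from_planar(
    anterior: PlanarImage,
    posterior: PlanarImage,
    lung_masks: tuple[RoiMask, RoiMask],
    liver_masks: tuple[RoiMask, RoiMask],
) -> float:
    """LSF from two planar images and (anterior, posterior) ROI mask pairs."""
    inputs = LsfInputs(
        lungs_anterior=mask_sum(anterior, lung_masks[0]),
        lungs_posterior=mask_sum(posterior, lung_masks[1]),
        liver_anterior=mask_sum(anterior, liver_masks[0]),
        liver_posterior=mask_sum(posterior, liver_masks[1]),
    )
    return lung_shunt_fraction(inputs)
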