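"""Voxel/planar image containers, ROI masks, and NIfTI/CSV I/O.

Conventions: voxel indices are 0-based; physical coordinates refer to voxel
centers; voxel values are activity in Bq (3-D) or detector counts (2-D).
Every other module builds on the types here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelImage",
    "PlanarImage",
    "RoiMask",
    "DoseConstants",
    "mask_sum",
    "voxel_volume_ml",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_planar_csv",
    "write_planar_csv",
]


def _validate_grid(values: np.ndarray, ndim: int, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != ndim:
        raise ValueError(f"{what} must be {ndim}-D, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite values")
    if np.any(values < 0):
        raise ValueError(f"{what} contains negative values")
    return values


@dataclass(frozen=True)
class VoxelImage:
    """A 3-D grid of activity values (Bq) with physical voxel spacing (mm).

    Parameters
    ----------
    values
        Non-negative activity per voxel in Bq, shape ``(nx, ny, nz)``.
    spacing
        Voxel edge lengths in mm per axis, all strictly positive.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_grid(self.values, 3, "voxel image"))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError(f"origin must have three components, got {self.origin}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self)

    def total(self) -> float:
        """Grand total of all voxel values (Bq)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class PlanarImage:
    """A 2-D planar count image with pixel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float] = (4.8, 4.8)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_grid(self.values, 2, "planar image"))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 2 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be two positive lengths, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class RoiMask:
    """A boolean region-of-interest mask congruent with its target image."""

    selected: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        selected = np.asarray(self.selected)
        if selected.dtype != bool:
            uniq = np.unique(selected)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be boolean or 0/1, got {uniq[:8]}")
            selected = selected.astype(bool)
        object.__setattr__(self, "selected", selected)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.selected.shape

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def __invert__(self) -> "RoiMask":
        return RoiMask(~self.selected, label=f"not({self.label})" if self.label else "")

    def __or__(self, other: "RoiMask") -> "RoiMask":
        return RoiMask(self.selected | other.selected, label=self.label or other.label)


@dataclass(frozen=True)
class DoseConstants:
    """Physical constants of the holmium-166 beta absorbed-dose formula.

    ``energy_per_activity`` is the total beta energy absorbed in tissue per
    unit of administered activity (mJ/MBq); ``tissue_density`` is the assumed
    soft-tissue density (g/cm3).
    """

    energy_per_activity: float = 15.87  # mJ/MBq, Ho-166 beta branch
    tissue_density: float = 1.06  # g/cm3 soft tissue

    def __post_init__(self) -> None:
        if self.energy_per_activity <= 0 or self.tissue_density <= 0:
            raise ValueError("dose constants must be strictly positive")


def mask_sum(image: VoxelImage | PlanarImage, mask: RoiMask) -> float:
    """Sum image values over the selected positions of ``mask``.

    Returns Bq for voxel images, counts for planar images; an empty mask
    sums to 0. Raises ``ValueError`` when the grids are not congruent.
    """
    if image.values.shape != mask.selected.shape:
        raise ValueError(
            f"mask shape {mask.selected.shape} does not match image shape {image.values.shape}"
        )
    return float(image.values[mask.selected].sum())


def voxel_volume_ml(image: VoxelImage) -> float:
    """Physical volume of one voxel in ml (= cm3)."""
    return float(np.prod(image.spacing)) / 1000.0


# ---------------------------------------------------------------------------
# I/O. 3-D images and masks travel as NIfTI; planar images as plain CSV so
# that test fixtures stay inspectable.
# ---------------------------------------------------------------------------


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_image(image: VoxelImage, path: str | Path) -> None:
    """Write a voxel image as NIfTI (.nii or .nii.gz)."""
    import nibabel as nib

    nifti = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.spacing, image.origin))
    nifti.header.set_zooms(image.spacing)
    nib.save(nifti, str(path))


def read_image(path: str | Path) -> VoxelImage:
    """Read a NIfTI voxel image; spacing from the affine diagonal, origin
    from its translation column."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        nifti = nib.load(str(path))
        values = np.asarray(nifti.dataobj, dtype=float)
        aff = nifti.affine
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if values.ndim != 3:
        raise ValueError(f"cannot read image {path}: expected 3-D data, got shape {values.shape}")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelImage(values, spacing, origin)


def write_mask(mask: RoiMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a 3-D ROI mask as a 0/1 uint8 NIfTI volume."""
    import nibabel as nib

    nifti = nib.Nifti1Image(mask.selected.astype(np.uint8), _affine(spacing, (0.0, 0.0, 0.0)))
    nifti.header.set_zooms(spacing)
    nib.save(nifti, str(path))


def read_mask(path: str | Path, label: str = "") -> RoiMask:
    """Read a 0/1 NIfTI volume as an ROI mask."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    data = np.asarray(nib.load(str(path)).dataobj)
    return RoiMask(data != 0, label=label or path.stem)


def write_planar_csv(image: PlanarImage, path: str | Path) -> None:
    header = f"spacing_mm,{image.spacing[0]},{image.spacing[1]}"
    np.savetxt(str(path), image.values, delimiter=",", header=header, comments="# ")


def read_planar_csv(path: str | Path) -> PlanarImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"planar image file not found: {path}")
    spacing = (4.8, 4.8)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        parts = first.lstrip("# ").strip().split(",")
        if parts[0] == "spacing_mm":
            spacing = (float(parts[1]), float(parts[2]))
    values = np.loadtxt(str(path), delimiter=",", comments="#", ndmin=2)
    return PlanarImage(values, spacing)


def read_planar_mask_csv(path: str | Path, label: str = "") -> RoiMask:
    """Read a 2-D 0/1 CSV grid as a planar ROI mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    values = np.loadtxt(str(path), delimiter=",", comments="#", ndmin=2)
    return RoiMask(values != 0, label=label or path.stem)
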