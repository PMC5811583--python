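"""Synthetic quantitative SPECT-like scenes with known ground truth.

Two families of scenes are generated on a physical voxel grid:

* an image-quality phantom — six fillable spheres (0.5–26.5 ml) suspended in
  a 9.7 L water compartment, used to calibrate the volume-delineation
  threshold; and
* a patient-like scene — a large hepatic activity distribution, optional lung
  activity, and a small extrahepatic deposition with known activity and
  volume.

The imaging chain is deliberately simple: partial-volume-aware rasterization
(sub-voxel sampling), an isotropic Gaussian point-spread function with a
sum-preserving kernel, and optional voxel-wise Poisson noise from a seeded
generator. Collimator response, scatter, and photon transport are out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import PlanarImage, RoiMask, VoxelImage

__all__ = [
    "SphereSpec",
    "PhantomSpec",
    "PatientSceneSpec",
    "PatientScene",
    "NEMA_SPHERE_VOLUMES_ML",
    "generate_phantom",
    "generate_patient_scene",
    "project_planar",
    "sphere_margin_masks",
]

# Inner volumes (ml) of the six fillable spheres of the NEMA NU2 image-quality
# phantom (10–37 mm inner diameter), ordered small to large.
NEMA_SPHERE_VOLUMES_ML: tuple[float, ...] = (0.5, 1.2, 2.6, 5.6, 11.5, 26.5)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume (ml); 1 ml = 1000 mm3."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SphereSpec:
    """One hot sphere: physical center (mm), true volume (ml), and activity
    concentration (MBq/ml)."""

    center: tuple[float, float, float]
    volume_ml: float
    concentration_mbq_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(f"sphere volume must be > 0, got {self.volume_ml}")
        if self.concentration_mbq_ml < 0:
            raise ValueError("sphere concentration must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius_mm(self) -> float:
        return sphere_radius_mm(self.volume_ml)

    @property
    def activity_mbq(self) -> float:
        return self.volume_ml * self.concentration_mbq_ml


def _default_nema_spheres(concentration: float = 1.0) -> tuple[SphereSpec, ...]:
    # Ring of radius 85 mm in the central transverse plane. Volumes are
    # interleaved around the ring so that the generous margin regions used
    # for per-sphere quantification stay pairwise disjoint.
    ring_order = (26.5, 0.5, 5.6, 2.6, 11.5, 1.2)
    rho = 85.0
    spheres = []
    for k, vol in enumerate(ring_order):
        ang = math.pi / 2 + k * math.pi / 3
        spheres.append(
            SphereSpec(
                center=(rho * math.cos(ang), rho * math.sin(ang), 0.0),
                volume_ml=vol,
                concentration_mbq_ml=concentration,
            )
        )
    return tuple(spheres)


@dataclass(frozen=True)
class PhantomSpec:
    """Image-quality phantom: six hot spheres in a water compartment.

    The background compartment is a 9.7 L cylinder, cold by default (its
    concentration may be raised for hot-background studies). ``psf_fwhm_mm``
    is the isotropic Gaussian system resolution; ``counts_per_bq`` scales
    voxel activity into Poisson count space when noise is enabled.
    """

    spheres: tuple[SphereSpec, ...] = field(default_factory=_default_nema_spheres)
    background_volume_l: float = 9.7
    background_concentration_mbq_ml: float = 0.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)
    psf_fwhm_mm: float = 12.0
    noise_enabled: bool = False
    counts_per_bq: float = 1.0
    subsample: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.background_volume_l <= 0 or self.background_concentration_mbq_ml < 0:
            raise ValueError("invalid background specification")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        object.__setattr__(self, "spheres", tuple(self.spheres))


@dataclass(frozen=True)
class PatientSceneSpec:
    """Patient-like scene: liver + lungs (ellipsoids) and one small
    extrahepatic deposition (sphere) with known total activities (MBq).

    Defaults emulate a ~250 MBq scout-dose administration with a 13.2%
    lung shunt and a 3.7 MBq deposition of 15.3 ml — the upper-median
    extrahepatic regime of the safety cohort this package models.
    """

    liver_center_mm: tuple[float, float, float] = (-45.0, 0.0, -60.0)
    liver_semiaxes_mm: tuple[float, float, float] = (80.0, 60.0, 50.0)
    liver_activity_mbq: float = 217.0
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (-50.0, 0.0, 95.0),
        (50.0, 0.0, 95.0),
    )
    lung_semiaxes_mm: tuple[float, float, float] = (32.0, 40.0, 45.0)
    lung_activity_mbq: float = 33.0
    deposition_center_mm: tuple[float, float, float] = (95.0, 55.0, -60.0)
    deposition_volume_ml: float = 15.3
    deposition_activity_mbq: float = 3.7
    grid_shape: tuple[int, int, int] = (64, 64, 72)
    spacing_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)
    psf_fwhm_mm: float = 12.0
    noise_enabled: bool = False
    counts_per_bq: float = 1.0
    subsample: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.liver_activity_mbq, self.lung_activity_mbq, self.deposition_activity_mbq):
            if a < 0:
                raise ValueError("activities must be >= 0")
        if self.deposition_volume_ml <= 0:
            raise ValueError("deposition volume must be > 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")


# ---------------------------------------------------------------------------
# Rasterization helpers
# ---------------------------------------------------------------------------


def _centered_origin(shape: tuple[int, ...], spacing: tuple[float, ...]) -> tuple[float, ...]:
    return tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))


def _axis_coords(shape, spacing, origin):
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def _fill_fraction(
    shape, spacing, origin, z_interval_fn, bbox_lo_mm, bbox_hi_mm, subsample: int
) -> np.ndarray:
    """Fractional fill per voxel for a region that is z-convex.

    ``z_interval_fn(x, y) -> (zlo, zhi)`` returns, for arrays of in-plane
    coordinates, the region's z-extent through each column (``zhi < zlo``
    where the column misses the region). Each voxel's in-plane face is
    sampled on a ``subsample``^2 grid of sub-pixel centers; the overlap of
    the exact z-chord with the voxel's z-extent is integrated analytically.
    This keeps the rasterization error to the in-plane midpoint quadrature
    only, which is what makes sub-percent activity conservation possible at
    4.8 mm voxels. Returns a full-grid float array of fill fractions.
    """
    frac = np.zeros(shape)
    idx_lo, idx_hi = [], []
    for a in range(3):
        lo = int(math.floor((bbox_lo_mm[a] - origin[a]) / spacing[a] - 0.5))
        hi = int(math.ceil((bbox_hi_mm[a] - origin[a]) / spacing[a] + 0.5))
        idx_lo.append(max(lo, 0))
        idx_hi.append(min(hi, shape[a] - 1))
    if any(idx_lo[a] > idx_hi[a] for a in range(3)):
        return frac
    n = subsample
    offsets = (np.arange(n) + 0.5) / n - 0.5  # voxel units
    sub_axes = []
    for a in (0, 1):
        centers = origin[a] + np.arange(idx_lo[a], idx_hi[a] + 1) * spacing[a]
        sub_axes.append((centers[:, None] + offsets[None, :] * spacing[a]).ravel())
    X = sub_axes[0][:, None]
    Y = sub_axes[1][None, :]
    zlo, zhi = z_interval_fn(X, Y)
    kz = np.arange(idx_lo[2], idx_hi[2] + 1)
    z_bot = origin[2] + (kz - 0.5) * spacing[2]
    z_top = z_bot + spacing[2]
    overlap = np.clip(
        np.minimum(zhi[:, :, None], z_top[None, None, :])
        - np.maximum(zlo[:, :, None], z_bot[None, None, :]),
        0.0,
        None,
    ) / spacing[2]
    nx = idx_hi[0] - idx_lo[0] + 1
    ny = idx_hi[1] - idx_lo[1] + 1
    frac[idx_lo[0] : idx_hi[0] + 1, idx_lo[1] : idx_hi[1] + 1, idx_lo[2] : idx_hi[2] + 1] = (
        overlap.reshape(nx, n, ny, n, len(kz)).mean(axis=(1, 3))
    )
    return frac


def _sphere_fraction(shape, spacing, origin, center, radius, subsample) -> np.ndarray:
    lo = tuple(c - radius for c in center)
    hi = tuple(c + radius for c in center)
    r2 = radius * radius

    def z_interval(x, y):
        t = r2 - (x - center[0]) ** 2 - (y - center[1]) ** 2
        half = np.sqrt(np.clip(t, 0.0, None))
        zlo = np.where(t >= 0, center[2] - half, 1.0)
        zhi = np.where(t >= 0, center[2] + half, 0.0)
        return zlo, zhi

    return _fill_fraction(shape, spacing, origin, z_interval, lo, hi, subsample)


def _ellipsoid_fraction(shape, spacing, origin, center, semiaxes, subsample) -> np.ndarray:
    lo = tuple(c - s for c, s in zip(center, semiaxes))
    hi = tuple(c + s for c, s in zip(center, semiaxes))
    a, b, c3 = semiaxes

    def z_interval(x, y):
        t = 1.0 - ((x - center[0]) / a) ** 2 - ((y - center[1]) / b) ** 2
        half = c3 * np.sqrt(np.clip(t, 0.0, None))
        zlo = np.where(t >= 0, center[2] - half, 1.0)
        zhi = np.where(t >= 0, center[2] + half, 0.0)
        return zlo, zhi

    return _fill_fraction(shape, spacing, origin, z_interval, lo, hi, subsample)


def _cylinder_fraction(shape, spacing, origin, radius, height, subsample) -> np.ndarray:
    # z-axis cylinder centered on the grid center
    lo = (-radius, -radius, -height / 2)
    hi = (radius, radius, height / 2)
    r2 = radius * radius

    def z_interval(x, y):
        hit = x * x + y * y <= r2
        zlo = np.where(hit, -height / 2, 1.0)
        zhi = np.where(hit, height / 2, 0.0)
        return zlo, zhi

    return _fill_fraction(shape, spacing, origin, z_interval, lo, hi, subsample)


def _check_inside_grid(lo_mm, hi_mm, shape, spacing, origin, margin_mm, what: str) -> None:
    for a in range(3):
        edge_lo = origin[a] - 0.5 * spacing[a]
        edge_hi = origin[a] + (shape[a] - 0.5) * spacing[a]
        if lo_mm[a] - margin_mm < edge_lo or hi_mm[a] + margin_mm > edge_hi:
            raise ValueError(
                f"{what} does not fit inside the grid with the required "
                f"{margin_mm:.1f} mm blur margin (axis {a})"
            )


def _blur(values: np.ndarray, spacing, fwhm_mm: float) -> np.ndarray:
    """Isotropic Gaussian blur with a normalized (sum-preserving) kernel."""
    if fwhm_mm == 0:
        return values
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
    return ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant", truncate=4.0)


def _apply_noise(values: np.ndarray, counts_per_bq: float, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(values * counts_per_bq)
    return counts.astype(float) / counts_per_bq


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelImage, pd.DataFrame]:
    """Rasterize, blur, and optionally noise the image-quality phantom.

    Returns the voxel image (Bq) and a ground-truth table with one row per
    sphere: true volume (ml), concentration (MBq/ml), and true activity
    (MBq). Spheres must be pairwise disjoint and fit in the grid with a
    margin of at least twice the PSF FWHM.
    """
    shape, spacing = tuple(spec.grid_shape), tuple(spec.spacing_mm)
    origin = _centered_origin(shape, spacing)
    margin = 2.0 * spec.psf_fwhm_mm

    for i, a in enumerate(spec.spheres):
        for b in spec.spheres[i + 1 :]:
            d = math.dist(a.center, b.center)
            if d < a.radius_mm + b.radius_mm:
                raise ValueError(
                    f"spheres at {a.center} and {b.center} overlap "
                    f"(center distance {d:.1f} mm < radius sum)"
                )
    voxel_ml = float(np.prod(spacing)) / 1000.0
    ideal = np.zeros(shape)
    sphere_frac_total = np.zeros(shape)
    rows = []
    for k, sph in enumerate(spec.spheres):
        r = sph.radius_mm
        lo = tuple(c - r for c in sph.center)
        hi = tuple(c + r for c in sph.center)
        _check_inside_grid(lo, hi, shape, spacing, origin, margin, f"sphere {k}")
        frac = _sphere_fraction(shape, spacing, origin, sph.center, r, spec.subsample)
        sphere_frac_total += frac
        ideal += frac * sph.concentration_mbq_ml * 1e6 * voxel_ml
        rows.append(
            {
                "sphere": k,
                "center_x_mm": sph.center[0],
                "center_y_mm": sph.center[1],
                "center_z_mm": sph.center[2],
                "true_volume_ml": sph.volume_ml,
                "concentration_mbq_ml": sph.concentration_mbq_ml,
                "true_activity_mbq": sph.activity_mbq,
            }
        )
    if spec.background_concentration_mbq_ml > 0:
        radius = 110.0
        height = spec.background_volume_l * 1e6 / (math.pi * radius * radius)
        bg = _cylinder_fraction(shape, spacing, origin, radius, height, spec.subsample)
        bg = np.clip(bg - sphere_frac_total, 0.0, None)
        ideal += bg * spec.background_concentration_mbq_ml * 1e6 * voxel_ml

    values = _blur(ideal, spacing, spec.psf_fwhm_mm)
    if spec.noise_enabled:
        rng = np.random.default_rng(spec.seed)
        values = _apply_noise(values, spec.counts_per_bq, rng)
    truth = pd.DataFrame(rows)
    truth.attrs.update(seed=spec.seed, psf_fwhm_mm=spec.psf_fwhm_mm, noise=spec.noise_enabled)
    return VoxelImage(values, spacing, origin), truth


def sphere_margin_masks(
    spec: PhantomSpec, margin_mm: float | None = None
) -> tuple[RoiMask, ...]:
    """One generous margin mask per phantom sphere.

    Each mask selects all voxels whose center lies within ``radius +
    margin_mm`` of the sphere center, emulating the manual delineation that
    takes a wide margin around a deposition to capture displaced counts. The
    default margin, twice the PSF FWHM plus one voxel, covers the truncated
    Gaussian blur support entirely. Masks must come out pairwise disjoint.
    """
    shape, spacing = tuple(spec.grid_shape), tuple(spec.spacing_mm)
    origin = _centered_origin(shape, spacing)
    if margin_mm is None:
        margin_mm = 2.0 * spec.psf_fwhm_mm + max(spacing)
    coords = _axis_coords(shape, spacing, origin)
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    masks = []
    for k, sph in enumerate(spec.spheres):
        d2 = (
            (X - sph.center[0]) ** 2 + (Y - sph.center[1]) ** 2 + (Z - sph.center[2]) ** 2
        )
        sel = d2 <= (sph.radius_mm + margin_mm) ** 2
        masks.append(RoiMask(sel, label=f"sphere_{k}_margin"))
    overlap = sum(m.selected.astype(int) for m in masks)
    if np.any(overlap > 1):
        raise ValueError("sphere margin masks overlap; reduce margin_mm or respace spheres")
    return tuple(masks)


# ---------------------------------------------------------------------------
# Patient scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientScene:
    """A generated patient-like scene: image, deposition margin mask, organ
    labels for planar projection, and the ground-truth record."""

    image: VoxelImage
    margin_mask: RoiMask
    labels: dict[str, RoiMask]
    truth: dict[str, float]


def generate_patient_scene(spec: PatientSceneSpec) -> PatientScene:
    """Generate a blurred (optionally noised) patient-like scene.

    The returned margin mask covers the deposition's entire blurred support
    while excluding liver and lung voxels; the deposition must be disjoint
    from the liver and fit in the grid with the PSF margin.
    """
    shape, spacing = tuple(spec.grid_shape), tuple(spec.spacing_mm)
    origin = _centered_origin(shape, spacing)
    margin = 2.0 * spec.psf_fwhm_mm
    voxel_ml = float(np.prod(spacing)) / 1000.0

    r_dep = sphere_radius_mm(spec.deposition_volume_ml)
    dep_lo = tuple(c - r_dep for c in spec.deposition_center_mm)
    dep_hi = tuple(c + r_dep for c in spec.deposition_center_mm)
    _check_inside_grid(dep_lo, dep_hi, shape, spacing, origin, margin, "deposition")

    liver_frac = _ellipsoid_fraction(
        shape, spacing, origin, spec.liver_center_mm, spec.liver_semiaxes_mm, spec.subsample
    )
    lung_frac = np.zeros(shape)
    for c in spec.lung_centers_mm:
        lung_frac += _ellipsoid_fraction(
            shape, spacing, origin, c, spec.lung_semiaxes_mm, spec.subsample
        )
    dep_frac = _sphere_fraction(
        shape, spacing, origin, spec.deposition_center_mm, r_dep, spec.subsample
    )
    if np.any((dep_frac > 0) & (liver_frac > 0)):
        raise ValueError("deposition overlaps the liver region; regions must be disjoint")

    ideal = np.zeros(shape)
    for frac, activity in (
        (liver_frac, spec.liver_activity_mbq),
        (lung_frac, spec.lung_activity_mbq),
        (dep_frac, spec.deposition_activity_mbq),
    ):
        vol = frac.sum()
        if vol > 0 and activity > 0:
            ideal += frac * (activity * 1e6 / vol)  # uniform Bq over the region

    values = _blur(ideal, spacing, spec.psf_fwhm_mm)
    if spec.noise_enabled:
        rng = np.random.default_rng(spec.seed)
        values = _apply_noise(values, spec.counts_per_bq, rng)

    coords = _axis_coords(shape, spacing, origin)
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    d2 = (
        (X - spec.deposition_center_mm[0]) ** 2
        + (Y - spec.deposition_center_mm[1]) ** 2
        + (Z - spec.deposition_center_mm[2]) ** 2
    )
    organ = (liver_frac > 0) | (lung_frac > 0)
    margin_sel = (d2 <= (r_dep + margin + max(spacing)) ** 2) & ~organ
    labels = {
        "liver": RoiMask(liver_frac > 0, label="liver"),
        "lungs": RoiMask(lung_frac > 0, label="lungs"),
    }
    truth = {
        "true_activity_mbq": spec.deposition_activity_mbq,
        "true_volume_ml": spec.deposition_volume_ml,
        "liver_activity_mbq": spec.liver_activity_mbq,
        "lung_activity_mbq": spec.lung_activity_mbq,
        "seed": spec.seed,
        "psf_fwhm_mm": spec.psf_fwhm_mm,
    }
    return PatientScene(
        image=VoxelImage(values, spacing, origin),
        margin_mask=RoiMask(margin_sel, label="deposition_margin"),
        labels=labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Planar projection
# ---------------------------------------------------------------------------


def project_planar(
    image: VoxelImage,
    labels: dict[str, RoiMask],
    axis: int = 1,
    mu_per_mm: float = 0.0,
    roi_margin_mm: float | None = None,
) -> tuple[PlanarImage, PlanarImage, dict[str, tuple[RoiMask, RoiMask]]]:
    """Anterior/posterior planar projections with organ ROI footprints.

    Projections are plain axis sums of the voxel image; with ``mu_per_mm``
    > 0 a single-coefficient exponential depth attenuation is applied (the
    anterior camera faces the low-index side of ``axis``). Each 3-D organ
    label is projected to its 2-D footprint; pass ``roi_margin_mm`` (typically
    twice the blur FWHM) to dilate the footprints, emulating ROIs drawn
    generously around the visible organ so that blurred counts are captured.

    Returns ``(anterior, posterior, rois)`` where ``rois`` maps each label
    name to its (anterior, posterior) ROI pair — identical masks, since both
    views share the detector grid.
    """
    if not labels:
        raise ValueError("at least one organ label is required for planar ROIs")
    for name, m in labels.items():
        if m.selected.shape != image.values.shape:
            raise ValueError(
                f"label '{name}' shape {m.selected.shape} does not match image {image.values.shape}"
            )
    values = image.values
    n = values.shape[axis]
    s = image.spacing[axis]
    if mu_per_mm > 0:
        depth = (np.arange(n) + 0.5) * s
        br = [1, 1, 1]
        br[axis] = n
        att_ant = np.exp(-mu_per_mm * depth).reshape(br)
        att_post = np.exp(-mu_per_mm * depth[::-1]).reshape(br)
        ant = (values * att_ant).sum(axis=axis)
        post = (values * att_post).sum(axis=axis)
    else:
        ant = values.sum(axis=axis)
        post = ant.copy()
    spacing2d = tuple(sp for a, sp in enumerate(image.spacing) if a != axis)

    rois: dict[str, tuple[RoiMask, RoiMask]] = {}
    for name, m in labels.items():
        fp = m.selected.any(axis=axis)
        if roi_margin_mm and roi_margin_mm > 0:
            fp = _dilate_footprint(fp, spacing2d, roi_margin_mm)
        roi = RoiMask(fp, label=name)
        rois[name] = (roi, roi)
    return PlanarImage(ant, spacing2d), PlanarImage(post, spacing2d), rois


def _dilate_footprint(fp: np.ndarray, spacing2d, margin_mm: float) -> np.ndarray:
    ri = int(math.ceil(margin_mm / spacing2d[0]))
    rj = int(math.ceil(margin_mm / spacing2d[1]))
    ii, jj = np.meshgrid(np.arange(-ri, ri + 1), np.arange(-rj, rj + 1), indexing="ij")
    disk = (ii * spacing2d[0]) ** 2 + (jj * spacing2d[1]) ** 2 <= margin_mm**2
    return ndimage.binary_dilation(fp, structure=disk)
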