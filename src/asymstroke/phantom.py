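"""Synthetic head CT phantoms with known ground-truth infarcts.

The head is modelled as nested ellipsoids: a brain ellipsoid (default
semi-axes 70/90/65 mm), a 6 mm skull shell around it, and two mirror-placed
ventricular CSF pockets.  Geometry is symmetric about the mid-sagittal
plane x = 0 unless a lesion or misalignment is requested, so the no-lesion
noise-free phantom doubles as a registration template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .imaging.volume import CTVolume, RigidTransform, apply_misalignment, centered_affine
from .imaging.segmentation import LesionMask


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head CT."""

    grid_shape: tuple[int, int, int] = (176, 208, 160)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull_hu: float = 700.0
    brain_hu: float = 35.0
    csf_hu: float = 8.0
    background_hu: float = -1000.0
    noise_sd: float = 0.0
    lesion_center: tuple[float, float, float] | None = None  # world mm
    lesion_radii: tuple[float, float, float] | None = None   # ellipsoid semi-axes, mm
    lesion_hu_drop: float = 15.0
    misalignment: RigidTransform | None = None
    seed: int = 0
    brain_semi_axes: tuple[float, float, float] = (70.0, 90.0, 65.0)
    skull_thickness_mm: float = 6.0
    ventricles: bool = True

    def __post_init__(self) -> None:
        for name in ("skull_hu", "brain_hu", "csf_hu", "background_hu",
                     "lesion_hu_drop", "noise_sd", "skull_thickness_mm"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if (self.lesion_center is None) != (self.lesion_radii is None):
            raise ValueError("lesion_center and lesion_radii must be given together")
        if self.lesion_radii is not None and any(r <= 0 for r in self.lesion_radii):
            raise ValueError("lesion radii must be > 0")
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)
        outer = np.asarray(self.brain_semi_axes) + self.skull_thickness_mm
        if np.any(2 * outer >= extent):
            raise ValueError("grid too small to contain the head ellipsoid")

    @property
    def has_lesion(self) -> bool:
        return self.lesion_center is not None


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _world_coords(spec: PhantomSpec):
    affine = centered_affine(spec.grid_shape, spec.voxel_spacing)
    axes = [affine[i, i] * np.arange(spec.grid_shape[i]) + affine[i, 3] for i in range(3)]
    return affine, np.meshgrid(*axes, indexing="ij", sparse=True)


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, LesionMask]:
    """Build a head phantom and its exact ground-truth lesion mask.

    Identical spec + seed gives identical output.  A lesion that leaves
    the brain ellipsoid or straddles the mid-sagittal plane raises a
    ``ValueError`` naming the violated invariant.
    """
    affine, coords = _world_coords(spec)
    brain = _ellipsoid(coords, (0, 0, 0), spec.brain_semi_axes)
    head = _ellipsoid(coords, (0, 0, 0),
                      np.asarray(spec.brain_semi_axes) + spec.skull_thickness_mm)

    vol = np.full(spec.grid_shape, spec.background_hu, dtype=np.float32)
    vol[head] = spec.skull_hu
    vol[brain] = spec.brain_hu
    if spec.ventricles:
        a, b, c = spec.brain_semi_axes
        vent_axes = (0.12 * a, 0.22 * b, 0.15 * c)
        for side in (-1.0, 1.0):
            vent = _ellipsoid(coords, (side * 0.20 * a, 0.05 * b, 0.10 * c), vent_axes)
            vol[vent & brain] = spec.csf_hu

    lesion = np.zeros(spec.grid_shape, dtype=bool)
    if spec.has_lesion:
        lesion = _ellipsoid(coords, spec.lesion_center, spec.lesion_radii)
        if not lesion.any():
            raise ValueError("lesion ellipsoid contains no voxels on this grid")
        if np.any(lesion & ~brain):
            raise ValueError("invariant violated: lesion must lie entirely "
                             "within the brain ellipsoid")
        xs = np.broadcast_to(coords[0], spec.grid_shape)[lesion]
        if xs.min() < 0 < xs.max():
            raise ValueError("invariant violated: lesion must lie entirely "
                             "within one hemisphere")
        vol[lesion] = spec.brain_hu - spec.lesion_hu_drop

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)

    volume = CTVolume(vol, affine, {"phantom_seed": spec.seed})
    mask = lesion
    if spec.misalignment is not None and not spec.misalignment.is_identity:
        volume = apply_misalignment(volume, spec.misalignment,
                                    cval=spec.background_hu)
        mask_vol = CTVolume(lesion.astype(np.float32), affine)
        mask = apply_misalignment(mask_vol, spec.misalignment, order=0,
                                  cval=0.0).voxels > 0.5
    return volume, LesionMask(mask, volume.spacing,
                              {"ground_truth": True, "seed": spec.seed})


def make_template(spec: PhantomSpec | None = None) -> CTVolume:
    """Perfectly left-right symmetric, noise-free head volume at 1 mm spacing.

    The spec must carry no lesion and no misalignment and have zero noise;
    voxel spacing is forced to 1 mm isotropic regardless of the spec (the
    grid shape is reinterpreted at 1 mm).
    """
    spec = spec or PhantomSpec()
    if spec.has_lesion:
        raise ValueError("template spec must not contain a lesion")
    if spec.misalignment is not None and not spec.misalignment.is_identity:
        raise ValueError("template spec must not be misaligned")
    if spec.noise_sd != 0:
        raise ValueError("template spec must be noise-free")
    spec = replace(spec, voxel_spacing=(1.0, 1.0, 1.0))
    volume, _ = make_phantom(spec)
    return volume


def analytic_lesion_volume_ml(radii) -> float:
    """Exact ellipsoid volume (4/3 pi abc) in millilitres."""
    a, b, c = radii
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def lesion_radius_for_volume_ml(volume_ml: float) -> float:
    """Radius of a sphere with the requested volume in mL."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def default_lesion_spec(volume_ml: float, seed: int = 0, side: str = "left",
                        **overrides) -> PhantomSpec:
    """Convenience spec with a spherical lesion of the requested volume.

    The lesion is centred deep in one hemisphere at 43% of the lateral
    brain semi-axis, which keeps spheres up to ~45 mL inside the brain.
    """
    base = PhantomSpec(**overrides) if overrides else PhantomSpec()
    r = lesion_radius_for_volume_ml(volume_ml)
    a = base.brain_semi_axes[0]
    sign = -1.0 if side == "left" else 1.0
    return replace(base, seed=seed,
                   lesion_center=(sign * 0.43 * a, 0.0, 0.0),
                   lesion_radii=(r, r, r))
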