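"""Volume container, rigid transforms and grid-level resampling operations.

World coordinates are RAS+ millimetres.  The first voxel axis of a canonical
volume runs left-to-right, so a left-right mirror is a flip of axis 0.
All voxel indexing is 0-based.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid world transform: rotate about the world origin, then translate.

    ``rotations`` are intrinsic Euler angles in degrees applied as
    ``Rz @ Ry @ Rx``; ``translations`` are millimetres.
    """

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.rotations) != 3 or len(self.translations) != 3:
            raise ValueError("a rigid transform has exactly 6 degrees of freedom")
        object.__setattr__(self, "rotations", tuple(float(v) for v in self.rotations))
        object.__setattr__(self, "translations", tuple(float(v) for v in self.translations))

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world matrix ``y = R x + t``."""
        ax, ay, az = np.deg2rad(self.rotations)
        cx, sx = math.cos(ax), math.sin(ax)
        cy, sy = math.cos(ay), math.sin(ay)
        cz, sz = math.cos(az), math.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        out = np.eye(4)
        out[:3, :3] = rz @ ry @ rx
        out[:3, 3] = self.translations
        return out

    @classmethod
    def from_params(cls, params) -> "RigidTransform":
        p = np.asarray(params, dtype=float)
        if p.shape != (6,):
            raise ValueError("expected 6 parameters (3 rotations deg, 3 translations mm)")
        return cls(tuple(p[:3]), tuple(p[3:]))

    @property
    def params(self) -> np.ndarray:
        return np.array(self.rotations + self.translations, dtype=float)

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        r = mat[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("matrix is not a proper rotation: transform must be rigid")
        # inverse of the Rz @ Ry @ Rx composition
        beta = math.asin(float(np.clip(-r[2, 0], -1.0, 1.0)))
        alpha = math.atan2(r[2, 1], r[2, 2])
        gamma = math.atan2(r[1, 0], r[0, 0])
        rot = tuple(np.rad2deg([alpha, beta, gamma]))
        return cls(rot, tuple(mat[:3, 3]))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        m = self.matrix
        inv = np.eye(4)
        inv[:3, :3] = m[:3, :3].T
        inv[:3, 3] = -m[:3, :3].T @ m[:3, 3]
        return RigidTransform.from_matrix(inv)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.rotations + self.translations)

    @property
    def rotation_magnitude_deg(self) -> float:
        """Total rotation angle (degrees) of the 3x3 rotation block."""
        r = self.matrix[:3, :3]
        c = float(np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0))
        return math.degrees(math.acos(c))

    @property
    def translation_magnitude_mm(self) -> float:
        return float(np.linalg.norm(self.translations))


@dataclass
class CTVolume:
    """A 3-D voxel grid in Hounsfield units with a voxel-to-world affine."""

    voxels: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3-D voxel grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def orientation_label(self) -> str:
        return "".join(nib.orientations.aff2axcodes(self.affine))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.affine.copy(), dict(self.meta))

    # -- NIfTI round trip -------------------------------------------------
    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(data, img.affine, {"source": str(path)})

    def to_nifti(self, path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.voxels.astype(np.float32), self.affine)
        nib.save(img, str(path))
        return path


def centered_affine(shape, spacing) -> np.ndarray:
    """Axis-aligned RAS+ affine with the grid centre at the world origin."""
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -(shape - 1) / 2.0 * spacing
    return aff


def reorient_to_standard(volume: CTVolume) -> CTVolume:
    """Permute/flip axes into the canonical RAS+ convention.

    World coordinates of every voxel are unchanged; only the storage order
    differs.  Oblique affines (any axis more than 1 degree off-grid) are
    rejected: resample first.
    """
    direction = volume.affine[:3, :3] / volume.spacing
    for col in range(3):
        if np.max(np.abs(direction[:, col])) < math.cos(math.radians(1.0)):
            raise ValueError(
                "affine is oblique (>1 degree off-axis); resample to an "
                "axis-aligned grid before reorienting"
            )
    ornt = nib.orientations.io_orientation(volume.affine)
    if np.all(ornt[:, 0] == [0, 1, 2]) and np.all(ornt[:, 1] == 1):
        return volume.copy()
    data = nib.orientations.apply_orientation(volume.voxels, ornt)
    new_affine = volume.affine @ nib.orientations.inv_ornt_aff(ornt, volume.shape)
    return CTVolume(np.ascontiguousarray(data), new_affine, dict(volume.meta))


def _resample_with_voxel_map(moving: CTVolume, voxel_map: np.ndarray,
                             out_shape, out_affine, order: int, cval: float) -> CTVolume:
    out = ndimage.affine_transform(
        moving.voxels, voxel_map[:3, :3], offset=voxel_map[:3, 3],
        output_shape=tuple(out_shape), order=order, cval=cval, prefilter=order > 1,
    )
    return CTVolume(out, out_affine, dict(moving.meta))


def resample_to_grid(moving: CTVolume, transform: RigidTransform,
                     grid_affine: np.ndarray, grid_shape,
                     order: int = 1, cval: float = -1000.0) -> CTVolume:
    """Resample ``moving`` under a world transform onto an output grid.

    Output voxel ``v`` receives ``moving`` sampled at
    ``A_m^-1 T^-1 A_g v`` — i.e. the content of ``moving`` is carried
    forward by ``T`` into the output frame.
    """
    vmap = np.linalg.inv(moving.affine) @ transform.inverse().matrix @ grid_affine
    return _resample_with_voxel_map(moving, vmap, grid_shape, np.asarray(grid_affine, float), order, cval)


def apply_misalignment(volume: CTVolume, transform: RigidTransform,
                       order: int = 1, cval: float | None = None) -> CTVolume:
    """Resample a volume under a rigid transform onto its own grid.

    The identity transform short-circuits to an exact copy.
    """
    if not isinstance(transform, RigidTransform):
        raise TypeError("apply_misalignment requires a RigidTransform (rigid only)")
    if transform.is_identity:
        return volume.copy()
    if cval is None:
        cval = float(volume.voxels.min())
    return resample_to_grid(volume, transform, volume.affine, volume.shape,
                            order=order, cval=cval)


def resample_isotropic(volume: CTVolume, iso_spacing: float = 1.0,
                       order: int = 1) -> CTVolume:
    """Trilinearly resample onto an isotropic grid of the given spacing."""
    iso_spacing = float(iso_spacing)
    if iso_spacing <= 0:
        raise ValueError("iso_spacing must be > 0")
    spacing = volume.spacing
    if np.allclose(spacing, iso_spacing, atol=1e-9):
        return volume.copy()
    scale = iso_spacing / spacing
    new_shape = np.maximum(1, np.round(np.asarray(volume.shape) / scale)).astype(int)
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = new_affine[:3, :3] @ np.diag(scale)
    vmap = np.eye(4)
    vmap[:3, :3] = np.diag(scale)
    return _resample_with_voxel_map(volume, vmap, new_shape, new_affine,
                                    order, float(volume.voxels.min()))


def resample_mask_isotropic(mask: np.ndarray, spacing, iso_spacing: float = 1.0) -> np.ndarray:
    """Nearest-neighbour companion of :func:`resample_isotropic` for masks."""
    spacing = np.asarray(spacing, dtype=float)
    if np.allclose(spacing, iso_spacing, atol=1e-9):
        return mask.copy()
    scale = float(iso_spacing) / spacing
    new_shape = np.maximum(1, np.round(np.asarray(mask.shape) / scale)).astype(int)
    out = ndimage.affine_transform(
        mask.astype(np.float32), np.diag(scale), output_shape=tuple(new_shape),
        order=0, cval=0.0,
    )
    return out > 0.5


def window_hu(volume: CTVolume, hu_window=(-20.0, 80.0)) -> CTVolume:
    """Clip to a HU window and rescale linearly onto [0, 1]."""
    lo, hi = float(hu_window[0]), float(hu_window[1])
    if lo >= hi:
        raise ValueError("hu_window lower bound must be below the upper bound")
    data = (np.clip(volume.voxels, lo, hi) - lo) / (hi - lo)
    out = CTVolume(data, volume.affine.copy(), dict(volume.meta))
    out.meta["hu_window"] = (lo, hi)
    return out
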