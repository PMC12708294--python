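"""Semi-automated hemispheric-asymmetry infarct segmentation.

Stage order: reorient -> skull strip -> isotropic resample -> HU window ->
left-right flip registration -> absolute difference map -> percentile
threshold -> hypodense-side restriction -> cluster-size filter ->
(optional) template alignment.  The percentile threshold is taken over
brain-mask voxels only; including background air would make it meaningless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import (
    CTVolume,
    reorient_to_standard,
    resample_isotropic,
    resample_mask_isotropic,
    window_hu,
)
from .registration import register_flipped, align_to_template

# HU bands for CT brain extraction
_SOFT_TISSUE_LO = 0.0
_SOFT_TISSUE_HI = 100.0
_BONE_HU = 300.0
# erosion depth in mm per unit of frac_threshold; at the 0.35 default this
# strips ~2.5 mm (the high-gradient rim voxels) while keeping the mask
# within 10% of the true brain volume
_EROSION_MM_PER_FRAC = 7.0

_CONNECTIVITY_MAP = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable constants of the asymmetry workflow.

    ``frac_threshold`` plays the role of a fractional brain-extraction
    parameter: larger values erode the brain mask more aggressively.
    ``side_rule`` restricts supra-threshold voxels to the hypodense side
    (original darker than its mirror), which disambiguates a lesion from
    its contralateral mirror site in the absolute difference map.
    """

    frac_threshold: float = 0.35
    iso_spacing: float = 1.0
    hu_window: tuple[float, float] = (-20.0, 80.0)
    percentile: float = 98.0
    min_cluster_mm3: float = 500.0
    connectivity: int = 26
    side_rule: bool = True
    align_template: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_threshold < 1.0:
            raise ValueError("frac_threshold must lie in (0, 1)")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if self.min_cluster_mm3 < 0:
            raise ValueError("min_cluster_mm3 must be >= 0")
        if self.iso_spacing <= 0:
            raise ValueError("iso_spacing must be > 0")
        if self.connectivity not in _CONNECTIVITY_MAP:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window lower bound must be below upper bound")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hu_window"] = list(self.hu_window)
        return d


@dataclass
class LesionMask:
    """Binary lesion mask plus the provenance of how it was produced."""

    voxels: np.ndarray
    spacing: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_ml(self) -> float:
        return lesion_volume_ml(self)


@dataclass
class LesionReport:
    """End-to-end result of quantifying one scan."""

    volume_ml: float
    n_clusters: int
    largest_cluster_ml: float
    laterality: str  # left | right | none
    qc: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "volume_ml": round(float(self.volume_ml), 6),
            "n_clusters": int(self.n_clusters),
            "largest_cluster_ml": round(float(self.largest_cluster_ml), 6),
            "laterality": self.laterality,
            "qc": self.qc,
        }
        return json.dumps(payload, sort_keys=True)


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def skull_strip_ct(volume: CTVolume, config: SegmentationConfig | None = None) -> np.ndarray:
    """Brain mask from a head CT by HU banding plus morphology.

    Soft tissue is selected in the 0-100 HU band (bone at > 300 HU and air
    fall outside it), closed morphologically, reduced to the largest
    connected component, hole-filled, then eroded by a depth proportional
    to ``frac_threshold``.  Raising ``frac_threshold`` never grows the mask.
    """
    config = config or SegmentationConfig()
    band = (volume.voxels >= _SOFT_TISSUE_LO) & (volume.voxels <= _SOFT_TISSUE_HI)
    if not band.any():
        raise ValueError("no brain tissue found: no voxels in the soft-tissue HU band")
    closed = ndimage.binary_closing(band, structure=ndimage.generate_binary_structure(3, 2),
                                    iterations=2)
    labels, n = ndimage.label(closed)
    if n == 0:
        raise ValueError("no brain tissue found after morphology")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    depth_mm = config.frac_threshold * _EROSION_MM_PER_FRAC
    dist = ndimage.distance_transform_edt(mask, sampling=volume.spacing)
    eroded = dist > depth_mm
    if not eroded.any():
        raise ValueError("no brain tissue found: erosion removed the whole mask")
    return eroded


def asymmetry_lesion_mask(original: CTVolume, mirrored: CTVolume,
                          brain_mask: np.ndarray,
                          config: SegmentationConfig | None = None) -> LesionMask:
    """Threshold the |original - mirror| map and filter small clusters.

    The threshold is the ``config.percentile``-th percentile of the
    difference map over brain-mask voxels.  With ``side_rule`` on, only
    voxels darker than their mirror survive.  Connected components smaller
    than ``min_cluster_mm3`` are removed.
    """
    config = config or SegmentationConfig()
    if original.shape != mirrored.shape:
        raise ValueError("original and mirrored volumes must share one grid")
    if brain_mask.shape != original.shape:
        raise ValueError("brain mask must live on the image grid")
    if not brain_mask.any():
        raise ValueError("empty brain mask")

    diff = np.abs(original.voxels - mirrored.voxels)
    inside = diff[brain_mask]
    provenance = {"config": config.to_dict(), "stages": []}
    if not np.any(inside > 0):
        provenance["qc_note"] = "all-zero difference map; empty mask returned"
        provenance["threshold"] = 0.0
        provenance["prefilter_fraction"] = 0.0
        return LesionMask(np.zeros(original.shape, bool), original.spacing, provenance)

    threshold = float(np.percentile(inside, config.percentile))
    supra = (diff > threshold) & brain_mask
    provenance["threshold"] = threshold
    provenance["prefilter_fraction"] = float(supra.sum() / brain_mask.sum())
    provenance["stages"].append("percentile_threshold")

    if config.side_rule:
        supra &= original.voxels < mirrored.voxels
        provenance["stages"].append("hypodense_side_rule")

    voxel_mm3 = original.voxel_volume_mm3
    labels = measure.label(supra, connectivity=_CONNECTIVITY_MAP[config.connectivity])
    keep = np.zeros_like(supra)
    for region in measure.regionprops(labels):
        if region.area * voxel_mm3 >= config.min_cluster_mm3:
            keep[labels == region.label] = True
    provenance["stages"].append("cluster_size_filter")
    return LesionMask(keep, original.spacing, provenance)


def lesion_volume_ml(mask: LesionMask | np.ndarray, spacing=None) -> float:
    """Set-voxel count times voxel volume, in millilitres."""
    if isinstance(mask, LesionMask):
        voxel_mm3 = mask.voxel_volume_mm3
        count = int(mask.voxels.sum())
    else:
        voxel_mm3 = float(np.prod(np.asarray(spacing, dtype=float)))
        count = int(np.asarray(mask, dtype=bool).sum())
    return count * voxel_mm3 / 1000.0


def centroid_voxel(mask: np.ndarray) -> tuple[int, int, int] | None:
    """Mask centroid rounded to the nearest voxel; None when empty."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    com = ndimage.center_of_mass(mask)
    return tuple(int(round(c)) for c in com)


def _cluster_stats(mask: LesionMask, connectivity: int):
    labels = measure.label(mask.voxels, connectivity=_CONNECTIVITY_MAP[connectivity])
    regions = measure.regionprops(labels)
    if not regions:
        return 0, 0.0, None
    sizes = [r.area for r in regions]
    largest = regions[int(np.argmax(sizes))]
    largest_ml = max(sizes) * mask.voxel_volume_mm3 / 1000.0
    return len(regions), largest_ml, largest.centroid


def quantify_scan(scan, config: SegmentationConfig | None = None,
                  template: CTVolume | None = None, seed: int = 0):
    """Run the full asymmetry workflow on one scan.

    Parameters
    ----------
    scan
        A :class:`CTVolume` or a path to a NIfTI file.
    template
        Optional 1 mm isotropic template; when given (or when
        ``config.align_template`` is set) the lesion mask is rigidly
        carried into template space before reporting.

    Returns
    -------
    (LesionReport, LesionMask, CTVolume)
        The report, the final mask and the preprocessed (isotropic,
        windowed) volume the mask lives on.
    """
    config = config or SegmentationConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, exc) from exc

    if not isinstance(scan, CTVolume):
        volume = stage("load", CTVolume.from_nifti, scan)
    else:
        volume = scan
    volume = stage("reorient", reorient_to_standard, volume)
    brain_native = stage("skull_strip", skull_strip_ct, volume, config)
    iso = stage("resample", resample_isotropic, volume, config.iso_spacing)
    brain = stage("resample", resample_mask_isotropic, brain_native,
                  volume.spacing, config.iso_spacing)
    windowed = stage("window", window_hu, iso, config.hu_window)
    transform, mirrored, reg_info = stage("flip_register", register_flipped,
                                          windowed, brain, seed)
    mask = stage("asymmetry", asymmetry_lesion_mask, windowed, mirrored, brain, config)

    volume_ml = lesion_volume_ml(mask)
    n_clusters, largest_ml, centroid = _cluster_stats(mask, config.connectivity)
    laterality = "none"
    if centroid is not None:
        world_x = float(windowed.voxel_to_world(np.array(centroid))[0][0])
        laterality = "left" if world_x < 0 else "right"

    qc = {
        "brain_mask_ml": round(float(brain.sum() * windowed.voxel_volume_mm3 / 1000.0), 6),
        "registration_residual": round(float(reg_info["residual"]), 9),
        "registration_converged": bool(reg_info["converged"]),
        "threshold": round(float(mask.provenance.get("threshold", 0.0)), 9),
        "prefilter_fraction": round(float(mask.provenance.get("prefilter_fraction", 0.0)), 9),
    }
    if "qc_note" in mask.provenance:
        qc["note"] = mask.provenance["qc_note"]

    if template is not None or config.align_template:
        if template is None:
            raise StageError("template_align", ValueError("no template supplied"))
        _, aligned_mask, t_tpl, tpl_info = stage("template_align", align_to_template,
                                                 windowed, mask, template, seed)
        before = max(1, tpl_info["mask_voxels_before"])
        scale = (windowed.voxel_volume_mm3 / template.voxel_volume_mm3)
        qc["template_mask_volume_change"] = round(
            abs(tpl_info["mask_voxels_after"] / scale - before) / before
            if before else 0.0, 6)
        qc["template_transform"] = [round(v, 6) for v in t_tpl.params.tolist()]

    report = LesionReport(volume_ml=volume_ml, n_clusters=n_clusters,
                          largest_cluster_ml=largest_ml, laterality=laterality, qc=qc)
    return report, mask, windowed


def qc_overlay(volume: CTVolume, mask, out_path) -> Path:
    """Write a 3-panel (axial/coronal/sagittal) overlay PNG at the mask centroid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask_arr = np.asarray(getattr(mask, "voxels", mask), dtype=bool)
    if mask_arr.shape != volume.shape:
        raise ValueError("volume and mask must share a grid")
    center = centroid_voxel(mask_arr)
    if center is None:
        center = tuple(s // 2 for s in volume.shape)

    out_path = Path(out_path)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    planes = [
        (volume.voxels[:, :, center[2]], mask_arr[:, :, center[2]], "axial"),
        (volume.voxels[:, center[1], :], mask_arr[:, center[1], :], "coronal"),
        (volume.voxels[center[0], :, :], mask_arr[center[0], :, :], "sagittal"),
    ]
    for ax, (img, m, title) in zip(axes, planes):
        ax.imshow(img.T, cmap="gray", origin="lower")
        if m.any():
            overlay = np.ma.masked_where(~m.T, m.T)
            ax.imshow(overlay, cmap="autumn", alpha=0.5, origin="lower")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    try:
        fig.savefig(out_path, dpi=100)
    finally:
        plt.close(fig)
    if not out_path.exists():
        raise OSError(f"could not write overlay to {out_path}")
    return out_path
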