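"""Color-encoded fusion of two aligned time points into one change image.

TP1 is mapped to orange (RGB {255, 128, 0}) and TP2 to light blue
(RGB {0, 127, 255}); the fused image is the voxel-wise superposition of the
two color-mapped volumes. Because the colors are complementary, unchanged
tissue renders gray, intensity increases over time render light blue, and
decreases render orange — and the pair remains legible under common color
vision deficiencies. No intensity standardization is applied: one shared
scalar window maps both raw volumes into color space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GridMismatchError, VolumeGrid

__all__ = [
    "TP1_COLOR",
    "TP2_COLOR",
    "NormalizedPair",
    "FusedImage",
    "normalize_pair",
    "fuse_color",
    "compose_vu_fusion",
]

TP1_COLOR = np.array([255, 128, 0], dtype=float)
TP2_COLOR = np.array([0, 127, 255], dtype=float)


@dataclass
class NormalizedPair:
    tp1: np.ndarray  # in [0, 1]
    tp2: np.ndarray
    window: float
    clip_fraction_tp1: float
    clip_fraction_tp2: float


def normalize_pair(
    tp1: VolumeGrid, tp2: VolumeGrid, window: float | str = "shared_max"
) -> NormalizedPair:
    """Map a raw, aligned volume pair into [0, 1] with one shared window.

    ``window='shared_max'`` divides both volumes by the maximum over the
    pair (so a uniformly brighter scan cannot produce a global color cast
    by construction); a numeric window divides by that fixed value instead.
    Values above the window are clipped to 1 and the clipped fraction is
    reported. Negative values (possible after interpolation of noisy data)
    clip to 0. No per-image histogram operation is ever applied.
    """
    tp1.require_same_grid(tp2, "normalize_pair")
    if window == "shared_max":
        w = float(max(tp1.data.max(), tp2.data.max(), 0.0))
        if w <= 0.0:
            warnings.warn("both volumes are non-positive; using window 1.0", stacklevel=2)
            w = 1.0
    else:
        w = float(window)
        if w <= 0:
            raise ValueError("window must be positive")
    n1 = tp1.data / w
    n2 = tp2.data / w
    clip1 = float(np.mean((n1 > 1.0) | (n1 < 0.0)))
    clip2 = float(np.mean((n2 > 1.0) | (n2 < 0.0)))
    return NormalizedPair(np.clip(n1, 0.0, 1.0), np.clip(n2, 0.0, 1.0), w, clip1, clip2)


@dataclass
class FusedImage:
    """Color-encoded change image on the TP1 grid."""

    rgb: np.ndarray  # uint8, (*grid, 3)
    affine: np.ndarray
    window: float
    vu_applied: int | None = None

    def save_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.rgb, self.affine), str(path))

    def save_slice_png(self, path, slice_index: int | None = None) -> None:
        """Export one sagittal slice (default: middle) as PNG for review.

        Array axes are (anterior-posterior, inferior-superior, slice); the
        exported image puts superior at the top.
        """
        from PIL import Image

        k = self.rgb.shape[2] // 2 if slice_index is None else slice_index
        sl = self.rgb[:, :, k, :]  # (AP, SI, 3)
        img = np.transpose(sl[:, ::-1, :], (1, 0, 2))  # rows = SI (superior first)
        Image.fromarray(img, mode="RGB").save(str(path))

    def save_all_slices_png(self, directory, prefix: str = "slice") -> None:
        """Export every sagittal slice as ``<prefix><k>.png`` under ``directory``."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k in range(self.rgb.shape[2]):
            self.save_slice_png(d / f"{prefix}{k:02d}.png", slice_index=k)


def fuse_color(tp1n: np.ndarray, tp2n: np.ndarray, affine=None, window: float = 1.0) -> FusedImage:
    """Superpose the orange-mapped TP1 and light-blue-mapped TP2 volumes.

    rgb = round(clip(I1 * {255,128,0} + I2 * {0,127,255})). Consequences:
    I2 > I1 makes blue exceed red (increase renders light blue), I1 > I2
    makes red exceed blue (decrease renders orange), and I1 = I2 leaves all
    channels within one count of each other (gray).
    """
    tp1n = np.asarray(tp1n, dtype=float)
    tp2n = np.asarray(tp2n, dtype=float)
    if tp1n.shape != tp2n.shape:
        raise GridMismatchError("normalized inputs differ in shape")
    for name, arr in (("tp1", tp1n), ("tp2", tp2n)):
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{name} must be normalized into [0, 1] before fusion")
    rgb = tp1n[..., None] * TP1_COLOR + tp2n[..., None] * TP2_COLOR
    rgb = np.floor(np.clip(rgb, 0.0, 255.0) + 0.5).astype(np.uint8)  # round half-up
    if affine is None:
        affine = np.eye(4)
    return FusedImage(rgb=rgb, affine=np.asarray(affine, dtype=float), window=window)


def compose_vu_fusion(
    tp1: VolumeGrid,
    tp2: VolumeGrid,
    field,
    vus,
    selected_vu: int,
    margin_mm: float = 5.0,
    window: float | str = "shared_max",
    annotate: bool = True,
) -> FusedImage:
    """Fuse the pair with the selected unit's locally rigid alignment baked in.

    TP2 is pulled into the TP1 frame through the global deformation field
    everywhere, then re-resampled with the selected vertebral unit's rigid
    transform inside its dilated region, and the pair is color-fused. The
    selected unit's boundary is annotated in yellow in the export.
    """
    from scipy import ndimage

    from .alignment import estimate_local_rigid, resample_locally_rigid, resample_with_field

    by_index = {v.vu_index: v for v in vus}
    if selected_vu not in by_index:
        raise ValueError(
            f"vertebral unit {selected_vu} not available; have {sorted(by_index)}"
        )
    vu = by_index[selected_vu]
    transform = estimate_local_rigid(vu, field)
    warped, _ = resample_with_field(tp2, field)
    rig = resample_locally_rigid(tp2, transform, tp1, vu.voxel_mask, margin_mm)
    aligned = warped.data.copy()
    use_rigid = rig.roi_dilated & rig.valid
    aligned[use_rigid] = rig.volume.data[use_rigid]
    pair = normalize_pair(tp1, VolumeGrid(aligned, tp1.affine), window)
    fused = fuse_color(pair.tp1, pair.tp2, affine=tp1.affine, window=pair.window)
    fused.vu_applied = selected_vu
    if annotate:
        boundary = vu.voxel_mask & ~ndimage.binary_erosion(vu.voxel_mask)
        fused.rgb[boundary] = np.array([255, 255, 0], dtype=np.uint8)
    return fused
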