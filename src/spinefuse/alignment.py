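"""Global registration contract and locally rigid per-unit alignment.

The global time-point alignment is a pluggable contract that yields a
dense deformation field on the TP1 grid (``register_global``). From that
field, a locally rigid transform is derived per vertebral unit by the
landmark transform: every unit voxel contributes a landmark pair (its TP1
world position, that position plus its displacement) and the closed-form
least-squares rigid fit (cross-covariance SVD with a reflection guard)
gives the rotation + translation that preserves bone rigidity. TP2 is then
resampled into the TP1 frame with that rigid transform inside a dilated
region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DeformationField,
    GridMismatchError,
    RigidTransform,
    VolumeGrid,
    voxel_from_world,
    world_from_voxel,
)
from .segmentation import VertebralUnit, build_vertebral_units

__all__ = [
    "RegistrationError",
    "register_global",
    "rigid_from_point_pairs",
    "estimate_local_rigid",
    "ResampleResult",
    "resample_locally_rigid",
    "resample_with_field",
    "ReverseEquivalenceReport",
    "align_reverse_equivalence_check",
]


class RegistrationError(RuntimeError):
    """The registration backend failed or produced an unusable field."""


def register_global(
    fixed: VolumeGrid, moving: VolumeGrid, backend_config: dict
) -> DeformationField:
    """Obtain a dense TP1->TP2 displacement field from a pluggable backend.

    ``backend_config['backend']`` selects:

    - ``'synthetic'``: an analytic field supplied as ``field`` (tests,
      phantoms);
    - ``'precomputed'``: a vector NIfTI loaded from ``path`` (fields
      estimated by any external registration tool);
    - ``'demons'``: SimpleITK displacement-field (demons) registration,
      for exploratory use on real image pairs.

    The returned field is always defined on the fixed (TP1) grid.
    """
    backend = backend_config.get("backend")
    if backend == "synthetic":
        fld = backend_config.get("field")
        if not isinstance(fld, DeformationField):
            raise RegistrationError("synthetic backend needs a 'field' DeformationField")
    elif backend == "precomputed":
        path = backend_config.get("path")
        if path is None:
            raise RegistrationError("precomputed backend needs a 'path'")
        try:
            fld = DeformationField.load(path)
        except Exception as exc:  # noqa: BLE001 - backend diagnostics
            raise RegistrationError(f"could not load displacement field {path}: {exc}") from exc
    elif backend == "demons":
        fld = _demons_field(fixed, moving, backend_config)
    else:
        raise RegistrationError(f"unknown registration backend {backend!r}")
    if fld.shape != fixed.shape or not np.allclose(fld.affine, fixed.affine):
        raise GridMismatchError(
            f"displacement field grid {fld.shape} does not match fixed image {fixed.shape}"
        )
    if not np.isfinite(fld.displacement).all():
        raise RegistrationError("displacement field contains non-finite values")
    return fld


def _demons_field(fixed: VolumeGrid, moving: VolumeGrid, cfg: dict) -> DeformationField:
    import SimpleITK as sitk

    def to_sitk(v: VolumeGrid) -> "sitk.Image":
        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.T.astype(np.float64)))
        # nibabel affines are RAS; SimpleITK works in LPS.
        m = np.diag([-1.0, -1.0, 1.0]) @ v.affine[:3, :3]
        img.SetSpacing(tuple(np.linalg.norm(m, axis=0)))
        img.SetDirection(tuple((m / np.linalg.norm(m, axis=0)).ravel()))
        img.SetOrigin(tuple(np.diag([-1.0, -1.0, 1.0]) @ v.affine[:3, 3]))
        return img

    f, m = to_sitk(fixed), to_sitk(moving)
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(cfg.get("iterations", 30)))
    demons.SetStandardDeviations(float(cfg.get("smoothing_sigma", 2.0)))
    try:
        disp_img = demons.Execute(f, m)
    except Exception as exc:  # noqa: BLE001
        raise RegistrationError(f"demons backend failed: {exc}") from exc
    disp = sitk.GetArrayFromImage(disp_img)  # (z, y, x, 3) LPS mm
    disp = np.moveaxis(disp, (0, 1, 2), (2, 1, 0))
    disp[..., 0] *= -1.0  # LPS -> RAS
    disp[..., 1] *= -1.0
    return DeformationField(disp, fixed.affine)


def rigid_from_point_pairs(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform taking points ``p`` onto ``q``.

    Kabsch/Umeyama solution: SVD of the centered cross-covariance, with the
    smallest singular direction flipped if the optimal orthogonal matrix
    would be a reflection. ``rms_residual_mm`` reports the post-fit RMS
    landmark error.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 landmark pairs")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("landmarks contain non-finite values")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("landmarks are collinear; rigid transform is not determined")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # Re-orthonormalize against accumulated floating-point drift.
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    t = q.mean(axis=0) - rot @ p.mean(axis=0)
    resid = p @ rot.T + t - q
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return RigidTransform(rot, t, rms)


def estimate_local_rigid(
    vu: VertebralUnit, field: DeformationField, stride: int = 1
) -> RigidTransform:
    """Landmark-transform rigid fit over one vertebral unit.

    Landmarks are all unit voxels (uniform weights): each pairs its TP1
    world position with that position plus the field displacement there.
    ``stride`` subsamples the landmarks for speed; the default uses every
    voxel (exactness first).
    """
    if vu.voxel_mask.shape != field.shape or not np.allclose(vu.affine, field.affine):
        raise GridMismatchError("vertebral unit and field are on different grids")
    idx = np.argwhere(vu.voxel_mask)[:: max(1, int(stride))]
    if idx.shape[0] < 3:
        raise ValueError(f"{vu.name}: fewer than 3 voxels, rigid fit is degenerate")
    p = world_from_voxel(field.affine, idx)
    d = field.displacement[tuple(idx.T)]
    if not np.isfinite(d).all():
        raise ValueError(f"{vu.name}: non-finite displacements inside the unit")
    return rigid_from_point_pairs(p, p + d)


@dataclass
class ResampleResult:
    """A locally resampled volume with its sampling-validity bookkeeping."""

    volume: VolumeGrid
    valid: np.ndarray  # bool: voxel was inside the dilated ROI and in moving extent
    roi_dilated: np.ndarray  # bool: the dilated ROI that was resampled


def _dilate_mm(mask: np.ndarray, spacing: np.ndarray, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def resample_locally_rigid(
    moving: VolumeGrid,
    transform: RigidTransform,
    fixed_grid: VolumeGrid | DeformationField,
    roi_mask: np.ndarray,
    margin_mm: float = 5.0,
    fill_value: float = 0.0,
) -> ResampleResult:
    """Sample ``moving`` at rigidly mapped positions of fixed-grid ROI voxels.

    For every fixed-grid voxel inside the ROI dilated by ``margin_mm``
    (millimeter-aware dilation, so the fused display keeps some anatomical
    context around the bone), the moving image is sampled with linear
    interpolation at ``transform(world position)``. Samples outside the
    moving extent get ``fill_value`` and are excluded from the validity
    mask; voxels outside the dilated ROI are left at ``fill_value``.
    """
    if roi_mask.shape != fixed_grid.shape:
        raise GridMismatchError("ROI mask does not match the fixed grid")
    roi = _dilate_mm(roi_mask.astype(bool), fixed_grid.spacing, margin_mm)
    idx = np.argwhere(roi)
    out = np.full(fixed_grid.shape, fill_value, dtype=float)
    valid = np.zeros(fixed_grid.shape, dtype=bool)
    if idx.size:
        p = world_from_voxel(fixed_grid.affine, idx)
        q = transform.apply(p)
        ci = voxel_from_world(moving.affine, q)
        inside = np.all((ci >= 0.0) & (ci <= np.array(moving.shape) - 1.0), axis=1)
        vals = ndimage.map_coordinates(
            moving.data, ci.T, order=1, mode="constant", cval=fill_value
        )
        out[tuple(idx.T)] = np.where(inside, vals, fill_value)
        valid[tuple(idx[inside].T)] = True
    return ResampleResult(VolumeGrid(out, np.array(fixed_grid.affine)), valid, roi)


def resample_with_field(
    moving: VolumeGrid, field: DeformationField, fill_value: float = 0.0
) -> tuple[VolumeGrid, np.ndarray]:
    """Pull ``moving`` onto the fixed grid through a dense deformation field."""
    pos = field.mapped_positions()
    ci = voxel_from_world(moving.affine, pos.reshape(-1, 3))
    inside = np.all((ci >= 0.0) & (ci <= np.array(moving.shape) - 1.0), axis=1)
    vals = ndimage.map_coordinates(moving.data, ci.T, order=1, mode="constant", cval=fill_value)
    data = np.where(inside, vals, fill_value).reshape(field.shape)
    return VolumeGrid(data, np.array(field.affine)), inside.reshape(field.shape)


@dataclass
class ReverseEquivalenceReport:
    """Per-unit check that TP1->TP2 and TP2->TP1 rigid fits are mutual inverses."""

    rows: pd.DataFrame  # vu_index, rotation_mismatch_deg, translation_mismatch_mm
    tolerance_deg: float
    tolerance_mm: float

    @property
    def max_rotation_mismatch_deg(self) -> float:
        return float(self.rows["rotation_mismatch_deg"].max())

    @property
    def max_translation_mismatch_mm(self) -> float:
        return float(self.rows["translation_mismatch_mm"].max())

    @property
    def all_within_tolerance(self) -> bool:
        return bool(
            (self.rows["rotation_mismatch_deg"] <= self.tolerance_deg).all()
            and (self.rows["translation_mismatch_mm"] <= self.tolerance_mm).all()
        )


def align_reverse_equivalence_check(
    case, tolerance_deg: float = 0.1, tolerance_mm: float = 0.1
) -> ReverseEquivalenceReport:
    """Verify direction symmetry of the locally rigid alignment on a phantom.

    The method may be run TP1->TP2 (units segmented on TP1) or TP2->TP1
    (units segmented on TP2); the per-unit transforms from the two
    directions must be mutual inverses. For every unit, the forward fit is
    composed with the reverse fit and the deviation of the composition from
    the identity is reported as a rotation angle and as the translation of
    the unit centroid.
    """
    vus_fwd = build_vertebral_units(case.mask_tp1)
    vus_rev = build_vertebral_units(case.mask_tp2)
    rev_by_index = {v.vu_index: v for v in vus_rev}
    records = []
    for vf in vus_fwd:
        vr = rev_by_index.get(vf.vu_index)
        if vr is None:
            continue
        tf = estimate_local_rigid(vf, case.true_field)
        tr = estimate_local_rigid(vr, case.true_field_reverse)
        comp = tr.compose(tf)  # should be identity on the unit
        centroid = world_from_voxel(case.mask_tp1.affine, np.argwhere(vf.voxel_mask)).mean(axis=0)
        records.append(
            {
                "vu_index": vf.vu_index,
                "rotation_mismatch_deg": comp.angle_deg,
                "translation_mismatch_mm": float(
                    np.linalg.norm(comp.apply(centroid) - centroid)
                ),
                "forward_rms_mm": tf.rms_residual_mm,
                "reverse_rms_mm": tr.rms_residual_mm,
            }
        )
    return ReverseEquivalenceReport(pd.DataFrame.from_records(records), tolerance_deg, tolerance_mm)
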