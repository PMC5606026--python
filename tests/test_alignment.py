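"""Registration contract, landmark rigid fits, rigid resampling, direction symmetry."""

import numpy as np
import pytest
from scipy import optimize

from spinefuse.alignment import (
    RegistrationError,
    align_reverse_equivalence_check,
    estimate_local_rigid,
    register_global,
    resample_locally_rigid,
    resample_with_field,
    rigid_from_point_pairs,
)
from spinefuse.core import (
    DeformationField,
    GridMismatchError,
    RigidTransform,
    VolumeGrid,
    rotation_about_axis,
    world_from_voxel,
)
from spinefuse.phantom import MotionSpec, PhantomConfig, generate_spine_phantom
from spinefuse.segmentation import VertebralUnit


def _rigid_field_on(grid_affine, shape, transform):
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    p = world_from_voxel(grid_affine, idx)
    return DeformationField(transform.apply(p) - p, grid_affine)


# --- register_global backends ---------------------------------------------


def test_synthetic_backend_passes_field_through(coarse_case):
    fld = register_global(
        coarse_case.tp1, coarse_case.tp2, {"backend": "synthetic", "field": coarse_case.true_field}
    )
    assert fld is coarse_case.true_field


def test_precomputed_backend_round_trips_bit_identically(tmp_path, coarse_case):
    path = tmp_path / "field.nii.gz"
    coarse_case.true_field.save(path)
    fld = register_global(coarse_case.tp1, coarse_case.tp2, {"backend": "precomputed", "path": path})
    assert np.array_equal(
        fld.displacement.astype(np.float32), coarse_case.true_field.displacement.astype(np.float32)
    )


def test_backend_errors_are_explicit(coarse_case):
    with pytest.raises(RegistrationError, match="unknown"):
        register_global(coarse_case.tp1, coarse_case.tp2, {"backend": "nonexistent"})
    with pytest.raises(RegistrationError, match="field"):
        register_global(coarse_case.tp1, coarse_case.tp2, {"backend": "synthetic"})
    bad = DeformationField(np.zeros((2, 2, 2, 3)), coarse_case.tp1.affine)
    with pytest.raises(GridMismatchError):
        register_global(coarse_case.tp1, coarse_case.tp2, {"backend": "synthetic", "field": bad})


def test_demons_backend_recovers_a_small_translation():
    """Smoke test of the intensity-based backend on a tiny shifted blob pair."""
    rng = np.random.default_rng(0)
    shape = (24, 24, 8)
    affine = np.diag([2.0, 2.0, 3.0, 1.0])
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    p = world_from_voxel(affine, idx)
    c = np.array([24.0, 24.0, 10.0])
    blob = lambda center: np.exp(-((np.linalg.norm(p - center, axis=-1) / 8.0) ** 2))
    fixed = VolumeGrid(blob(c), affine)
    moving = VolumeGrid(blob(c + [4.0, 0.0, 0.0]), affine)
    fld = register_global(fixed, moving, {"backend": "demons", "iterations": 50})
    core = fixed.data > 0.5
    assert abs(fld.displacement[core, 0].mean() - 4.0) < 1.5
    assert abs(fld.displacement[core, 1].mean()) < 1.0


# --- landmark rigid estimation --------------------------------------------


def test_zero_field_gives_identity_transform(coarse_vus, coarse_case):
    fld = DeformationField(
        np.zeros(coarse_case.tp1.shape + (3,)), coarse_case.tp1.affine
    )
    t = estimate_local_rigid(coarse_vus[0], fld)
    assert np.allclose(t.rotation, np.eye(3))
    assert np.allclose(t.translation, 0.0)
    assert t.rms_residual_mm < 1e-12


def test_constant_field_is_recovered_as_pure_translation(coarse_vus, coarse_case):
    disp = np.zeros(coarse_case.tp1.shape + (3,))
    disp[:] = [1.5, -2.0, 0.4]
    t = estimate_local_rigid(coarse_vus[5], DeformationField(disp, coarse_case.tp1.affine))
    assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t.translation, [1.5, -2.0, 0.4])
    assert t.rms_residual_mm < 1e-9


def test_known_rotation_about_left_right_axis_is_recovered(coarse_vus, coarse_case):
    centroid = world_from_voxel(
        coarse_case.tp1.affine, np.argwhere(coarse_vus[10].voxel_mask)
    ).mean(axis=0)
    truth = RigidTransform.about_center(
        rotation_about_axis([1.0, 0.0, 0.0], np.radians(5.0)), centroid, [2.0, -1.0, 0.5]
    )
    fld = _rigid_field_on(coarse_case.tp1.affine, coarse_case.tp1.shape, truth)
    t = estimate_local_rigid(coarse_vus[10], fld)
    assert np.abs(t.rotation - truth.rotation).max() < 1e-6
    assert np.abs(t.translation - truth.translation).max() < 1e-6


def test_rigid_recovery_holds_for_random_transforms_and_every_unit_shape(
    coarse_vus, coarse_case
):
    rng = np.random.default_rng(123)
    for seed in range(5):
        axis = rng.normal(size=3)
        truth = RigidTransform.about_center(
            rotation_about_axis(axis, rng.uniform(0, np.radians(8.0))),
            rng.uniform(0, 300, 3),
            rng.uniform(-5, 5, 3),
        )
        fld = _rigid_field_on(coarse_case.tp1.affine, coarse_case.tp1.shape, truth)
        vu = coarse_vus[int(rng.integers(0, 23))]
        t = estimate_local_rigid(vu, fld)
        assert np.abs(t.rotation - truth.rotation).max() < 1e-6
        assert np.abs(t.translation - truth.translation).max() < 1e-6
        assert np.abs(t.rotation.T @ t.rotation - np.eye(3)).max() < 1e-10
        assert np.linalg.det(t.rotation) > 0


def test_degenerate_landmark_geometry_is_rejected():
    line = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
    with pytest.raises(ValueError, match="collinear"):
        rigid_from_point_pairs(line, line + 1.0)
    with pytest.raises(ValueError, match="at least 3"):
        rigid_from_point_pairs(line[:2], line[:2])
    pts = np.random.default_rng(0).normal(size=(5, 3))
    bad = pts.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        rigid_from_point_pairs(pts, bad)


def test_closed_form_matches_numerical_minimization_oracle():
    """On small landmark sets, the SVD solution equals brute-force minimization."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        n = int(rng.integers(4, 51))
        p = rng.uniform(-20, 20, (n, 3))
        q = rng.uniform(-20, 20, (n, 3))
        closed = rigid_from_point_pairs(p, q)

        def objective(params):
            rot = rotation_about_axis(
                params[:3] / (np.linalg.norm(params[:3]) + 1e-12),
                np.linalg.norm(params[:3]),
            )
            return ((p @ rot.T + params[3:] - q) ** 2).sum()

        best = None
        for trial in range(4):
            x0 = np.concatenate([rng.normal(0, 0.5, 3), q.mean(0) - p.mean(0)])
            res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        closed_obj = (closed.rms_residual_mm**2) * n
        assert closed_obj <= best.fun + 1e-5


def test_noise_never_helps_the_rigid_fit_on_average(coarse_vus, coarse_case):
    """Adding i.i.d. displacement noise increases the RMS residual in expectation."""
    vu = coarse_vus[8]
    base = coarse_case.true_field
    clean = estimate_local_rigid(vu, base).rms_residual_mm
    rng = np.random.default_rng(2024)
    noisy = []
    for _ in range(100):
        disp = base.displacement + rng.normal(0, 0.3, base.displacement.shape)
        noisy.append(estimate_local_rigid(vu, DeformationField(disp, base.affine)).rms_residual_mm)
    assert np.mean(noisy) >= clean


# --- rigid-only resampling ------------------------------------------------


def test_identity_resampling_reproduces_moving_on_roi(coarse_case, coarse_vus):
    vu = coarse_vus[3]
    res = resample_locally_rigid(
        coarse_case.tp2, RigidTransform.identity(), coarse_case.tp1, vu.voxel_mask, 5.0
    )
    assert np.allclose(res.volume.data[res.valid], coarse_case.tp2.data[res.valid])
    assert res.valid[vu.voxel_mask].all()


def test_one_voxel_translation_matches_index_shift_oracle(coarse_case, coarse_vus):
    sp = coarse_case.tp1.spacing  # axis 1 step is world z under the phantom affine
    t = RigidTransform(np.eye(3), [0.0, 0.0, sp[1]])
    vu = coarse_vus[12]
    res = resample_locally_rigid(coarse_case.tp2, t, coarse_case.tp1, vu.voxel_mask, 0.0)
    sel = vu.voxel_mask
    idx = np.argwhere(sel)
    shifted = coarse_case.tp2.data[idx[:, 0], idx[:, 1] + 1, idx[:, 2]]
    assert np.allclose(res.volume.data[sel], shifted, atol=1e-12)


def test_roi_mapped_fully_outside_moving_extent_is_flagged_invalid(coarse_case, coarse_vus):
    vu = coarse_vus[0]
    t = RigidTransform(np.eye(3), [10000.0, 0.0, 0.0])
    res = resample_locally_rigid(coarse_case.tp2, t, coarse_case.tp1, vu.voxel_mask, 2.0, fill_value=-1.0)
    assert not res.valid.any()
    assert (res.volume.data[res.roi_dilated] == -1.0).all()


def test_global_field_resampling_aligns_the_still_phantom(still_case):
    warped, inside = resample_with_field(still_case.tp2, still_case.true_field)
    assert np.allclose(warped.data[inside], still_case.tp2.data[inside])


# --- direction symmetry ---------------------------------------------------


def test_zero_motion_phantom_gives_identity_in_both_directions(still_case):
    rep = align_reverse_equivalence_check(still_case)
    assert len(rep.rows) == 23
    assert rep.max_rotation_mismatch_deg < 1e-5
    assert rep.max_translation_mismatch_mm < 1e-6


def test_pure_translation_phantom_has_opposite_forward_and_reverse_translations():
    specs = [MotionSpec((0, 0, 1), 0.0, (0.0, 2.5, -2.5)) for _ in range(24)]
    case = generate_spine_phantom(
        PhantomConfig.coarse(seed=5, motion_specs=specs, global_warp_amplitude_mm=0.0, noise_sd=0.0)
    )
    from spinefuse.segmentation import build_vertebral_units

    vus_f = build_vertebral_units(case.mask_tp1)
    vus_r = {v.vu_index: v for v in build_vertebral_units(case.mask_tp2)}
    for vf in vus_f[:5]:
        tf = estimate_local_rigid(vf, case.true_field)
        tr = estimate_local_rigid(vus_r[vf.vu_index], case.true_field_reverse)
        assert np.allclose(tf.translation, -tr.translation, atol=1e-9)


def test_globally_rigid_posture_change_composes_to_identity():
    spec = MotionSpec((1.0, 0.3, 0.1), 1.5, (1.0, -0.8, 0.6), center=(20.0, 45.0, 300.0))
    case = generate_spine_phantom(
        PhantomConfig.coarse(seed=6, motion_specs=[spec] * 24, global_warp_amplitude_mm=0.0, noise_sd=0.0)
    )
    rep = align_reverse_equivalence_check(case)
    assert rep.all_within_tolerance
    assert rep.max_rotation_mismatch_deg < 0.1
    assert rep.max_translation_mismatch_mm < 0.1
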