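"""Label propagation, majority vote, component labeling, vertebral units."""

import collections

import numpy as np
import pytest

from spinefuse.core import DeformationField, LabelMask
from spinefuse.segmentation import (
    SegmentationFailure,
    apply_manual_correction,
    build_vertebral_units,
    extract_and_label_components,
    majority_vote,
    propagate_labels,
    vertebra_label,
)


def _mask(data, affine=None):
    return LabelMask(np.asarray(data), np.eye(4) if affine is None else affine)


def _zero_field(shape, affine=None):
    return DeformationField(np.zeros(shape + (3,)), np.eye(4) if affine is None else affine)


# --- label propagation ----------------------------------------------------


def test_propagation_with_identity_field_reproduces_atlas():
    rng = np.random.default_rng(0)
    atlas = _mask(rng.integers(0, 4, size=(6, 7, 5)))
    out = propagate_labels(atlas, _zero_field((6, 7, 5)))
    assert np.array_equal(out.data, atlas.data)


def test_propagation_with_one_voxel_translation_matches_index_shift_oracle():
    rng = np.random.default_rng(1)
    atlas = _mask(rng.integers(0, 4, size=(6, 7, 5)))
    disp = np.zeros((6, 7, 5, 3))
    disp[..., 1] = 1.0  # one voxel along axis 1 (identity affine: 1 mm)
    out = propagate_labels(atlas, DeformationField(disp, np.eye(4)))
    oracle = np.zeros_like(atlas.data)
    oracle[:, :-1, :] = atlas.data[:, 1:, :]  # border fills with background
    assert np.array_equal(out.data, oracle)


def test_propagation_outside_atlas_extent_is_background():
    atlas = _mask(np.ones((4, 4, 4)))
    disp = np.full((4, 4, 4, 3), 100.0)
    out = propagate_labels(atlas, DeformationField(disp, np.eye(4)))
    assert (out.data == 0).all()


# --- majority vote --------------------------------------------------------


def test_vote_strict_majority_and_all_background():
    c2 = vertebra_label("C2")
    a = _mask(np.full((2, 2, 1), c2))
    b = _mask(np.full((2, 2, 1), c2))
    bg = _mask(np.zeros((2, 2, 1)))
    assert (majority_vote([a, b, bg]).data == c2).all()
    assert (majority_vote([bg, bg, bg]).data == 0).all()


def test_vote_tie_breaks_toward_smallest_label():
    c3, c4 = vertebra_label("C3"), vertebra_label("C4")
    candidates = (
        [_mask(np.full((1, 1, 1), c3))] * 5
        + [_mask(np.full((1, 1, 1), c4))] * 5
        + [_mask(np.zeros((1, 1, 1)))]
    )
    assert majority_vote(candidates).data[0, 0, 0] == c3


def test_vote_matches_exhaustive_per_voxel_count_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = rng.integers(1, 6)
        stack = rng.integers(0, 5, size=(n, 5, 5, 4))
        voted = majority_vote([_mask(s) for s in stack])
        for pos in np.ndindex(5, 5, 4):
            votes = collections.Counter(int(stack[(i, *pos)]) for i in range(n))
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            assert voted.data[pos] == best


def test_vote_rejects_empty_candidate_list_and_grid_mismatch():
    with pytest.raises(ValueError):
        majority_vote([])
    with pytest.raises(Exception, match="grids differ"):
        majority_vote([_mask(np.zeros((2, 2, 2))), _mask(np.zeros((3, 2, 2)))])


# --- connected components and anatomical labeling -------------------------


def _line_components(sizes, spacing=2):
    """Isolated straight-line components of the given sizes, stacked along z."""
    shape = (max(sizes) + 4, 3, spacing * len(sizes) + 2)
    data = np.zeros(shape, dtype=int)
    for i, s in enumerate(sizes):
        data[1 : 1 + s, 1, 1 + spacing * i] = 1
    return _mask(data)


def test_noise_filter_removes_components_under_twenty_voxels():
    mask = _line_components([100, 19, 50])
    labeled = extract_and_label_components(mask, "top_down", "C2")
    assert len(labeled.labels) == 2
    # flood-fill oracle: recompute sizes of surviving components
    survivors = sorted(
        int((labeled.data == lab).sum()) for lab in labeled.labels
    )
    assert survivors == [50, 100]


def test_phantom_bodies_label_c2_to_s1_in_superior_inferior_order(coarse_case):
    binary = LabelMask((coarse_case.mask_tp1.data != 0).astype(int), coarse_case.mask_tp1.affine)
    labeled = extract_and_label_components(binary, "top_down", "C2", expected_count=24)
    assert np.array_equal(labeled.data, coarse_case.mask_tp1.data)


def test_bottom_up_labeling_from_s1_matches_truth_on_lower_spine(clean_case):
    from spinefuse.phantom import split_upper_lower

    _, (vol_l, mask_l) = split_upper_lower(clean_case.tp1, clean_case.mask_tp1)
    binary = LabelMask((mask_l.data != 0).astype(int), mask_l.affine)
    labeled = extract_and_label_components(binary, "bottom_up", "S1")
    assert np.array_equal(labeled.data, mask_l.data)


def test_empty_mask_is_a_segmentation_failure_with_count_zero():
    with pytest.raises(SegmentationFailure) as err:
        extract_and_label_components(_mask(np.zeros((4, 4, 4))), "top_down", "C2")
    assert err.value.count == 0


def test_unexpected_component_count_is_a_segmentation_failure():
    mask = _line_components([30, 40, 25])
    with pytest.raises(SegmentationFailure) as err:
        extract_and_label_components(mask, "top_down", "C2", expected_count=24)
    assert err.value.count == 3
    assert err.value.expected == 24


def test_centroid_tie_uses_secondary_axes_with_warning():
    # two bars at i=1..3 and i=5..7, identical z (axis 2) centroid
    data = np.zeros((9, 3, 3), dtype=int)
    data[1:4, 1, 1] = 1
    data[5:8, 1, 1] = 1
    with pytest.warns(UserWarning, match="tie"):
        labeled = extract_and_label_components(_mask(data), "top_down", "C2", min_size=1)
    with pytest.warns(UserWarning):
        labeled2 = extract_and_label_components(_mask(data), "top_down", "C2", min_size=1)
    assert np.array_equal(labeled.data, labeled2.data)
    assert len(labeled.labels) == 2


# --- vertebral units ------------------------------------------------------


def test_twenty_four_bodies_give_twenty_three_units(coarse_case, coarse_vus):
    assert len(coarse_vus) == 23
    assert (coarse_vus[0].upper_body_label, coarse_vus[0].lower_body_label) == (1, 2)
    assert coarse_vus[0].name.startswith("VU1 (C2/C3")
    assert (coarse_vus[-1].upper_body_label, coarse_vus[-1].lower_body_label) == (23, 24)
    assert coarse_vus[-1].name == "VU23 (L5/S1)"


def test_two_bodies_give_one_unit_of_facing_halves():
    data = np.zeros((3, 10, 3), dtype=int)
    data[1, 6:10, 1] = 1  # upper body (higher z under phantom-style affine)
    data[1, 0:4, 1] = 2
    affine = np.eye(4)
    affine[2, 2] = 1.0  # axis 1 -> world y; keep world z = axis 2? use permuted affine
    # world z must grow with axis 1 for 'upper' to mean higher z:
    affine = np.array([[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1.0]])
    units = build_vertebral_units(LabelMask(data, affine))
    assert len(units) == 1
    vu = units[0]
    # facing halves: lower half of body 1 (j=6,7) + upper half of body 2 (j=2,3)
    expected = np.zeros_like(data, dtype=bool)
    expected[1, 6:8, 1] = True
    expected[1, 2:4, 1] = True
    assert np.array_equal(vu.voxel_mask, expected)


def test_symmetric_slab_splits_into_equal_halves(coarse_case, coarse_vus):
    """Bodies are symmetric slabs: each interior body is halved by its centroid."""
    mask = coarse_case.mask_tp1
    for vu in coarse_vus[:3]:
        upper = mask.data == vu.upper_body_label
        in_vu = vu.voxel_mask & upper
        frac = in_vu.sum() / upper.sum()
        assert abs(frac - 0.5) < 0.15  # voxel-quantized halves


def test_unit_halves_partition_each_interior_body(coarse_case, coarse_vus):
    mask = coarse_case.mask_tp1
    by_upper = {v.upper_body_label: v for v in coarse_vus}
    by_lower = {v.lower_body_label: v for v in coarse_vus}
    for lab in range(2, 24):  # interior bodies
        body = mask.data == lab
        lower_half = by_upper[lab].voxel_mask & body
        upper_half = by_lower[lab].voxel_mask & body
        assert not (lower_half & upper_half).any()
        assert np.array_equal(lower_half | upper_half, body)


def test_missing_intermediate_label_is_reported():
    data = np.zeros((3, 12, 3), dtype=int)
    affine = np.array([[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1.0]])
    data[1, 9:11, 1] = 1
    data[1, 5:7, 1] = 2
    data[1, 1:3, 1] = 4  # label 3 missing
    with pytest.raises(ValueError, match="C4"):
        build_vertebral_units(LabelMask(data, affine))


# --- manual correction ----------------------------------------------------


def test_empty_correction_is_identity(coarse_case):
    out, log = apply_manual_correction(
        coarse_case.mask_tp1, LabelMask(np.zeros(coarse_case.mask_tp1.shape), coarse_case.mask_tp1.affine)
    )
    assert np.array_equal(out.data, coarse_case.mask_tp1.data)
    assert log == []


def test_correction_adds_missing_body_without_touching_others(coarse_case):
    auto = coarse_case.mask_tp1
    th10 = vertebra_label("Th10")
    incomplete = LabelMask(np.where(auto.data == th10, 0, auto.data), auto.affine)
    correction = LabelMask(np.where(auto.data == th10, th10, 0), auto.affine)
    fixed, log = apply_manual_correction(incomplete, correction)
    assert np.array_equal(fixed.data, auto.data)
    assert log == [(th10, int((auto.data == th10).sum()))]


def test_correction_creating_duplicate_disjoint_body_is_rejected(coarse_case):
    auto = coarse_case.mask_tp1
    c3, c4 = vertebra_label("C3"), vertebra_label("C4")
    correction = LabelMask(np.where(auto.data == c3, c4, 0), auto.affine)
    with pytest.raises(ValueError, match="C4"):
        apply_manual_correction(auto, correction)
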