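"""Atlas-based vertebral-body segmentation, anatomical labeling, and vertebral units.

Pipeline: labels from each registered atlas are propagated onto the target
grid (nearest-neighbor through the target->atlas deformation field), fused
by a per-voxel majority vote (background votes too), cleaned by a
26-connectivity component filter that drops components under 20 voxels,
and labeled anatomically in superior->inferior order (C2 first) or
inferior->superior order (S1 first) for lower-spine acquisitions. Adjacent
labeled bodies are then paired into vertebral units: unit k joins bodies k
and k+1 and covers the region between their mid-points, so 24 bodies
(C2..S1) yield exactly 23 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DeformationField, GridMismatchError, LabelMask, voxel_from_world

__all__ = [
    "VERTEBRA_NAMES",
    "vertebra_label",
    "SegmentationFailure",
    "VertebralUnit",
    "propagate_labels",
    "majority_vote",
    "extract_and_label_components",
    "build_vertebral_units",
    "apply_manual_correction",
    "MIN_COMPONENT_VOXELS",
]

#: Anatomical names for body labels 1..24 (C2..S1).
VERTEBRA_NAMES = (
    ["C2", "C3", "C4", "C5", "C6", "C7"]
    + [f"Th{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["S1"]
)

#: Components smaller than this many voxels are treated as noise.
MIN_COMPONENT_VOXELS = 20

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def vertebra_label(name: str) -> int:
    """Label value (1..24) for an anatomical name like 'C2', 'Th10', 'S1'."""
    try:
        return VERTEBRA_NAMES.index(name) + 1
    except ValueError:
        raise ValueError(f"unknown vertebra name {name!r}") from None


class SegmentationFailure(RuntimeError):
    """Vertebra count after filtering does not match the expected anatomy.

    Carries the observed component count so callers can report it (and,
    in an interactive setting, fall back to manual correction).
    """

    def __init__(self, count: int, expected: int | None = None):
        self.count = count
        self.expected = expected
        msg = f"found {count} vertebral component(s)"
        if expected is not None:
            msg += f", expected {expected}"
        super().__init__(msg)


def propagate_labels(atlas_mask: LabelMask, field_target_to_atlas: DeformationField) -> LabelMask:
    """Map an atlas label mask onto the target grid through a deformation field.

    Each target voxel takes the atlas label at its mapped world position
    (nearest-neighbor); positions falling outside the atlas extent become
    background.
    """
    field = field_target_to_atlas
    mapped = field.mapped_positions()  # (*target_grid, 3) world mm
    atlas_idx = voxel_from_world(atlas_mask.affine, mapped)
    coords = np.moveaxis(atlas_idx, -1, 0)
    out = ndimage.map_coordinates(
        atlas_mask.data, coords, order=0, mode="constant", cval=0, output=np.int16
    )
    return LabelMask(out, field.affine)


def majority_vote(candidates: list[LabelMask]) -> LabelMask:
    """Per-voxel majority vote over candidate label volumes.

    Background counts as a candidate label; ties are broken toward the
    smallest label value (deterministic).
    """
    if not candidates:
        raise ValueError("majority_vote needs at least one candidate")
    first = candidates[0]
    for c in candidates[1:]:
        first.require_same_grid(c, "majority_vote candidates")
    stack = np.stack([c.data for c in candidates])
    max_label = int(stack.max())
    counts = np.empty((max_label + 1,) + first.shape, dtype=np.int32)
    for lab in range(max_label + 1):
        counts[lab] = (stack == lab).sum(axis=0)
    winner = counts.argmax(axis=0)  # argmax takes the first (smallest) max label
    return LabelMask(winner.astype(np.int16), first.affine)


def _superior_axis_coords(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """World superior-inferior (z) coordinate of voxel indices."""
    return idx @ affine[2, :3] + affine[2, 3]


def extract_and_label_components(
    mask: LabelMask,
    direction: str,
    start_label: str = "C2",
    expected_count: int | None = None,
    min_size: int = MIN_COMPONENT_VOXELS,
) -> LabelMask:
    """Find vertebral bodies as 3D connected components and label them anatomically.

    Components are computed with 26-connectivity; those under ``min_size``
    voxels are removed as noise. Survivors are ordered by their centroid
    along the world superior-inferior axis — descending for ``top_down``
    (the topmost component becomes ``start_label``, e.g. C2), ascending for
    ``bottom_up`` (the bottommost becomes ``start_label``, e.g. S1) — and
    assigned consecutive anatomical labels. Ties on the sort axis fall back
    to the anterior-posterior, then left-right centroid (with a warning).

    Raises :class:`SegmentationFailure` if no component survives, or the
    surviving count differs from ``expected_count``.
    """
    if direction not in ("top_down", "bottom_up"):
        raise ValueError("direction must be 'top_down' or 'bottom_up'")
    binary = mask.data != 0
    comp, n = ndimage.label(binary, structure=_CONNECTIVITY_26)
    if n == 0:
        raise SegmentationFailure(0, expected_count)
    sizes = np.bincount(comp.ravel())
    keep = [i for i in range(1, n + 1) if sizes[i] >= min_size]
    if not keep:
        raise SegmentationFailure(0, expected_count)
    if expected_count is not None and len(keep) != expected_count:
        raise SegmentationFailure(len(keep), expected_count)

    centroids_idx = np.array(ndimage.center_of_mass(binary, comp, keep))
    world = centroids_idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    # Sort key: superior-inferior first, then anterior-posterior, then
    # left-right for determinism on exact ties.
    z = world[:, 2]
    if len(set(np.round(z, 9))) < len(z):
        import warnings

        warnings.warn(
            "component centroids tie along the superior-inferior axis; "
            "using anterior-posterior/left-right tie-break",
            stacklevel=2,
        )
    order = np.lexsort((world[:, 0], world[:, 1], z))
    if direction == "top_down":
        order = order[::-1]  # descending z: topmost first

    start = vertebra_label(start_label)
    out = np.zeros_like(mask.data, dtype=np.int16)
    for rank, ci in enumerate(order):
        anat = start + rank if direction == "top_down" else start - rank
        if not (1 <= anat <= len(VERTEBRA_NAMES)):
            raise SegmentationFailure(len(keep), expected_count)
        out[comp == keep[ci]] = anat
    return LabelMask(out, mask.affine)


@dataclass
class VertebralUnit:
    """The region between the mid-points of two adjacent vertebral bodies.

    Unit ``k`` joins body ``k`` (upper) and ``k + 1`` (lower): its mask is
    the inferior half of the upper body plus the superior half of the lower
    body, the halves being split at each body's voxel-centroid coordinate
    along the superior-inferior axis.
    """

    vu_index: int
    upper_body_label: int
    lower_body_label: int
    voxel_mask: np.ndarray  # bool, on the target grid
    affine: np.ndarray

    @property
    def name(self) -> str:
        return (
            f"VU{self.vu_index} "
            f"({VERTEBRA_NAMES[self.upper_body_label - 1]}/"
            f"{VERTEBRA_NAMES[self.lower_body_label - 1]})"
        )

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_mask.sum())


def build_vertebral_units(labeled: LabelMask) -> list[VertebralUnit]:
    """Construct vertebral units from an anatomically labeled body mask.

    Requires a consecutive run of at least two labels; a missing
    intermediate label is an error (it would silently skip a unit).
    """
    labels = [int(v) for v in labeled.labels]
    if len(labels) < 2:
        raise ValueError("need at least two labeled bodies to build vertebral units")
    gaps = [v for v in range(labels[0], labels[-1] + 1) if v not in labels]
    if gaps:
        names = ", ".join(VERTEBRA_NAMES[g - 1] for g in gaps)
        raise ValueError(f"labeled mask has gaps at {names}; cannot pair adjacent bodies")

    idx = np.argwhere(labeled.data != 0)
    vals = labeled.data[labeled.data != 0]
    z = _superior_axis_coords(labeled.affine, idx)
    z_all = np.full(labeled.shape, np.nan)
    z_all[tuple(idx.T)] = z
    mid = {lab: float(z[vals == lab].mean()) for lab in labels}

    units = []
    for upper, lower in zip(labels[:-1], labels[1:]):
        upper_half = (labeled.data == upper) & (z_all <= mid[upper])
        lower_half = (labeled.data == lower) & (z_all > mid[lower])
        units.append(
            VertebralUnit(
                vu_index=upper,
                upper_body_label=upper,
                lower_body_label=lower,
                voxel_mask=upper_half | lower_half,
                affine=labeled.affine,
            )
        )
    return units


def apply_manual_correction(
    auto: LabelMask, correction: LabelMask
) -> tuple[LabelMask, list[tuple[int, int]]]:
    """Override automatic labels with nonzero correction voxels.

    Returns the corrected mask and a provenance log of
    ``(label, n_voxels_overridden)`` pairs. Raises if the merge leaves any
    label split into disjoint components (a duplicated body).
    """
    auto.require_same_grid(correction, "apply_manual_correction")
    merged = auto.data.copy()
    sel = correction.data != 0
    merged[sel] = correction.data[sel]
    log = []
    for lab in np.unique(correction.data[sel]):
        log.append((int(lab), int((correction.data[sel] == lab).sum())))
    for lab in np.unique(merged[merged != 0]):
        _, n = ndimage.label(merged == lab, structure=_CONNECTIVITY_26)
        if n > 1:
            raise ValueError(
                f"correction leaves label {VERTEBRA_NAMES[int(lab) - 1]} "
                f"split into {n} disjoint components"
            )
    return LabelMask(merged, auto.affine), log
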