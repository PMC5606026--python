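"""Synthetic two-time-point spine phantoms with exact ground truth.

The phantom emulates the geometry of a sagittal STIR acquisition of the
whole spine: thin in-plane voxels, thick slices (4 mm slice + 0.4 mm gap =
4.4 mm between slice centers), 24 vertebral bodies (C2..S1) stacked along
the superior-inferior axis with disc gaps, and hyperintense bone-marrow
lesions whose amplitude changes between the two time points.

Time point 2 is constructed analytically as

    TP2 anatomy = (global smooth posture warp) o (per-body rigid motion)

applied to the TP1 anatomy, with lesion amplitudes swapped to their TP2
values. The exact TP1->TP2 position mapping is recorded as a dense
deformation field (and its numerical inverse on the TP2 grid), so every
downstream stage — label propagation, locally rigid estimation, fusion,
change quantification — can be tested against exact truth with no
registration run.

Intensities are arbitrary units loosely shaped after STIR contrast:
dim soft-tissue background, moderate vertebral marrow, bright edema blobs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DeformationField,
    LabelMask,
    RigidTransform,
    VolumeGrid,
    rotation_about_axis,
    world_from_voxel,
)

__all__ = [
    "PhantomError",
    "LesionSpec",
    "MotionSpec",
    "PhantomConfig",
    "PhantomCase",
    "Atlas",
    "SmoothWarp",
    "generate_spine_phantom",
    "generate_atlas_set",
    "split_upper_lower",
]

# Intensity model (arbitrary units).
BACKGROUND_INTENSITY = 0.10
MARROW_INTENSITY = 0.35

# Canonical vertebral-body geometry (mm). Bodies are rounded superellipsoid
# slabs; half-sizes along world (x=left-right, y=anterior-posterior,
# z=superior-inferior), i.e. 20 mm tall bodies with 4 mm disc gaps.
BODY_HALF_MM = np.array([12.0, 15.0, 10.0])
DISC_GAP_MM = 4.0
SUPERIOR_MARGIN_MM = 10.0

# Lesion-amplitude -> truth-score mapping (fixed, monotone in the
# TP2/TP1 amplitude ratio; the scale endpoints mean "dramatic" change).
_AMP_EPS = 0.05
_NEW_LESION_DRAMATIC = 0.3
_RATIO_DRAMATIC = 2.0
_RATIO_MILD = 1.25


class PhantomError(ValueError):
    """Invalid phantom configuration (lesion outside body, bodies colliding, ...)."""


@dataclass(frozen=True)
class LesionSpec:
    """A marrow edema lesion hosted by the upper body of vertebral unit ``vu_index``.

    The lesion is a smooth ellipsoidal hyperintensity sitting against the
    lower endplate of its host body (the typical location of inflammatory
    corner/endplate lesions): ``radius_mm`` is the in-plane semi-axis,
    ``height_mm`` the superior-inferior semi-axis. The defaults occupy
    roughly a tenth of the vertebral unit's bone volume — a mild lesion on
    the Berlin fraction scale.
    """

    vu_index: int
    amplitude_tp1: float
    amplitude_tp2: float
    radius_mm: float = 9.0
    height_mm: float = 4.5


@dataclass(frozen=True)
class MotionSpec:
    """Per-body rigid perturbation: rotation about a center, then translation.

    The rotation center defaults to the body's own center; an explicit
    ``center`` (shared across bodies) expresses a globally rigid posture
    change, under which every vertebral unit sees one and the same world
    transform.
    """

    axis: tuple[float, float, float]
    angle_deg: float
    translation_mm: tuple[float, float, float]
    center: tuple[float, float, float] | None = None

    def as_transform(self, body_center: np.ndarray) -> RigidTransform:
        if self.angle_deg == 0.0:
            rot = np.eye(3)
        else:
            rot = rotation_about_axis(np.asarray(self.axis), np.radians(self.angle_deg))
        c = body_center if self.center is None else np.asarray(self.center, dtype=float)
        return RigidTransform.about_center(rot, c, np.asarray(self.translation_mm))


def _default_lesions() -> list[LesionSpec]:
    # An increasing lesion, a decreasing lesion (the canonical demonstration
    # pair), and one stable lesion.
    return [
        LesionSpec(21, 0.15, 0.55),
        LesionSpec(22, 0.55, 0.15),
        LesionSpec(5, 0.40, 0.40, 6.0, 3.0),
    ]


@dataclass
class PhantomConfig:
    """Parameters of a two-time-point spine phantom.

    Defaults emulate the sagittal acquisition geometry: 1.25 mm in-plane
    voxels (380 mm field of view at a ~300 acquisition matrix) and 4.4 mm
    between slice centers (4 mm slices with a 0.4 mm gap), with 24
    vertebral bodies so that vertebral-unit construction yields 23 units.
    """

    grid_shape: tuple[int, int, int] = (72, 480, 9)
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 4.4)
    n_bodies: int = 24
    lesion_specs: list[LesionSpec] = field(default_factory=_default_lesions)
    motion_specs: list[MotionSpec] | None = None
    max_rotation_deg: float = 2.0
    max_translation_mm: float = 1.5
    global_warp_amplitude_mm: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0

    @classmethod
    def coarse(cls, **overrides) -> "PhantomConfig":
        """Compact test geometry: 2.5 mm in-plane, 5 slices, same anatomy."""
        cfg = cls(grid_shape=(36, 240, 5), spacing_mm=(2.5, 2.5, 4.4))
        return replace(cfg, **overrides)

    def validate(self) -> None:
        if self.n_bodies < 2:
            raise PhantomError("n_bodies must be >= 2")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing must be strictly positive")
        if any(s < 2 for s in self.grid_shape):
            raise PhantomError("grid too small")
        for les in self.lesion_specs:
            if les.amplitude_tp1 < 0 or les.amplitude_tp2 < 0:
                raise PhantomError("lesion amplitudes must be >= 0")
            if not (1 <= les.vu_index <= self.n_bodies - 1):
                raise PhantomError(
                    f"lesion VU index {les.vu_index} outside 1..{self.n_bodies - 1}: "
                    "no host body"
                )
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        # Spine must fit in the grid along the superior-inferior axis.
        z_extent = (self.grid_shape[1] - 1) * self.spacing_mm[1]
        span = SUPERIOR_MARGIN_MM + self.n_bodies * self.body_pitch_mm + SUPERIOR_MARGIN_MM
        if z_extent < span:
            raise PhantomError(
                f"grid z-extent {z_extent:.0f} mm cannot hold {self.n_bodies} bodies "
                f"({span:.0f} mm needed)"
            )

    @property
    def body_pitch_mm(self) -> float:
        return 2 * BODY_HALF_MM[2] + DISC_GAP_MM

    def affine(self) -> np.ndarray:
        """Sagittal-stack affine: array axes (i, j, k) -> world (y, z, x).

        Axis i runs anterior-posterior, j inferior-superior, k is the
        slice (left-right) direction — a proper (det > 0) scaled
        permutation, so orientation handling is genuinely exercised.
        """
        si, sj, sk = self.spacing_mm
        a = np.zeros((4, 4))
        a[1, 0] = si
        a[2, 1] = sj
        a[0, 2] = sk
        a[3, 3] = 1.0
        return a

    def to_json(self) -> str:
        d = {
            "grid_shape": list(self.grid_shape),
            "spacing_mm": list(self.spacing_mm),
            "n_bodies": self.n_bodies,
            "lesion_specs": [
                [l.vu_index, l.amplitude_tp1, l.amplitude_tp2, l.radius_mm, l.height_mm]
                for l in self.lesion_specs
            ],
            "motion_specs": None
            if self.motion_specs is None
            else [
                [list(m.axis), m.angle_deg, list(m.translation_mm),
                 None if m.center is None else list(m.center)]
                for m in self.motion_specs
            ],
            "max_rotation_deg": self.max_rotation_deg,
            "max_translation_mm": self.max_translation_mm,
            "global_warp_amplitude_mm": self.global_warp_amplitude_mm,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomConfig":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["spacing_mm"] = tuple(d["spacing_mm"])
        d["lesion_specs"] = [LesionSpec(*row) for row in d.get("lesion_specs", [])]
        if d.get("motion_specs") is not None:
            d["motion_specs"] = [
                MotionSpec(tuple(row[0]), row[1], tuple(row[2]),
                           None if len(row) < 4 or row[3] is None else tuple(row[3]))
                for row in d["motion_specs"]
            ]
        return cls(**d)


@dataclass
class SmoothWarp:
    """Low-frequency posture deformation: sinusoidal displacement along the spine.

    Displacement depends on the superior-inferior coordinate only, with
    per-axis amplitude weights (anterior-posterior bending dominates, as in
    a posture change between scanning sessions). Amplitudes stay well below
    the inversion limit, so the warp is a bijection and its inverse is
    computed by fixed-point iteration.
    """

    amplitude_mm: float
    weights: np.ndarray  # (3,)
    wavelengths_mm: np.ndarray  # (3,)
    phases: np.ndarray  # (3,)
    z0: float = 0.0

    @classmethod
    def sample(cls, amplitude_mm: float, rng: np.random.Generator, span_mm: float) -> "SmoothWarp":
        w = np.array([0.3, 1.0, 0.3]) * rng.uniform(0.5, 1.0, 3)
        lam = span_mm * rng.choice([1.0, 2.0], 3)
        ph = rng.uniform(0, 2 * np.pi, 3)
        return cls(amplitude_mm, w, lam, ph)

    @classmethod
    def zero(cls) -> "SmoothWarp":
        return cls(0.0, np.zeros(3), np.ones(3), np.zeros(3))

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        if self.amplitude_mm == 0.0:
            return np.zeros_like(pts)
        z = pts[..., 2]
        out = np.empty_like(pts)
        for a in range(3):
            out[..., a] = (
                self.amplitude_mm
                * self.weights[a]
                * np.sin(2 * np.pi * (z - self.z0) / self.wavelengths_mm[a] + self.phases[a])
            )
        return out

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)

    def invert(self, pts: np.ndarray, n_iter: int = 12) -> np.ndarray:
        """Solve W(q) = pts for q by fixed-point iteration (contractive warp)."""
        if self.amplitude_mm == 0.0:
            return np.array(pts, dtype=float, copy=True)
        q = np.array(pts, dtype=float, copy=True)
        for _ in range(n_iter):
            q = pts - self.displacement(q)
        return q


@dataclass
class _Body:
    label: int  # 1..24 (C2..S1)
    center: np.ndarray  # canonical world center, mm
    half: np.ndarray  # (hx, hy, hz) half sizes, mm
    lesions: list[tuple[np.ndarray, np.ndarray, float, float]]  # (offset, semi-axes, amp1, amp2)


def _inside_body(local: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Rounded-slab membership: superellipsoid of exponent 4."""
    return ((np.abs(local) / half) ** 4).sum(axis=-1) <= 1.0


def _lesion_bump(
    local: np.ndarray, offset: np.ndarray, semi: np.ndarray, amp: float
) -> np.ndarray:
    """Compactly supported smooth ellipsoidal bump (cosine profile)."""
    d = np.sqrt((((local - offset) / semi) ** 2).sum(axis=-1))
    out = np.zeros(local.shape[:-1])
    sel = d < 1.0
    out[sel] = amp * 0.5 * (1.0 + np.cos(np.pi * d[sel]))
    return out


def _build_bodies(config: PhantomConfig, half_scale: np.ndarray | None = None) -> list[_Body]:
    si, sj, sk = config.spacing_mm
    ni, nj, nk = config.grid_shape
    center_y = (ni - 1) * si / 2.0
    center_x = (nk - 1) * sk / 2.0
    z_top = (nj - 1) * sj - SUPERIOR_MARGIN_MM - BODY_HALF_MM[2]
    bodies = []
    for b in range(config.n_bodies):
        half = BODY_HALF_MM.copy()
        if half_scale is not None:
            half = half * half_scale[b]
        center = np.array([center_x, center_y, z_top - b * config.body_pitch_mm])
        bodies.append(_Body(label=b + 1, center=center, half=half, lesions=[]))
    # Attach lesions to the upper body of their vertebral unit, centered in
    # that body's inferior half (near the lower endplate, where inflammatory
    # corner lesions sit), entirely below the body mid-point so the change
    # stays within its unit.
    for les in config.lesion_specs:
        body = bodies[les.vu_index - 1]
        semi = np.array([les.radius_mm, les.radius_mm, les.height_mm])
        offset = np.array([0.0, 0.0, -body.half[2] / 2.0])
        hz = body.half[2]
        fits = (
            les.height_mm <= hz / 2.0 - 0.5
            and les.radius_mm <= min(body.half[0], body.half[1]) - 0.5
        )
        if fits:
            # Parametric containment check of the ellipsoid in the
            # superellipsoid, sliced along the superior-inferior axis.
            z = np.linspace(-les.height_mm, les.height_mm, 21)
            les_rad = np.sqrt(np.clip(1.0 - (z / les.height_mm) ** 2, 0.0, 1.0))
            body_room = (1.0 - ((offset[2] + z) / hz) ** 4) ** 0.25
            for a in (0, 1):
                if np.any(semi[a] * les_rad > body.half[a] * body_room - 0.25):
                    fits = False
        if not fits:
            raise PhantomError(
                f"lesion ({les.radius_mm} x {les.height_mm} mm) does not fit inside "
                f"the host body of VU {les.vu_index} (half-sizes {body.half} mm)"
            )
        body.lesions.append((offset, semi, les.amplitude_tp1, les.amplitude_tp2))
    return bodies


def _bbox_slices(
    config: PhantomConfig, center: np.ndarray, half: np.ndarray, margin_mm: float
) -> tuple[slice, slice, slice]:
    """Index-space bounding box of a world-space axis-aligned box."""
    lo = center - half - margin_mm
    hi = center + half + margin_mm
    corners = np.array([[lo[a] if b & (1 << a) else hi[a] for a in range(3)] for b in range(8)])
    inv = np.linalg.inv(config.affine())
    idx = corners @ inv[:3, :3].T + inv[:3, 3]
    lo_i = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
    hi_i = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + 1, config.grid_shape)
    return tuple(slice(lo_i[a], hi_i[a]) for a in range(3))


def _grid_points(config: PhantomConfig, slices: tuple[slice, slice, slice]) -> np.ndarray:
    ranges = [np.arange(s.start, s.stop) for s in slices]
    idx = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
    return world_from_voxel(config.affine(), idx)


def _rasterize_tp1(
    config: PhantomConfig, bodies: list[_Body], marrow: float = MARROW_INTENSITY
) -> tuple[np.ndarray, np.ndarray]:
    vol = np.full(config.grid_shape, BACKGROUND_INTENSITY)
    lab = np.zeros(config.grid_shape, dtype=np.int16)
    for body in bodies:
        sl = _bbox_slices(config, body.center, body.half, 1.0)
        pts = _grid_points(config, sl)
        local = pts - body.center
        inside = _inside_body(local, body.half)
        val = np.full(local.shape[:-1], marrow)
        for offset, semi, amp1, _ in body.lesions:
            val += _lesion_bump(local, offset, semi, amp1)
        vol[sl][inside] = val[inside]
        lab[sl][inside] = body.label
    return vol, lab


def _truth_change_score(a1: float, a2: float) -> int:
    if a1 < _AMP_EPS and a2 < _AMP_EPS:
        return 0
    if a1 < _AMP_EPS:
        return 2 if a2 >= _NEW_LESION_DRAMATIC else 1
    if a2 < _AMP_EPS:
        return -2 if a1 >= _NEW_LESION_DRAMATIC else -1
    r = a2 / a1
    if r >= _RATIO_DRAMATIC:
        return 2
    if r >= _RATIO_MILD:
        return 1
    if r > 1.0 / _RATIO_MILD:
        return 0
    if r > 1.0 / _RATIO_DRAMATIC:
        return -1
    return -2


@dataclass
class PhantomCase:
    """A generated two-time-point case with exhaustive ground truth."""

    tp1: VolumeGrid
    tp2: VolumeGrid
    mask_tp1: LabelMask
    mask_tp2: LabelMask
    true_field: DeformationField  # TP1 grid -> TP2 positions
    true_field_reverse: DeformationField  # TP2 grid -> TP1 positions
    true_rigid_per_body: list[RigidTransform]
    true_vu_change: dict[int, int]
    config: PhantomConfig

    def truth_json(self) -> str:
        return json.dumps(
            {
                "true_rigid_per_body": [t.to_matrix().tolist() for t in self.true_rigid_per_body],
                "true_vu_change": {str(k): v for k, v in self.true_vu_change.items()},
            },
            indent=2,
        )


def generate_spine_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a fully ground-truthed two-time-point spine phantom.

    Deterministic: identical config (including seed) yields bit-identical
    arrays. Raises :class:`PhantomError` if a lesion cannot fit inside its
    host body or the per-body motion makes bodies overlap at time point 2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bodies = _build_bodies(config)
    affine = config.affine()

    # Per-body rigid motion (sampled unless given explicitly).
    if config.motion_specs is not None:
        if len(config.motion_specs) != config.n_bodies:
            raise PhantomError(
                f"motion_specs has {len(config.motion_specs)} entries, "
                f"need {config.n_bodies}"
            )
        specs = list(config.motion_specs)
    else:
        specs = []
        for _ in range(config.n_bodies):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0, config.max_rotation_deg)
            trans = rng.uniform(-config.max_translation_mm, config.max_translation_mm, 3)
            specs.append(MotionSpec(tuple(axis), float(angle), tuple(trans)))
    rigids = [spec.as_transform(body.center) for spec, body in zip(specs, bodies)]

    if config.global_warp_amplitude_mm > 0:
        span = config.n_bodies * config.body_pitch_mm
        warp = SmoothWarp.sample(config.global_warp_amplitude_mm, rng, span)
    else:
        _ = rng  # keep draw order stable regardless of warp setting
        warp = SmoothWarp.zero()

    # --- TP1: canonical anatomy ---
    vol1, lab1 = _rasterize_tp1(config, bodies)

    # --- TP2: warp o rigid applied to TP1 anatomy, lesion amps swapped ---
    full_sl = tuple(slice(0, s) for s in config.grid_shape)
    x = _grid_points(config, full_sl)  # (I, J, K, 3)
    y = warp.invert(x)  # undo the global warp
    vol2 = np.full(config.grid_shape, BACKGROUND_INTENSITY)
    lab2 = np.zeros(config.grid_shape, dtype=np.int16)
    rev_target = np.array(y)  # background voxels map back through the warp only
    motion_margin = config.max_translation_mm + config.global_warp_amplitude_mm + 3.0
    for body, rigid in zip(bodies, rigids):
        sl = _bbox_slices(config, body.center, body.half, motion_margin)
        q = rigid.inverse().apply(y[sl])
        local = q - body.center
        inside = _inside_body(local, body.half)
        if np.any(lab2[sl][inside] != 0):
            raise PhantomError(
                f"per-body motion makes body {body.label} overlap a neighbor at TP2; "
                "reduce rotation/translation limits"
            )
        val = np.full(local.shape[:-1], MARROW_INTENSITY)
        for offset, semi, _, amp2 in body.lesions:
            val += _lesion_bump(local, offset, semi, amp2)
        vol2[sl][inside] = val[inside]
        lab2[sl][inside] = body.label
        rev_target[sl][inside] = q[inside]

    # --- exact forward deformation field on the TP1 grid ---
    disp_fwd = warp.apply(x) - x
    for body, rigid in zip(bodies, rigids):
        sel = lab1 == body.label
        moved = rigid.apply(x[sel])
        disp_fwd[sel] = warp.apply(moved) - x[sel]
    disp_rev = rev_target - x

    if config.noise_sd > 0:
        vol1 = vol1 + rng.normal(0.0, config.noise_sd, config.grid_shape)
        vol2 = vol2 + rng.normal(0.0, config.noise_sd, config.grid_shape)

    # --- truth change score per vertebral unit from lesion amplitudes ---
    true_change = {}
    for vu in range(1, config.n_bodies):
        a1 = sum(l.amplitude_tp1 for l in config.lesion_specs if l.vu_index == vu)
        a2 = sum(l.amplitude_tp2 for l in config.lesion_specs if l.vu_index == vu)
        true_change[vu] = _truth_change_score(a1, a2)

    return PhantomCase(
        tp1=VolumeGrid(vol1, affine),
        tp2=VolumeGrid(vol2, affine),
        mask_tp1=LabelMask(lab1, affine),
        mask_tp2=LabelMask(lab2, affine),
        true_field=DeformationField(disp_fwd, affine),
        true_field_reverse=DeformationField(disp_rev, affine),
        true_rigid_per_body=rigids,
        true_vu_change=true_change,
        config=config,
    )


@dataclass
class Atlas:
    """One labeled reference case plus the analytic mapping from the canonical frame.

    Unpacks as a ``(volume, mask)`` pair. ``field_from_reference`` is the
    dense displacement taking canonical-frame (target) positions to this
    atlas's positions — the quantity a registration run would estimate.
    """

    volume: VolumeGrid
    mask: LabelMask
    field_from_reference: DeformationField
    warp: SmoothWarp

    def __iter__(self):
        return iter((self.volume, self.mask))


def _erode_mask_mm(lab: np.ndarray, spacing: np.ndarray, margin_mm: float) -> np.ndarray:
    """Remove foreground voxels within ``margin_mm`` of the background."""
    from scipy import ndimage

    if margin_mm <= 0:
        return lab.copy()
    dist = ndimage.distance_transform_edt(lab != 0, sampling=spacing)
    out = lab.copy()
    out[dist <= margin_mm] = 0
    return out


def generate_atlas_set(
    n_atlases: int,
    base_config: PhantomConfig,
    seed: int,
    under_segment_mm: float = 1.3,
    shape_jitter: float = 0.03,
    intensity_jitter: float = 0.05,
    warp_amplitude_mm: float = 2.0,
    atlas_noise_sd: float = 0.01,
) -> list[Atlas]:
    """Generate independently perturbed labeled atlases of the canonical spine.

    Each atlas applies its own smooth posture warp plus per-body shape and
    intensity jitter to the canonical anatomy. Masks deliberately
    under-segment the bone: the outline stays inside the cortex (default
    margin about one in-plane voxel), because for locally rigid alignment a
    region that stays within bone beats one that spills into non-rigid soft
    tissue.
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    base_config.validate()
    affine = base_config.affine()
    span = base_config.n_bodies * base_config.body_pitch_mm
    spacing = np.asarray(base_config.spacing_mm)
    rng = np.random.default_rng(seed)
    atlases = []
    for _ in range(n_atlases):
        scale = np.clip(rng.normal(1.0, shape_jitter, base_config.n_bodies), 0.92, 1.08)
        marrow = MARROW_INTENSITY * float(np.clip(rng.normal(1.0, intensity_jitter), 0.8, 1.2))
        warp = (
            SmoothWarp.sample(warp_amplitude_mm, rng, span)
            if warp_amplitude_mm > 0
            else SmoothWarp.zero()
        )
        bodies = _build_bodies(replace(base_config, lesion_specs=[]), half_scale=scale)
        # Atlas anatomy = canonical anatomy pushed through this atlas's warp.
        full_sl = tuple(slice(0, s) for s in base_config.grid_shape)
        x = _grid_points(base_config, full_sl)
        q = warp.invert(x)
        vol = np.full(base_config.grid_shape, BACKGROUND_INTENSITY)
        lab = np.zeros(base_config.grid_shape, dtype=np.int16)
        for body in bodies:
            sl = _bbox_slices(base_config, body.center, body.half, warp_amplitude_mm + 2.0)
            local = q[sl] - body.center
            inside = _inside_body(local, body.half)
            vol[sl][inside] = marrow
            lab[sl][inside] = body.label
        if atlas_noise_sd > 0:
            vol = vol + rng.normal(0.0, atlas_noise_sd, base_config.grid_shape)
        lab_eroded = _erode_mask_mm(lab, spacing, under_segment_mm)
        field = DeformationField(warp.displacement(x), affine)
        atlases.append(
            Atlas(
                volume=VolumeGrid(vol, affine),
                mask=LabelMask(lab_eroded, affine),
                field_from_reference=field,
                warp=warp,
            )
        )
    return atlases


def _crop_j(grid_like, j0: int, j1: int):
    """Crop a VolumeGrid/LabelMask along array axis 1, shifting the affine origin."""
    cls = type(grid_like)
    data = grid_like.data[:, j0:j1, :]
    affine = grid_like.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.array([0.0, j0, 0.0])
    return cls(data, affine)


def split_upper_lower(
    volume: VolumeGrid,
    mask: LabelMask,
    split_label: int = 14,
    overlap_bodies: int = 2,
) -> tuple[tuple[VolumeGrid, LabelMask], tuple[VolumeGrid, LabelMask]]:
    """Crop a whole-spine case into overlapping upper and lower acquisitions.

    Mirrors two-stage spine imaging: the upper image covers C2 down to
    ``split_label + overlap_bodies - 1``, the lower image covers
    ``split_label - overlap_bodies`` down to S1. The cropped masks keep
    their original labels (tests typically binarize and relabel them).
    """
    volume.require_same_grid(mask, "split_upper_lower")
    labels = mask.labels
    if split_label not in labels:
        raise ValueError(f"split label {split_label} not present in mask")
    j_idx = np.nonzero(mask.data)[1]
    lab_of = mask.data[np.nonzero(mask.data)]

    def j_range(lab_lo, lab_hi):
        sel = (lab_of >= lab_lo) & (lab_of <= lab_hi)
        return int(j_idx[sel].min()), int(j_idx[sel].max()) + 1

    top = int(labels.min())
    bottom = int(labels.max())
    upper_lo, upper_hi = j_range(top, min(split_label + overlap_bodies - 1, bottom))
    lower_lo, lower_hi = j_range(max(split_label - overlap_bodies, top), bottom)
    # NOTE: array j increases toward superior, so the "upper spine" crop is
    # the high-j range.
    upper = (_crop_j(volume, upper_lo - 1 if upper_lo else 0, volume.shape[1]),
             _crop_j(mask, upper_lo - 1 if upper_lo else 0, volume.shape[1]))
    lower = (_crop_j(volume, 0, lower_hi + 1), _crop_j(mask, 0, lower_hi + 1))
    return upper, lower
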