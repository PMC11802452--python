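"""Synthetic astrocyte-engulfment stacks with per-punctum ground truth.

An astrocyte arbor is modeled as a connected union of capsules (tube
segments) rasterized at the anisotropic confocal voxel size (default
0.12 x 0.045 x 0.045 um).  Synaptic puncta are spheres planted in one of
three classes: *inside* the arbor (all voxels within the tube, fraction 1),
*straddling* its surface (fraction strictly between 0 and 1) or *outside*
(fraction 0).  Planted radii span volumes below, inside and above the
0.01-1 um^3 bouton window so the volume filter can be checked against ground
truth.  Distractor blobs below the 10 um^3 astro volume threshold exercise
the astro-mask cleanup.  Ground truth (rasterized volume, engulfment
fraction, class) is computed from the rendered masks before any noise is
added, and emitted alongside the intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..engulfment import LABEL_ASTRO, LABEL_PUNCTA, VoxelStack

__all__ = [
    "PunctumPlan",
    "PunctumTruth",
    "EngulfmentSceneSpec",
    "EngulfmentScene",
    "generate_engulfment_stack",
    "random_engulfment_spec",
]

_CLASSES = ("inside", "straddling", "outside")


@dataclass(frozen=True)
class PunctumPlan:
    """A planted punctum: center and radius in um, plus its planted class."""

    center_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    klass: str

    def __post_init__(self):
        if self.klass not in _CLASSES:
            raise ValueError(f"class must be one of {_CLASSES}")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PunctumTruth:
    """Ground truth for one planted punctum (from the rendered masks)."""

    plan: PunctumPlan
    voxel_count: int
    volume_um3: float
    engulfment_fraction: float

    @property
    def in_volume_window(self) -> bool:
        return 0.01 <= self.volume_um3 <= 1.0


@dataclass(frozen=True)
class EngulfmentSceneSpec:
    """Generative description of a two-channel engulfment stack."""

    stack_shape: tuple[int, int, int] = (48, 160, 160)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.12, 0.045, 0.045)
    arbor_segments: tuple = ()  # ((z,y,x) start um, (z,y,x) end um, radius um)
    puncta_plan: tuple[PunctumPlan, ...] = ()
    distractors: tuple = ()  # ((z,y,x) center um, radius um)
    astro_level: float = 200.0
    puncta_level: float = 200.0
    snr: float | None = None  # signal/noise-SD; None renders noiselessly
    seed: int = 0

    def __post_init__(self):
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(self.arbor_segments) == 0:
            raise ValueError("the arbor needs at least one tube segment")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")


@dataclass(frozen=True)
class EngulfmentScene:
    """Rendered stack, ground-truth masks/labels and per-punctum truth."""

    stack: VoxelStack
    arbor_mask: np.ndarray
    labels: np.ndarray  # ground-truth label volume (puncta precedence)
    truth: tuple[PunctumTruth, ...]
    spec: EngulfmentSceneSpec


def _grids(shape, voxel_size):
    z = np.arange(shape[0])[:, None, None] * voxel_size[0]
    y = np.arange(shape[1])[None, :, None] * voxel_size[1]
    x = np.arange(shape[2])[None, None, :] * voxel_size[2]
    return z, y, x


def _capsule_mask(shape, voxel_size, a, b, radius):
    z, y, x = _grids(shape, voxel_size)
    a = np.asarray(a, float)
    v = np.asarray(b, float) - a
    vv = float(v @ v)
    dz, dy, dx = z - a[0], y - a[1], x - a[2]
    if vv == 0:
        d2 = dz**2 + dy**2 + dx**2
    else:
        t = np.clip((dz * v[0] + dy * v[1] + dx * v[2]) / vv, 0.0, 1.0)
        d2 = (dz - t * v[0]) ** 2 + (dy - t * v[1]) ** 2 + (dx - t * v[2]) ** 2
    return d2 <= radius * radius


def _sphere_coords(shape, voxel_size, center, radius):
    lo = [max(0, int((c - radius) / v) - 1) for c, v in zip(center, voxel_size)]
    hi = [
        min(s, int((c + radius) / v) + 2)
        for s, c, v in zip(shape, center, voxel_size)
    ]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    z = (np.arange(lo[0], hi[0])[:, None, None]) * voxel_size[0]
    y = (np.arange(lo[1], hi[1])[None, :, None]) * voxel_size[1]
    x = (np.arange(lo[2], hi[2])[None, None, :]) * voxel_size[2]
    inside = (
        (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
        <= radius * radius
    )
    local = np.argwhere(inside)
    return local + np.array([s.start for s in sl])


def generate_engulfment_stack(spec: EngulfmentSceneSpec) -> EngulfmentScene:
    """Render the scene and derive exact voxel-level ground truth.

    The engulfment fraction of each punctum is the fraction of its rasterized
    voxels lying inside the rendered arbor mask; planted classes are verified
    against it (an "inside" punctum must reach fraction 1, an "outside" one
    fraction 0) and a violation raises, so emitted truth is always
    consistent.  Intensities are channel level times mask plus Gaussian noise
    of SD level/snr, clipped at zero.
    """
    shape, vs = spec.stack_shape, spec.voxel_size

    arbor = np.zeros(shape, dtype=bool)
    for a, b, r in spec.arbor_segments:
        arbor |= _capsule_mask(shape, vs, a, b, r)

    astro_extra = np.zeros(shape, dtype=bool)
    for center, r in spec.distractors:
        coords = _sphere_coords(shape, vs, center, r)
        astro_extra[tuple(coords.T)] = True
    if (astro_extra & arbor).any():
        raise ValueError("a distractor blob touches the arbor; adjust the plan")

    puncta_mask = np.zeros(shape, dtype=bool)
    truths = []
    for plan in spec.puncta_plan:
        if any(plan.radius_um < v for v in vs):
            warnings.warn(
                f"punctum radius {plan.radius_um} um is below the voxel size in "
                "at least one axis; rendering anyway", stacklevel=2,
            )
        coords = _sphere_coords(shape, vs, plan.center_um, plan.radius_um)
        if len(coords) == 0:
            # sub-voxel punctum: keep at least its center voxel
            center_idx = [
                min(s - 1, max(0, int(round(c / v))))
                for s, c, v in zip(shape, plan.center_um, vs)
            ]
            coords = np.array([center_idx])
        if puncta_mask[tuple(coords.T)].any():
            raise ValueError("planted puncta overlap; adjust the plan")
        puncta_mask[tuple(coords.T)] = True
        frac = float(arbor[tuple(coords.T)].mean())
        if plan.klass == "inside" and frac < 1.0:
            raise ValueError(
                f"'inside' punctum at {plan.center_um} has voxels outside the "
                f"arbor (fraction {frac:.3f}); adjust the plan"
            )
        if plan.klass == "outside" and frac > 0.0:
            raise ValueError(
                f"'outside' punctum at {plan.center_um} intersects the arbor; "
                "adjust the plan"
            )
        if plan.klass == "straddling" and not (0.0 < frac < 1.0):
            raise ValueError(
                f"'straddling' punctum at {plan.center_um} has fraction {frac}; "
                "adjust the plan"
            )
        truths.append(
            PunctumTruth(
                plan=plan,
                voxel_count=len(coords),
                volume_um3=len(coords) * float(np.prod(vs)),
                engulfment_fraction=frac,
            )
        )

    labels = np.zeros(shape, dtype=np.uint8)
    labels[arbor | astro_extra] = LABEL_ASTRO
    labels[puncta_mask] = LABEL_PUNCTA

    astro_int = spec.astro_level * (arbor | astro_extra).astype(float)
    puncta_int = spec.puncta_level * puncta_mask.astype(float)
    if spec.snr is not None:
        rng = np.random.default_rng(spec.seed)
        astro_int = astro_int + rng.normal(0, spec.astro_level / spec.snr, shape)
        puncta_int = puncta_int + rng.normal(0, spec.puncta_level / spec.snr, shape)
        astro_int = np.clip(astro_int, 0, None)
        puncta_int = np.clip(puncta_int, 0, None)

    stack = VoxelStack(astro_int.astype(np.float32), puncta_int.astype(np.float32), vs)
    return EngulfmentScene(
        stack=stack, arbor_mask=arbor, labels=labels, truth=tuple(truths), spec=spec
    )


def random_engulfment_spec(
    seed: int,
    stack_shape: tuple[int, int, int] = (48, 160, 160),
    n_inside: int = 3,
    n_straddling: int = 2,
    n_outside: int = 3,
    n_below_window: int = 1,
    n_above_window: int = 1,
    snr: float | None = None,
) -> EngulfmentSceneSpec:
    """Draw a valid random scene on the standard layout.

    A main tube (radius 1.3 um) runs along x through the stack with a thinner
    branch toward +y; inside puncta sit on the main axis, straddling puncta
    on its +y surface, and all out-of-arbor objects (outside puncta,
    below/above-window puncta, a distractor blob) occupy the -y half, with
    spacings that keep every component separate after rasterization.
    """
    rng = np.random.default_rng(seed)
    vs = (0.12, 0.045, 0.045)
    ext = tuple(s * v for s, v in zip(stack_shape, vs))  # physical extent
    if ext[0] < 4.5 or ext[1] < 6.4 or ext[2] < 6.4:
        raise ValueError(
            "the standard layout needs a physical extent of at least "
            f"(4.5, 6.4, 6.4) um; got {tuple(round(e, 2) for e in ext)}"
        )
    z_mid, y_mid = ext[0] / 2.0, ext[1] / 2.0
    tube_r = 1.3

    segments = (
        ((z_mid, y_mid, 0.7), (z_mid, y_mid, ext[2] - 0.7), tube_r),
        ((z_mid, y_mid, 2.0), (min(z_mid + 1.2, ext[0] - 1.0), min(y_mid + 1.6, ext[1] - 1.0), 3.2), 0.7),
    )

    plan: list[PunctumPlan] = []
    axis_slots = [1.1 + 1.0 * k for k in range(6) if 1.1 + 1.0 * k < ext[2] - 1.0]
    rng.shuffle(axis_slots)
    for x in axis_slots[:n_inside]:
        r = float(rng.uniform(0.18, 0.38))
        plan.append(PunctumPlan((z_mid, y_mid, x), r, "inside"))

    stradd_slots = [4.2 + 0.9 * k for k in range(3)]
    rng.shuffle(stradd_slots)
    for x in stradd_slots[:n_straddling]:
        r = float(rng.uniform(0.18, 0.4))
        plan.append(PunctumPlan((z_mid, y_mid + tube_r, x), r, "straddling"))

    out_y = max(0.85, y_mid - 2.7)
    out_slots = [0.8 + 1.25 * k for k in range(5)]
    rng.shuffle(out_slots)
    need = n_outside + n_below_window + n_above_window
    if need > len(out_slots):
        raise ValueError("too many out-of-arbor puncta for the layout")
    kinds = (["outside_ok"] * n_outside + ["below"] * n_below_window
             + ["above"] * n_above_window)
    for x, kind in zip(out_slots, kinds):
        if kind == "outside_ok":
            r = float(rng.uniform(0.18, 0.38))
        elif kind == "below":
            r = float(rng.uniform(0.08, 0.1))  # ~0.002-0.004 um^3
        else:
            r = 0.7  # ~1.4 um^3, above the window
        plan.append(PunctumPlan((z_mid, out_y, x), r, "outside"))

    distractors = (((max(0.9, z_mid - 2.0), max(1.5, y_mid - 2.1), ext[2] - 1.4), 1.0),)

    return EngulfmentSceneSpec(
        stack_shape=stack_shape,
        voxel_size=vs,
        arbor_segments=segments,
        puncta_plan=tuple(plan),
        distractors=distractors,
        snr=snr,
        seed=seed,
    )
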