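"""Synthetic neuron trees with analytic Sholl ground truth.

Trees are grown outward from the soma from a recursive branch plan.  Every
segment direction is constrained to make an angle of less than 90 degrees
with the outward radial direction at its start point, which guarantees that
Euclidean distance from the soma increases monotonically along every segment.
Under that constraint a segment crosses the sphere of radius r exactly once
when its endpoint distances straddle r, so shell-crossing counts are exact
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..morphometry import NeuronTree, ShollProfile

__all__ = ["BranchPlan", "TreeSpec", "TreeSample", "generate_neuron_tree", "random_tree_spec"]


@dataclass(frozen=True)
class BranchPlan:
    """One straight dendritic segment and its children.

    For trunk segments (attached to the soma) ``tilt_deg`` and ``azimuth_deg``
    are spherical angles of the absolute direction (tilt = polar angle from
    +z).  For deeper segments, ``tilt_deg`` is the angle away from the local
    outward radial direction (must be < 90 so distance from the soma grows
    monotonically) and ``azimuth_deg`` selects the rotation plane.
    """

    length: float
    tilt_deg: float = 0.0
    azimuth_deg: float = 0.0
    children: tuple["BranchPlan", ...] = ()

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if not (0.0 <= self.tilt_deg < 90.0) and self.children is not None:
            # trunk tilt may span [0, 180); deeper tilts are validated at build
            if not (0.0 <= self.tilt_deg < 180.0):
                raise ValueError("tilt_deg out of range")


@dataclass(frozen=True)
class TreeSpec:
    """Recursive description of a synthetic neuron."""

    trunks: tuple[BranchPlan, ...]
    soma_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    soma_radius: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if len(self.trunks) == 0:
            raise ValueError("a tree needs at least one trunk (disconnected plan)")


@dataclass(frozen=True)
class TreeSample:
    """A rendered tree plus its analytic shell-crossing ground truth."""

    tree: NeuronTree
    shell_step: float
    truth: ShollProfile


def _unit_from_spherical(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    t, a = math.radians(tilt_deg), math.radians(azimuth_deg)
    return np.array(
        [math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), math.cos(t)]
    )


def _tilted_direction(p0: np.ndarray, tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Direction at ``tilt_deg`` from the outward radial direction at p0."""
    if tilt_deg >= 90.0:
        raise ValueError("non-trunk tilt must be < 90 degrees for radial growth")
    r_hat = p0 / np.linalg.norm(p0)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(float(r_hat @ helper)) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(r_hat, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(r_hat, e1)
    t, a = math.radians(tilt_deg), math.radians(azimuth_deg)
    return math.cos(t) * r_hat + math.sin(t) * (math.cos(a) * e1 + math.sin(a) * e2)


def generate_neuron_tree(spec: TreeSpec, shell_step: float = 20.0) -> TreeSample:
    """Render a branch plan as a tree and derive analytic Sholl counts.

    The ground truth counts, for each shell radius, the segments whose start
    distance is < r and whose end distance is >= r (half-open convention
    matching the crossing counter in :mod:`neuroquant.morphometry`).
    """
    soma = np.asarray(spec.soma_position, dtype=float)
    positions = [soma]
    parents = [-1]
    radii = [spec.soma_radius]
    types = [1]
    segments: list[tuple[float, float]] = []  # (start, end) distances from soma

    def grow(plan: BranchPlan, parent_idx: int, is_trunk: bool):
        p0 = positions[parent_idx]
        rel0 = p0 - soma
        if is_trunk:
            direction = _unit_from_spherical(plan.tilt_deg, plan.azimuth_deg)
        else:
            direction = _tilted_direction(rel0, plan.tilt_deg, plan.azimuth_deg)
        p1 = p0 + plan.length * direction
        d0 = float(np.linalg.norm(rel0))
        d1 = float(np.linalg.norm(p1 - soma))
        if d1 <= d0:
            raise ValueError("branch plan does not grow outward")
        positions.append(p1)
        parents.append(parent_idx)
        radii.append(0.5)
        types.append(3)
        segments.append((d0, d1))
        idx = len(positions) - 1
        for ch in plan.children:
            grow(ch, idx, is_trunk=False)

    for trunk in spec.trunks:
        grow(trunk, 0, is_trunk=True)

    tree = NeuronTree(
        np.asarray(positions), np.asarray(parents), np.asarray(radii), np.asarray(types)
    )
    dmax = max(d1 for _, d1 in segments)
    n_shells = max(1, int(math.floor(dmax / shell_step + 1e-9)))
    shell_radii = shell_step * np.arange(1, n_shells + 1)
    counts = np.array(
        [sum(1 for d0, d1 in segments if d0 < r <= d1 + 1e-12) for r in shell_radii],
        dtype=int,
    )
    return TreeSample(tree=tree, shell_step=shell_step, truth=ShollProfile(shell_radii, counts))


def random_tree_spec(
    seed: int,
    n_trunks: tuple[int, int] = (2, 4),
    depth: int = 4,
    branch_prob: float = 0.6,
    length_range: tuple[float, float] = (15.0, 60.0),
    tilt_max: float = 55.0,
) -> TreeSpec:
    """Draw a random, valid branch plan (radial growth guaranteed)."""
    rng = np.random.default_rng(seed)

    def make(level: int, is_trunk: bool) -> BranchPlan:
        length = float(rng.uniform(*length_range))
        tilt = float(rng.uniform(0.0, 179.0 if is_trunk else tilt_max))
        azimuth = float(rng.uniform(0.0, 360.0))
        children: tuple[BranchPlan, ...] = ()
        if level < depth and rng.random() < branch_prob:
            children = tuple(make(level + 1, False) for _ in range(2))
        return BranchPlan(length, tilt, azimuth, children)

    k = int(rng.integers(n_trunks[0], n_trunks[1] + 1))
    trunks = tuple(make(1, True) for _ in range(k))
    return TreeSpec(trunks=trunks, seed=seed)
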