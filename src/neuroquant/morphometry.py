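"""Neuronal morphometry: Sholl analysis, path order, spine density.

Operates on reconstructed neurons (SWC-style rooted trees with 3D positions
in micrometres).  Sholl intersections are counted against concentric spheres
around the soma at a fixed radial increment (20 um by default); distances are
full 3D Euclidean by default with an optional 2D-projection mode.  Path-order
summaries classify dendritic paths as primary, secondary or tertiary, folding
deeper orders into tertiary.  Spine density is count-per-length arithmetic
with the replicate-aggregation convention used throughout: segments average
to cells, cells average to animals (the biological replication unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTree",
    "ShollProfile",
    "PathOrderSummary",
    "SpineDensityTables",
    "sholl",
    "path_order",
    "spine_density",
    "refine_edges",
    "DEFAULT_COMPARTMENTS",
]

# SWC structure-type codes -> compartment tags (configurable per call)
DEFAULT_COMPARTMENTS = {
    1: "soma",
    3: "basal",
    4: "apical-oblique",
    5: "apical-tuft",
}


@dataclass(frozen=True)
class NeuronTree:
    """A rooted neuron reconstruction.

    ``parents`` holds, for each node, the index of its parent in the arrays
    (-1 for the root).  Exactly one root is allowed, the structure must be
    acyclic, and every parent must precede its children (standard SWC order).
    Positions and radii are in micrometres.
    """

    positions: np.ndarray  # (n, 3) xyz um
    parents: np.ndarray  # (n,) int, -1 for root
    radii: np.ndarray  # (n,) um
    types: np.ndarray  # (n,) SWC type codes

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        par = np.asarray(self.parents, dtype=int)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "parents", par)
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "types", np.asarray(self.types, dtype=int))
        n = len(pos)
        if pos.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        roots = np.flatnonzero(par < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if np.any(par >= np.arange(n)):
            raise ValueError("every parent must precede its children")

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parents < 0)[0])

    @property
    def soma_position(self) -> np.ndarray:
        return self.positions[self.root]

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    def edges(self) -> np.ndarray:
        """Indices of child nodes (each defines the edge parent->child)."""
        return np.flatnonzero(self.parents >= 0)

    def edge_lengths(self) -> np.ndarray:
        child = self.edges()
        d = self.positions[child] - self.positions[self.parents[child]]
        return np.linalg.norm(d, axis=1)

    def total_cable_length(self) -> float:
        return float(self.edge_lengths().sum())

    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parents[self.parents >= 0], 1)
        return counts


@dataclass(frozen=True)
class ShollProfile:
    """Intersection counts on concentric shells around the soma."""

    shell_radii: np.ndarray  # um, strictly increasing
    intersections: np.ndarray  # counts, same length

    def __post_init__(self):
        r = np.asarray(self.shell_radii, dtype=float)
        c = np.asarray(self.intersections, dtype=int)
        object.__setattr__(self, "shell_radii", r)
        object.__setattr__(self, "intersections", c)
        if len(r) != len(c):
            raise ValueError("radii and counts must have equal length")
        if len(r) and np.any(np.diff(r) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("intersection counts must be non-negative")


def sholl(
    tree: NeuronTree,
    step: float = 20.0,
    max_radius: float | None = None,
    projection: str | None = None,
) -> ShollProfile:
    """Count dendritic intersections with spheres every ``step`` um.

    Each tree edge is treated as a straight segment; an edge crossing a shell
    contributes one intersection per crossing, and a tangential graze counts
    once.  Crossings exactly at a node are attributed to the incoming edge
    (roots of the crossing equation are counted on the half-open parameter
    interval (0, 1]), so refining an edge into collinear sub-edges does not
    change any count.

    With ``projection="xy"`` (or ``"xz"``/``"yz"``) distances are measured in
    the projected plane, mirroring 2D Sholl on maximum-intensity projections.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    soma = tree.soma_position
    pos = tree.positions - soma
    if projection is not None:
        keep = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}.get(projection)
        if keep is None:
            raise ValueError(f"unknown projection {projection!r}")
        pos = pos[:, keep]

    child = tree.edges()
    a = pos[tree.parents[child]]
    b = pos[child]
    if max_radius is None:
        if len(child) == 0:
            raise ValueError("tree has no edges")
        dmax = float(np.linalg.norm(b, axis=1).max())
        max_radius = step * max(1, int(np.floor(dmax / step + 1e-9)))
    if max_radius < step:
        raise ValueError("max_radius must be at least one step")

    radii = np.arange(step, max_radius + step / 2, step)

    v = b - a
    A = np.einsum("ij,ij->i", v, v)
    B = 2.0 * np.einsum("ij,ij->i", a, v)
    C0 = np.einsum("ij,ij->i", a, a)
    ok = A > 0  # ignore zero-length edges

    counts = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        C = C0 - r * r
        disc = B * B - 4.0 * A * C
        tol = 1e-9 * np.maximum(1.0, B * B)
        n = np.zeros(len(A), dtype=int)
        # tangential graze: single (double) root
        tangent = ok & (np.abs(disc) <= tol)
        t0 = np.where(A > 0, -B / (2.0 * np.maximum(A, 1e-300)), np.nan)
        n += (tangent & (t0 > 1e-12) & (t0 <= 1.0 + 1e-12)).astype(int)
        # two distinct roots
        cross = ok & (disc > tol)
        sq = np.sqrt(np.where(cross, disc, 0.0))
        for sign in (-1.0, 1.0):
            t = np.where(cross, (-B + sign * sq) / (2.0 * np.maximum(A, 1e-300)), np.nan)
            n += (cross & (t > 1e-12) & (t <= 1.0 + 1e-12)).astype(int)
        counts[k] = int(n.sum())
    return ShollProfile(radii, counts)


_ORDER_LABELS = ("primary", "secondary", "tertiary")


@dataclass(frozen=True)
class PathOrderSummary:
    """Counts and total cable length per branch-order class.

    Orders above 3 are folded into tertiary, so ``lengths`` always sums to the
    total cable length of the tree.
    """

    counts: dict = field(default_factory=dict)
    lengths: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths.values()))


def path_order(tree: NeuronTree) -> PathOrderSummary:
    """Classify dendritic paths from the soma as primary/secondary/tertiary.

    A new path starts at the soma (primary) or at any branch point, where the
    order increments.  Orders deeper than tertiary accrue, in both count and
    length, to the tertiary class.
    """
    root = tree.root
    n_children = tree.n_children()
    child = tree.edges()
    lengths = tree.edge_lengths()

    order = np.zeros(tree.n_nodes, dtype=int)
    starts_path = np.zeros(tree.n_nodes, dtype=bool)
    for i, c in enumerate(child):  # parents precede children: single pass works
        p = tree.parents[c]
        if p == root:
            order[c] = 1
            starts_path[c] = True
        elif n_children[p] >= 2:
            order[c] = order[p] + 1
            starts_path[c] = True
        else:
            order[c] = order[p]

    counts = dict.fromkeys(_ORDER_LABELS, 0)
    sums = dict.fromkeys(_ORDER_LABELS, 0.0)
    fold = lambda o: _ORDER_LABELS[min(o, 3) - 1]
    for i, c in enumerate(child):
        label = fold(order[c])
        sums[label] += float(lengths[i])
        if starts_path[c]:
            counts[label] += 1
    return PathOrderSummary(counts=counts, lengths=sums)


@dataclass(frozen=True)
class SpineDensityTables:
    """Spine densities at the three aggregation levels of the design."""

    per_segment: pd.DataFrame
    per_cell: pd.DataFrame
    per_animal: pd.DataFrame


def spine_density(records: pd.DataFrame) -> SpineDensityTables:
    """Protrusions-per-um densities with animal-level aggregation.

    ``records`` needs columns ``count`` and ``length`` (um) plus ``cell`` and
    ``animal``; ``group`` and ``compartment`` columns, when present, are kept
    as grouping keys.  Technical replicates collapse upward: segment densities
    average to a cell value, cell values to an animal value.
    """
    required = {"count", "length", "cell", "animal"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["length"] <= 0).any():
        raise ValueError("all segment lengths must be positive")

    keys = [c for c in ("group", "compartment") if c in records.columns]
    seg = records.copy()
    seg["density"] = seg["count"] / seg["length"]
    per_cell = (
        seg.groupby(keys + ["animal", "cell"], sort=True)["density"]
        .mean()
        .reset_index()
    )
    per_animal = (
        per_cell.groupby(keys + ["animal"], sort=True)["density"].mean().reset_index()
    )
    return SpineDensityTables(seg, per_cell, per_animal)


def refine_edges(tree: NeuronTree, n_sub: int) -> NeuronTree:
    """Split every edge into ``n_sub`` collinear sub-edges (geometry preserved)."""
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    positions = [tree.positions[tree.root]]
    radii = [tree.radii[tree.root]]
    types = [tree.types[tree.root]]
    parents = [-1]
    new_index = {tree.root: 0}
    for c in tree.edges():
        p = tree.parents[c]
        a, b = tree.positions[p], tree.positions[c]
        prev = new_index[p]
        for k in range(1, n_sub + 1):
            t = k / n_sub
            positions.append(a + t * (b - a))
            radii.append(tree.radii[c])
            types.append(tree.types[c])
            parents.append(prev)
            prev = len(parents) - 1
        new_index[c] = prev
    return NeuronTree(
        np.asarray(positions), np.asarray(parents), np.asarray(radii), np.asarray(types)
    )
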