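"""k-d tree over atom centers for candidate-atom retrieval.

The tree is built by recursive median splitting, cycling the split axis
x -> y -> z with depth.  Queries return every atom whose sphere, inflated by
a caller-supplied ``extra`` margin, could contain the query point; pruning
uses the global maximum atom radius, so the result may contain false
positives but never misses an atom (callers re-check exact distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Atom
from .errors import VoxVolError

__all__ = ["AtomTree", "build_tree", "atoms_near"]


@dataclass
class _Node:
    index: int  # index into the tree's atom arrays
    axis: int
    left: "_Node | None"
    right: "_Node | None"


@dataclass
class AtomTree:
    """Binary k-d tree over atom centers.

    ``positions``/``radii`` are parallel arrays in original atom order;
    nodes store indices into them.
    """

    atoms: list[Atom]
    positions: np.ndarray
    radii: np.ndarray
    root: _Node
    r_max: float

    @property
    def n(self) -> int:
        return len(self.atoms)


def build_tree(atoms: list[Atom]) -> AtomTree:
    """Construct the tree by recursive median splits (median index
    ``floor((len-1)/2)`` of the axis-sorted list; coordinate ties broken by
    original atom index for determinism)."""
    if not atoms:
        raise VoxVolError("cannot build an atom tree from an empty atom list")
    positions = np.array([a.position for a in atoms], dtype=float)
    radii = np.array(
        [a.radius if a.radius is not None else 0.0 for a in atoms], dtype=float
    )

    def build(indices: list[int], depth: int) -> _Node | None:
        if not indices:
            return None
        axis = depth % 3
        indices = sorted(indices, key=lambda i: (positions[i, axis], i))
        mid = (len(indices) - 1) // 2
        return _Node(
            index=indices[mid],
            axis=axis,
            left=build(indices[:mid], depth + 1),
            right=build(indices[mid + 1:], depth + 1),
        )

    root = build(list(range(len(atoms))), 0)
    assert root is not None
    return AtomTree(atoms=list(atoms), positions=positions, radii=radii,
                    root=root, r_max=float(radii.max()))


def atoms_near(tree: AtomTree, point, extra: float = 0.0) -> list[int]:
    """Indices of atoms with ``|point - center| < radius + extra``.

    Branches are pruned when the axis distance to the splitting plane
    exceeds ``r_max + extra``; the exact 3D distance is re-checked for every
    reported atom, so the result is exact (no false positives survive).
    """
    if extra < 0:
        raise VoxVolError("extra must be non-negative")
    p = np.asarray(point, dtype=float)
    threshold = tree.r_max + extra
    out: list[int] = []

    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node is None:
            continue
        pos = tree.positions[node.index]
        d2 = float(((p - pos) ** 2).sum())
        limit = tree.radii[node.index] + extra
        if d2 < limit * limit:
            out.append(node.index)
        axis_d = p[node.axis] - pos[node.axis]
        if axis_d > threshold:
            # every left-subtree atom lies even further along this axis
            stack.append(node.right)
        elif axis_d < -threshold:
            stack.append(node.left)
        else:
            stack.append(node.left)
            stack.append(node.right)
    out.sort()
    return out
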