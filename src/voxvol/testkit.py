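"""Synthetic structures and independent geometric oracles.

The fixtures emulate the classes of structures the voxel pipeline is meant
to analyze: single spheres, random non-overlapping sphere fields, a small
linear molecule (acetylene), and toy cages with zero, one or two apertures.
The oracles compute reference volumes and areas for unions of spheres
without any voxelization — Monte-Carlo or closed-form inclusion-exclusion
for volumes, exposed spherical caps for areas — and share no geometry code
with the pipeline beyond the Atom container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemio import Atom, Structure
from .errors import VoxVolError

__all__ = ["FixtureSpec", "make_fixture", "acetylene",
           "oracle_union_volume", "oracle_union_volume_collinear",
           "oracle_union_area", "oracle_point_class"]

#: Acetylene geometry (standard bond lengths, atoms on the z axis) and the
#: vdW radii used throughout: H 1.20 A, C 1.77 A.
CC_BOND = 1.203
CH_BOND = 1.061
H_RADIUS = 1.20
C_RADIUS = 1.77


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic structure."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _fib_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def acetylene() -> Structure:
    """HC#CH on the z axis with resolved radii and weights."""
    zc = CC_BOND / 2
    zh = zc + CH_BOND
    atoms = [
        Atom("H", (0.0, 0.0, -zh), H_RADIUS, 1.008),
        Atom("C", (0.0, 0.0, -zc), C_RADIUS, 12.011),
        Atom("C", (0.0, 0.0, zc), C_RADIUS, 12.011),
        Atom("H", (0.0, 0.0, zh), H_RADIUS, 1.008),
    ]
    return Structure(atoms)


def make_fixture(spec: FixtureSpec) -> Structure:
    """Build a synthetic structure; deterministic for a given seed."""
    k, p = spec.kind, dict(spec.params)
    rng = np.random.default_rng(spec.seed)
    if k == "single_sphere":
        r = p.get("radius", 1.2)
        center = tuple(p.get("center", (0.0, 0.0, 0.0)))
        return Structure([Atom("H", center, r, 1.008)])
    if k == "acetylene":
        return acetylene()
    if k == "scattered_spheres":
        return _scattered(rng, n=p.get("n", 1000), radius=p.get("radius", 1.2),
                          box=p.get("box", 100.0))
    if k == "closed_cage":
        return _shell_cage(R=p.get("shell_radius", 4.0), n=p.get("n", 80),
                           r_atom=p.get("atom_radius", 1.7))
    if k == "open_pocket":
        return _shell_cage(R=p.get("shell_radius", 4.0), n=p.get("n", 120),
                           r_atom=p.get("atom_radius", 1.7),
                           aperture_deg=p.get("aperture_deg", 50.0))
    if k == "open_tube":
        return _tube(R=p.get("tube_radius", 3.5),
                     half_length=p.get("half_length", 4.0),
                     r_atom=p.get("atom_radius", 1.7))
    if k == "fullerene_like":
        return _truncated_icosahedron(R=p.get("shell_radius", 3.55),
                                      r_atom=p.get("atom_radius", C_RADIUS))
    raise VoxVolError(f"unknown fixture kind {spec.kind!r}")


def _scattered(rng, n: int, radius: float, box: float) -> Structure:
    """Non-overlapping spheres: pairwise center distance > 2*radius."""
    from scipy.spatial import cKDTree

    if n * (2 * radius) ** 3 > 0.3 * box ** 3:
        raise VoxVolError("too many spheres for the requested box")
    pos = rng.uniform(0, box, size=(n, 3))
    for _ in range(200):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(2 * radius, output_type="ndarray")
        if pairs.size == 0:
            break
        bad = np.unique(pairs[:, 1])
        pos[bad] = rng.uniform(0, box, size=(bad.size, 3))
    else:
        raise VoxVolError("could not pack the spheres without overlap")
    return Structure([Atom("H", tuple(q), radius, 1.008) for q in pos])


def _shell_cage(R: float, n: int, r_atom: float,
                aperture_deg: float | None = None) -> Structure:
    pts = _fib_sphere(n) * R
    if aperture_deg is not None:
        polar = np.degrees(np.arccos(np.clip(pts[:, 2] / R, -1, 1)))
        pts = pts[polar > aperture_deg]
    return Structure([Atom("C", tuple(q), r_atom, 12.011) for q in pts])


def _tube(R: float, half_length: float, r_atom: float,
          ring_spacing: float = 1.4, n_per_ring: int = 16) -> Structure:
    zs = np.arange(-half_length, half_length + 1e-9, ring_spacing)
    atoms = []
    for i, z in enumerate(zs):
        ang = np.arange(n_per_ring) * 2 * np.pi / n_per_ring
        ang = ang + (i % 2) * np.pi / n_per_ring  # stagger rings
        for a in ang:
            atoms.append(Atom("C", (R * math.cos(a), R * math.sin(a), z),
                              r_atom, 12.011))
    return Structure(atoms)


def _truncated_icosahedron(R: float, r_atom: float) -> Structure:
    """60 vertices of a truncated icosahedron scaled to circumradius R."""
    phi = (1 + 5 ** 0.5) / 2
    base = [(0.0, 1.0, 3 * phi), (1.0, 2 + phi, 2 * phi), (phi, 2.0, 2 * phi + 1)]
    verts = set()
    for (x, y, z) in base:
        # even permutations of each coordinate triple, all sign choices
        for perm in ((x, y, z), (y, z, x), (z, x, y)):
            for sx in (1, -1):
                for sy in (1, -1):
                    for sz in (1, -1):
                        verts.add((round(sx * perm[0], 9), round(sy * perm[1], 9),
                                   round(sz * perm[2], 9)))
    pts = np.array(sorted(verts))
    pts = pts[np.abs(np.linalg.norm(pts, axis=1)
                     - np.linalg.norm(pts, axis=1).max()) < 1e-6]
    pts = pts / np.linalg.norm(pts, axis=1)[:, None] * R
    if len(pts) != 60:
        raise VoxVolError(f"truncated icosahedron construction gave {len(pts)} vertices")
    return Structure([Atom("C", tuple(q), r_atom, 12.011) for q in pts])


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _arrays(atoms, inflate: float):
    pos = np.array([a.position for a in atoms], dtype=float)
    rad = np.array([a.radius for a in atoms], dtype=float) + inflate
    return pos, rad


def _lens_volume(r1: float, r2: float, d: float) -> float:
    """Intersection volume of two spheres (0 if disjoint, min sphere if nested)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r ** 3
    return (math.pi * (r1 + r2 - d) ** 2
            * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d))


def oracle_union_volume(atoms, inflate: float = 0.0, n_samples: int = 1_000_000,
                        seed: int = 0):
    """Volume of the union of (inflated) atom spheres, with standard error.

    Uses exact inclusion-exclusion (sphere volumes minus pairwise lenses)
    whenever no three spheres can overlap mutually; otherwise Monte-Carlo
    over the union's bounding box.  Returns ``(volume, stderr)`` in A^3;
    stderr is 0.0 for the exact path.
    """
    pos, rad = _arrays(atoms, inflate)
    n = len(pos)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    overlap = d < (rad[:, None] + rad[None, :])
    np.fill_diagonal(overlap, False)
    triple_free = True
    for i in range(n):
        nb = np.flatnonzero(overlap[i])
        if any(overlap[j, k] for a, j in enumerate(nb) for k in nb[a + 1:]):
            triple_free = False
            break
    if triple_free:
        total = float((4.0 / 3.0 * np.pi * rad ** 3).sum())
        for i in range(n):
            for j in range(i + 1, n):
                if overlap[i, j]:
                    total -= _lens_volume(rad[i], rad[j], d[i, j])
        return total, 0.0
    rng = np.random.default_rng(seed)
    lo = (pos - rad[:, None]).min(axis=0)
    hi = (pos + rad[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    hits = 0
    chunk = 2_000_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = np.zeros(m, dtype=bool)
        for p, r in zip(pos, rad):
            inside |= ((pts - p) ** 2).sum(axis=1) < r * r
        hits += int(inside.sum())
        done += m
    frac = hits / n_samples
    vol = frac * box
    stderr = box * math.sqrt(max(frac * (1 - frac), 0.0) / n_samples)
    return vol, stderr


def oracle_union_volume_collinear(atoms, inflate: float = 0.0,
                                  n_points: int = 2_000_001) -> float:
    """Exact union volume for spheres whose centers lie on the z axis.

    The union's cross-section at height z is a disk of squared radius
    ``max_i(r_i^2 - (z - z_i)^2)``; the volume is the 1D integral of the
    disk area (composite Simpson on a dense grid).
    """
    pos, rad = _arrays(atoms, inflate)
    if not np.allclose(pos[:, :2], pos[0, :2]):
        raise VoxVolError("collinear oracle requires atoms on a common z axis")
    z0, z1 = (pos[:, 2] - rad).min(), (pos[:, 2] + rad).max()
    z = np.linspace(z0, z1, n_points)
    r2 = (rad ** 2)[None, :] - (z[:, None] - pos[None, :, 2]) ** 2
    disk = np.pi * np.clip(r2.max(axis=1), 0.0, None)
    from scipy.integrate import simpson
    return float(simpson(disk, x=z))


def oracle_union_area(atoms, inflate: float = 0.0,
                      n_theta: int = 2000, n_phi: int = 400) -> float:
    """Exposed surface area of the union of (inflated) spheres.

    Collinear structures (all centers on one z line) use the closed form:
    on sphere i the region buried in sphere j is a z cap bounded by the
    plane z* = (r_i^2 - r_j^2 + z_j^2 - z_i^2) / (2 (z_j - z_i)), so the
    exposed part is a zone of area 2*pi*r_i*(z_hi - z_lo).  General
    geometries fall back to latitude-longitude quadrature of the exposed
    fraction per sphere.
    """
    pos, rad = _arrays(atoms, inflate)
    n = len(pos)
    if np.allclose(pos[:, :2], pos[0, :2]):
        total = 0.0
        for i in range(n):
            zi, ri = pos[i, 2], rad[i]
            lo, hi = zi - ri, zi + ri
            for j in range(n):
                if j == i:
                    continue
                zj, rj = pos[j, 2], rad[j]
                dd = abs(zj - zi)
                if dd >= ri + rj:
                    continue
                if dd <= rj - ri:
                    lo, hi = 0.0, -1.0  # fully buried
                    break
                zstar = (ri * ri - rj * rj + zj * zj - zi * zi) / (2 * (zj - zi))
                if zj > zi:
                    hi = min(hi, zstar)
                else:
                    lo = max(lo, zstar)
            if hi > lo:
                total += 2 * math.pi * ri * (hi - lo)
        return total
    # quadrature fallback
    theta = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
    mu = (np.arange(n_phi) + 0.5) * 2.0 / n_phi - 1.0  # cos(polar), uniform
    ct, st = np.cos(theta), np.sin(theta)
    sphi = np.sqrt(1 - mu ** 2)
    total = 0.0
    for i in range(n):
        dirs = np.stack([
            np.outer(sphi, ct), np.outer(sphi, st),
            np.broadcast_to(mu[:, None], (n_phi, n_theta)),
        ], axis=-1).reshape(-1, 3)
        pts = pos[i] + rad[i] * dirs
        buried = np.zeros(len(pts), dtype=bool)
        for j in range(n):
            if j != i:
                buried |= ((pts - pos[j]) ** 2).sum(axis=1) < rad[j] ** 2
        total += 4 * math.pi * rad[i] ** 2 * (1 - buried.mean())
    return total


def oracle_point_class(atoms, r_small: float, point,
                       r_large: float | None = None) -> str:
    """Grid-free classification of one point against all atoms.

    Returns 'atom' (inside a vdW sphere), 'buffer_small' (within
    r_atom + r_small of some atom), 'buffer_large' (within r_atom +
    r_large; two-probe only), or 'free'.
    """
    p = np.asarray(point, dtype=float)
    pos, rad = _arrays(atoms, 0.0)
    d = np.linalg.norm(pos - p, axis=1)
    if np.any(d < rad):
        return "atom"
    if np.any(d < rad + r_small):
        return "buffer_small"
    if r_large is not None and np.any(d < rad + r_large):
        return "buffer_large"
    return "free"
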