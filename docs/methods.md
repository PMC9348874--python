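# Methods

## Model

voxvol treats a chemical structure as a set of static, impenetrable spheres:
each atom occupies a ball of its van der Waals radius r_atom. A spherical
probe of radius r_probe (approximating a solvent or guest molecule) is
"rolled" over this structure in the Lee–Richards/Connolly sense. Space is
partitioned into cubic voxels of side length g (the grid resolution) and
every voxel — represented by its center point — receives exactly one label:

* **atom**: within r_atom of some atom center;
* **probe core**: at distance ≥ r_atom + r_probe from every atom — the
  probe's center can sit here;
* **probe shell**: reachable by the probe body but not its center;
* **probe-excluded void**: the remaining space between atoms that the probe
  cannot reach at all.

Volumes are voxel tallies times g³: V_vdw (atom), V_void (excluded void),
V_core, V_shell, and the combinations V_mol = V_vdw + V_void,
V_occ = V_core + V_shell, V_acc = V_vdw + V_void + V_shell and
V_mol-isolated = V_mol plus the occupied volume of isolated cavities. The
identities hold exactly by construction. Macroscopic values use
N_A·10⁻²⁴/M cm³ g⁻¹ and N_A·10⁻²⁰/M m² g⁻¹ with M the structure's molar
mass.

Cavities are the connected components of probe-core space (26-connectivity;
face-only connectivity splits cavities with sharp features). Components
touching the grid boundary are the outside; shell voxels inherit the cavity
id of their nearest core voxel, so touching cavities split at the
equidistance surface of their cores and no shell volume is counted twice.

In **two-probe mode** a large probe defines the outside envelope and a
small probe explores the space the large probe cannot occupy. Four passes
run: (i) atom/large-core typing, (ii) large shell, (iii) small-core typing
restricted to the remaining unassigned space, (iv) small shell and excluded
void. Enclosed large-core components (large-probe-sized but sealed) are
returned to the unassigned pool before pass (ii) so the small probe claims
them as cavities. Each cavity is typed by its number of entrances —
Isolated (0), Pocket (1), Tunnel (≥ 2) — counted as the 26-connected
patches of the cavity's voxels that touch the outside space across a face.
The entrance-counting procedure (interface patches) is this package's own
construction; only the intended meaning (number of openings) is inherited.

## Typing algorithms

Pass 1 computes voxel-center-to-atom distances. A k-d tree over atom
centers (median splits, axis cycling x→y→z, median index ⌊(n−1)/2⌋,
coordinate ties broken by input order) retrieves candidate atoms; pruning
uses the global maximum atom radius plus the query margin, and exact
distances are re-checked, so results equal a full scan. An octree
accelerates the pass: blocks of 2^depth voxels per side are classified
wholesale when conservative bounds using the block half-diagonal h allow
(all-inside if d + h < r_atom for some atom; all-core if d − h ≥
r_atom + r_probe for all; all-buffer if inside one inflated sphere and
outside every atom), and subdivide otherwise down to single voxels, which
are zero-dimensional points. The conservative bounds (padded by 10⁻⁹ to
absorb rounding) and shared per-voxel arithmetic make the results
bit-identical for optimization depths 0–6; depth only affects speed.
Grid dims are always rounded up to a multiple of 2⁶ so every depth tiles
the same grid — otherwise the outside volumes would depend on the depth.

Pass 2 classifies each remaining voxel by the distance to its nearest
probe-core voxel, in voxel units, against the search radius
r_search = r_probe/g + δ with δ = √2/4 (in voxel side lengths). The δ term
compensates the half-voxel displacement of discretized boundaries, which
would otherwise produce spurious excluded-void voxels. Production code
uses an exact Euclidean distance transform (scipy) with feature indices,
which accepts exactly the same integer offsets as the sorted
neighbor-table scan (squared offset distance ≤ r_search²) and also yields
the nearest core's cavity id; the literal table scan is retained and
cross-checked in the tests. At exact distance ties between two cores the
attribution follows the transform's deterministic internal order; the
volume split is unaffected.

**Resolution requirement and a known δ limitation.** A probe smaller than
one voxel cannot be represented: the shell band is thinner than the voxel
spacing and neighbor searches cannot see past the first lattice shell.
More generally, δ = √2/4 does not eliminate excluded-void false negatives
for all sub-voxel placements of an atom: for unlucky phases the nearest
admissible core lattice point lies marginally beyond r_search (for
example, at √5 voxel units against r_search = 2.2325), producing a
handful of spurious void voxels. These events are rare (a few percent of
random placements, decaying with r_probe/g), affect single-digit voxel
counts, and vanish for the lattice-aligned configurations typically
tested; δ is kept at √2/4 because every reported void volume depends on
it. The test suite asserts the realistic behavior (rare, small counts) and
the acceptance suite records the idealized zero-void claim as not
attainable under random placement.

## Surface areas

Surface areas use a marching-cube estimator: every 2×2×2 window of voxel
centers — (dims−1)³ windows — maps to an 8-bit corner pattern; the 256
patterns collapse to 14 classes under cube rotations, mirrors and
inside/outside complement; each class carries an area weight in units of
g². Plain voxel-face counting would give a sphere ≈ 6πr² instead of 4πr²;
the weighted windows remove that bias. S_vdw uses inside = {atom}, S_exc
inside = {atom, void}, S_acc inside = {atom, void, shells}, S_mol-open
inside = everything but the outside space. Per-cavity areas sum the
windows containing at least one voxel of the cavity's core∪shell; windows
shared between cavities are split equally (a choice made here; it
conserves the total).

**Weight calibration.** Because voxelization depends only on the ratio
radius/g, the default weights are fitted over that ratio on two kinds of
synthetic observations: single spheres at well-resolved ratios 3–24
(pinning the smooth-surface limit) and fields of thousands of disjoint
spheres at coarse ratios 0.6–2.5 at two packing fractions (pinning the
barely-resolved regime, including window patterns produced by adjacent
features). The fit is nonnegative least squares with every row normalized
by its analytic target (equal relative weight); the all-inside/all-outside
class is pinned to zero and classes with fewer than 2000 observed windows
stay at zero (too rare to fit stably; they do not arise on smooth closed
surfaces). The ratio domain matches the range the estimator is exercised
over in the convergence study (g from 0.05 to 2.0 Å for 1.2 Å spheres).
The fitted constants are frozen in `measure.py`; `calibrate_mc_weights()`
reproduces them and is the documented recalibration path. Typical
accuracy: ≤ 0.3% on well-resolved spheres and sphere unions, a few
percent in aggregate for sub-voxel spheres.

## Grid construction and placement

The grid covers the structure's sphere-inflated bounding box padded by
2·r_probe_outside + 2g per side, so the outside probe core is a connected
region surrounding the structure. The origin is the padded minimum corner.
Voxel (i,j,k) has center origin + ((i,j,k)+0.5)·g. Translating a structure
by exact voxel multiples reproduces identical results. Voxelization error
at a fixed resolution depends on the sub-voxel phase of the structure
relative to the grid: for a small axis-aligned molecule at g = 0.2 Å the
vdW-volume error spans roughly 0.0–0.5% over phases (median ≈ 0.2%).
No phase is canonical, so the package does not try to pick a lucky one;
averaging over randomized orientations would reduce this anisotropy but is
out of scope. A configurable cap (3·10⁸ voxels) guards against accidental
huge grids.

## Synthetic data and oracles

The test kit generates the study structures programmatically: single
spheres; fields of n non-overlapping spheres (pairwise center distance
> 2r) in a cubic box; acetylene on the z axis (C≡C 1.203 Å, C–H 1.061 Å,
radii H 1.20 / C 1.77 Å — standard bond lengths fixed as repository
constants); spherical shell cages (closed, or with a polar aperture that
passes only the small probe); open tubes; and a 60-vertex truncated
icosahedron at circumradius 3.55 Å. Reference values come from
implementation-independent oracles: exact inclusion–exclusion (pairwise
lens subtraction) or Monte-Carlo sampling for union volumes, a 1D
disk-integral for collinear unions, exposed-cap closed forms (collinear)
or latitude–longitude quadrature for union areas, and a grid-free distance
classifier for point labels. What passing these tests does *not* show:
behavior on real macromolecules (thousands of atoms, heterogeneous radii,
PDB quirks beyond ATOM/HETATM/altLoc basics), crystal unit cells (out of
scope), or probe radii below the grid resolution.

## Numerical choices

* Strict inequalities at both typing thresholds (d < r_atom,
  d < r_atom + r_probe); boundary-equal distances fall outward. The
  affected set has measure zero; the choice makes runs deterministic.
* r_probe = 0 skips pass 2 entirely: no shell, no excluded void.
* Shell inclusion compares squared distances with a 10⁻¹² relative
  tolerance so the distance-transform route cannot drop an exact lattice
  tie.
* Volumes print with 2 decimals; areas with 2 decimals; the DX maps encode
  types monotonically (atom=6 … large core=1) so one isovalue per surface
  (5.5 vdW, 4.5 excluded, 2.5 accessible) thresholds cleanly.

## Problem sizes

Default test and acceptance runs use grids of 64³–192³ voxels (acetylene
at g = 0.1–0.2 Å, 1000-sphere fields at g = 2 Å, cages at g = 0.25–0.4 Å),
sizes at which every pipeline stage is exercised, including octree
classification, distance-transform shell assignment and per-cavity surface
attribution. Larger grids change cost, not code paths.

## Known limitations

* Single-orientation results carry grid anisotropy (see placement above).
* Sub-voxel probes and sub-voxel atoms are outside the calibrated domain.
* Cavity types require the outside envelope; structures that fill the grid
  (insufficient padding) degrade to all-Isolated with a warning.
* The marching-cube weights are calibrated for smooth sphere-like
  surfaces; exotic voxel patterns (checkerboards, isolated corners in
  contact) carry zero weight and would undercount pathological inputs.
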