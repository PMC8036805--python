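"""Radical Voronoi (power-diagram) assignment of periodic grid points.

The radical Voronoi tessellation assigns a point x to the site i with the
smallest *power distance* ||x - p_i||^2 - r_i^2. Cell faces are planes; for
two sites A, B at distance R the A-B face sits at

    w = R/2 + (r_A^2 - r_B^2) / (2 R)

from A along the A->B axis. Because only differences of squared radii
enter, the map r_i -> sqrt(r_i^2 + C) (a *gauge shift*) leaves every
assignment unchanged. With all radii equal the construction reduces to
the classical Voronoi tessellation. A site may own no points at all
(degenerate cell); this is permitted and tracked.

The two-step scheme first assigns each grid point to a molecule using the
rMol radius set, then re-assigns it to an atom of that molecule using the
rAtom set. The per-point argmin over periodic images implemented here is
the result contract; any accelerated path must reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import AtomTypeClasses, MoleculeAssignment
from .volumetric import DensityGrid, UnitCell, VolumetricFrame


@dataclass(frozen=True)
class RadiiSet:
    """One radius (pm) per equivalence class; role 'molecular' or 'atomic'."""

    values: np.ndarray
    role: str = "molecular"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("radii must be a 1-d array of finite non-negative values")
        if self.role not in ("molecular", "atomic"):
            raise ValueError(f"unknown radii role {self.role!r}")
        object.__setattr__(self, "values", v)

    def per_atom(self, classes: AtomTypeClasses) -> np.ndarray:
        if len(self.values) != classes.n_classes:
            raise ValueError(
                f"radii set has {len(self.values)} entries for {classes.n_classes} classes"
            )
        return self.values[classes.class_id]


@dataclass(frozen=True)
class SiteSet:
    """Voronoi sites: positions (pm), per-site radii (pm), periodic cell."""

    positions: np.ndarray  # (S, 3)
    radii: np.ndarray  # (S,)
    cell: UnitCell

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        r = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if p.shape[0] != r.shape[0]:
            raise ValueError("positions and radii must have one entry per site")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "radii", r)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def r_squared(self) -> np.ndarray:
        return self.radii**2


@dataclass(frozen=True)
class CellAssignment:
    """Per-grid-point owners on the (possibly refined) lattice."""

    molecule_owner: np.ndarray  # (n1, n2, n3) int
    atom_owner: np.ndarray  # (n1, n2, n3) int
    refinement: int = 1
    degenerate_atoms: frozenset[int] = field(default_factory=frozenset)
    degenerate_molecules: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_points(self) -> int:
        return int(self.atom_owner.size)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _shell_shifts(shell: int) -> np.ndarray:
    rng = np.arange(-shell, shell + 1)
    return np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)


def min_image_sq_distances(points: np.ndarray, sites: np.ndarray, cell: UnitCell,
                           shell: int | None = None) -> np.ndarray:
    """Squared minimum-image distances, shape (n_points, n_sites).

    For orthorhombic cells the rounded fractional image is exact; skewed
    cells are handled by scanning a +/-``shell`` image block around it
    (default 1, i.e. 27 images). A subsample check escalates the shell if
    a larger one would ever win, which only happens for severely skewed
    cells.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    inv = np.linalg.inv(cell.matrix)
    if shell is None:
        if cell.is_orthorhombic:
            shell = 0
        else:
            shell = 1
            if _needs_wider_shell(points, sites, cell, inv, shell):
                shell = 2
    out = np.empty((points.shape[0], sites.shape[0]))
    shifts = _shell_shifts(shell) if shell > 0 else np.zeros((1, 3))
    shift_cart = shifts @ cell.matrix
    for j in range(sites.shape[0]):
        frac = (points - sites[j]) @ inv
        frac -= np.round(frac)
        cart = frac @ cell.matrix
        if shell == 0:
            out[:, j] = np.einsum("ij,ij->i", cart, cart)
        else:
            d2 = np.full(points.shape[0], np.inf)
            for s in shift_cart:
                c = cart + s
                np.minimum(d2, np.einsum("ij,ij->i", c, c), out=d2)
            out[:, j] = d2
    return out


def _needs_wider_shell(points, sites, cell, inv, shell, n_sample=512) -> bool:
    idx = np.linspace(0, points.shape[0] - 1, min(n_sample, points.shape[0])).astype(int)
    a = min_image_sq_distances(points[idx], sites, cell, shell=shell)
    b = min_image_sq_distances(points[idx], sites, cell, shell=shell + 1)
    return not np.array_equal(a, b)


def power_distance(x: np.ndarray, p: np.ndarray, r: float, cell: UnitCell) -> float:
    """min over periodic images of ||x - p||^2 - r^2 (pm^2, may be negative)."""
    d2 = min_image_sq_distances(np.asarray(x, dtype=float)[None, :],
                                np.asarray(p, dtype=float)[None, :], cell)
    return float(d2[0, 0] - float(r) ** 2)


def plane_position(r_a: float, r_b: float, r_ab: float) -> float:
    """Distance w of the A-B separation plane from site A (pm).

    w = R/2 + (r_A^2 - r_B^2)/(2R); w may fall outside [0, R], in which
    case one of the two cells is degenerate in the pair geometry.
    """
    if r_ab <= 0:
        raise ValueError("site separation must be positive")
    return 0.5 * r_ab + (r_a**2 - r_b**2) / (2.0 * r_ab)


def gauge_shift(radii: RadiiSet, c: float) -> RadiiSet:
    """Return the gauge-transformed set r_i' = sqrt(r_i^2 + C).

    Any assignment computed from the shifted set is identical to one
    computed from the original, including tie-breaks, because all power
    distances change by the common constant -C.
    """
    r2 = radii.values**2 + c
    if np.any(r2 < -1e-12):
        raise ValueError(f"gauge constant C={c} would make some r^2 negative")
    return RadiiSet(values=np.sqrt(np.maximum(r2, 0.0)), role=radii.role)


# ---------------------------------------------------------------------------
# Refined lattice geometry
# ---------------------------------------------------------------------------

def refined_shape(grid: DensityGrid, factor: int) -> tuple[int, int, int]:
    n1, n2, n3 = grid.shape
    return (n1 * factor, n2 * factor, n3 * factor)


def refined_offsets(factor: int):
    """Sub-voxel offsets (a, b, c) of the refined lattice, C order."""
    for a in range(factor):
        for b in range(factor):
            for c in range(factor):
                yield (a, b, c)


def refined_positions_block(grid: DensityGrid, offset: tuple[int, int, int],
                            factor: int) -> np.ndarray:
    """Positions of the fine points at sub-voxel ``offset``, C-index order.

    The fine lattice node (i*f+a, j*f+b, k*f+c) sits at
    (i + a/f) v1 + (j + b/f) v2 + (k + c/f) v3.
    """
    base = grid.point_positions()
    shift = (np.asarray(offset, dtype=float) / factor) @ grid.strides
    return base + shift


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_points(points: np.ndarray, site_set: SiteSet) -> np.ndarray:
    """Power-distance argmin owner for each point; ties -> lowest site index."""
    d2 = min_image_sq_distances(points, site_set.positions, site_set.cell)
    return np.argmin(d2 - site_set.r_squared[None, :], axis=1)


def assign_one_step(frame: VolumetricFrame, site_set: SiteSet,
                    refinement: int = 1) -> np.ndarray:
    """Owner site index per (refined) grid point, shape refined_shape."""
    if refinement < 1:
        raise ValueError("refinement factor must be >= 1")
    shape = refined_shape(frame.grid, refinement)
    owners = np.empty(shape, dtype=np.int64)
    for off in refined_offsets(refinement):
        pts = refined_positions_block(frame.grid, off, refinement)
        blk = assign_points(pts, site_set).reshape(frame.grid.shape)
        owners[off[0]::refinement, off[1]::refinement, off[2]::refinement] = blk
    return owners


def assign_two_step(frame: VolumetricFrame, rmol_sites: SiteSet, ratom_sites: SiteSet,
                    molecule_assignment: MoleculeAssignment,
                    refinement: int = 1) -> CellAssignment:
    """Molecule owners from rMol, then atom owners restricted to that molecule.

    The second tessellation uses only the atoms of the owning molecule as
    candidate sites, which is equivalent to tessellating each molecular
    volume separately with the rAtom radii.
    """
    if refinement < 1:
        raise ValueError("refinement factor must be >= 1")
    mol_of_atom = molecule_assignment.molecule_id
    shape = refined_shape(frame.grid, refinement)
    mol_owner = np.empty(shape, dtype=np.int64)
    atom_owner = np.empty(shape, dtype=np.int64)
    for off in refined_offsets(refinement):
        pts = refined_positions_block(frame.grid, off, refinement)
        d2 = min_image_sq_distances(pts, rmol_sites.positions, rmol_sites.cell)
        win_atom = np.argmin(d2 - rmol_sites.r_squared[None, :], axis=1)
        mo = mol_of_atom[win_atom]
        d2a = min_image_sq_distances(pts, ratom_sites.positions, ratom_sites.cell)
        ao = restricted_argmin(d2a - ratom_sites.r_squared[None, :], mo, mol_of_atom)
        sl = (slice(off[0], None, refinement), slice(off[1], None, refinement),
              slice(off[2], None, refinement))
        mol_owner[sl] = mo.reshape(frame.grid.shape)
        atom_owner[sl] = ao.reshape(frame.grid.shape)
    n_atoms = ratom_sites.n_sites
    n_mols = molecule_assignment.n_molecules
    owned_atoms = np.bincount(atom_owner.ravel(), minlength=n_atoms)
    owned_mols = np.bincount(mol_owner.ravel(), minlength=n_mols)
    return CellAssignment(
        molecule_owner=mol_owner,
        atom_owner=atom_owner,
        refinement=refinement,
        degenerate_atoms=frozenset(np.flatnonzero(owned_atoms == 0).tolist()),
        degenerate_molecules=frozenset(np.flatnonzero(owned_mols == 0).tolist()),
    )


def restricted_argmin(power: np.ndarray, mol_owner: np.ndarray,
                      mol_of_atom: np.ndarray) -> np.ndarray:
    """Per-row argmin over the columns whose atom belongs to the row's molecule."""
    out = np.empty(power.shape[0], dtype=np.int64)
    for m in np.unique(mol_owner):
        rows = mol_owner == m
        cols = np.flatnonzero(mol_of_atom == m)
        sub = power[np.ix_(rows, cols)]
        out[rows] = cols[np.argmin(sub, axis=1)]
    return out


def owner_map_frame(frame: VolumetricFrame, owners: np.ndarray) -> VolumetricFrame:
    """Wrap an integer owner map as a frame for CUBE export/visualization.

    The owner index is stored per (refined) lattice node; writing the
    returned frame with ``write_cube(..., unit_convention='raw_counts')``
    emits the integer labels verbatim.
    """
    owners = np.asarray(owners)
    if owners.ndim != 3:
        raise ValueError("owner map must be a 3-d lattice")
    n = np.array(owners.shape, dtype=float)
    strides = frame.cell.matrix / n[:, None]
    vox = float(abs(np.linalg.det(strides)))
    grid = DensityGrid(strides=strides, values=owners.astype(float) / vox)
    return VolumetricFrame(cell=frame.cell, atoms=(), grid=grid,
                           frame_index=frame.frame_index)
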