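"""Synthetic periodic electron densities with known ground truth.

Each atom contributes a normalized spherical Gaussian times its electron
population; the discrete grid sum is renormalized by a single global
factor per frame so the electron count equals the sum of populations
exactly. Frames differ by seeded rigid-body jitter (translation plus
rotation) of whole molecules, so the bond topology stays valid and
frame-to-frame charge fluctuation is the only variance source. These
densities emulate the *structure* of pseudopotential valence densities
from ab initio molecular dynamics — localized blobs, small intermolecular
overlap, strict charge content — not their physics (no bonding density,
no polarization, no basis-set features).

Default widths are 30 pm for hydrogen-like and ~50 pm for heavy atoms,
giving small but nonzero overlap at typical liquid-phase contact
distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .elements import default_core_charge
from .volumetric import AtomRecord, DensityGrid, UnitCell, VolumetricFrame


@dataclass(frozen=True)
class MoleculeTemplate:
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) pm, internal coordinates
    populations: np.ndarray  # e per atom
    widths: np.ndarray  # Gaussian sigma per atom, pm

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        p = np.atleast_1d(np.asarray(self.populations, dtype=float))
        w = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if not (len(self.elements) == c.shape[0] == p.size == w.size):
            raise ValueError("template fields must all have one entry per atom")
        if np.any(p < 0) or np.any(w <= 0):
            raise ValueError("populations must be >= 0 and widths > 0")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "populations", p)
        object.__setattr__(self, "widths", w)


@dataclass(frozen=True)
class SyntheticSpec:
    cell: UnitCell
    templates: tuple[MoleculeTemplate, ...]
    placements: tuple[tuple[int, tuple[float, float, float]], ...]  # (template, center)
    grid_n: tuple[int, int, int]
    n_frames: int = 1
    jitter_pm: float = 0.0
    seed: int = 0
    orientations: tuple | None = None  # per placement: rotation matrix or None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_pm < 0:
            raise ValueError("jitter amplitude must be >= 0")


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _gaussian_density_on_grid(cell: UnitCell, grid_n, positions, populations, widths,
                              origin_shift=None) -> np.ndarray:
    """Sum of periodic spherical Gaussians sampled at the lattice nodes (e/pm^3)."""
    n = np.asarray(grid_n, dtype=int)
    strides = cell.matrix / n[:, None].astype(float)
    idx = np.stack(np.meshgrid(*[np.arange(k) for k in n], indexing="ij"), axis=-1)
    pts = idx.reshape(-1, 3).astype(float) @ strides
    inv = np.linalg.inv(cell.matrix)
    values = np.zeros(pts.shape[0])
    shifts = np.stack(np.meshgrid(*([np.arange(-1, 2)] * 3), indexing="ij"), axis=-1)
    shift_cart = shifts.reshape(-1, 3).astype(float) @ cell.matrix
    for p, pop, sigma in zip(positions, populations, widths):
        if pop == 0.0:
            continue
        norm = pop / ((2.0 * math.pi) ** 1.5 * sigma**3)
        cutoff2 = (8.5 * sigma) ** 2
        frac = (pts - p) @ inv
        frac -= np.round(frac)
        base = frac @ cell.matrix
        for s in shift_cart:
            d = base + s
            d2 = np.einsum("ij,ij->i", d, d)
            mask = d2 < cutoff2
            if mask.any():
                values[mask] += norm * np.exp(-0.5 * d2[mask] / sigma**2)
    return values.reshape(tuple(n))


def build_gaussian_density(spec: SyntheticSpec) -> list[VolumetricFrame]:
    """Render T frames of the spec with seeded rigid-body jitter per molecule.

    The rotation-jitter angle is jitter_pm/100 radians, so one amplitude
    controls both degrees of freedom. The discrete electron count of each
    frame is renormalized to the exact sum of populations.
    """
    rng = np.random.default_rng(spec.seed)
    n = np.asarray(spec.grid_n, dtype=int)
    strides = spec.cell.matrix / n[:, None].astype(float)

    # resolved (static) molecule geometries
    base_positions, elements, pops, widths, mol_sizes = [], [], [], [], []
    for k, (ti, center) in enumerate(spec.placements):
        tpl = spec.templates[ti]
        coords = tpl.coords
        if spec.orientations is not None and spec.orientations[k] is not None:
            coords = coords @ np.asarray(spec.orientations[k]).T
        base_positions.append(coords + np.asarray(center, dtype=float))
        elements.extend(tpl.elements)
        pops.extend(tpl.populations.tolist())
        widths.extend(tpl.widths.tolist())
        mol_sizes.append(len(tpl.elements))
    pops = np.array(pops)
    widths = np.array(widths)
    total_pop = float(pops.sum())
    _warn_on_overlap(spec, base_positions, widths, mol_sizes)

    frames = []
    vox = float(abs(np.linalg.det(strides)))
    for t in range(spec.n_frames):
        positions = []
        for mol in base_positions:
            centroid = mol.mean(axis=0)
            if spec.jitter_pm > 0:
                axis = rng.normal(size=3)
                angle = rng.uniform(-1.0, 1.0) * spec.jitter_pm / 100.0
                rot = _rotation_matrix(axis, angle)
                trans = rng.uniform(-spec.jitter_pm, spec.jitter_pm, size=3)
            else:
                rot = np.eye(3)
                trans = np.zeros(3)
            positions.append((mol - centroid) @ rot.T + centroid + trans)
        positions = spec.cell.wrap(np.vstack(positions))
        values = _gaussian_density_on_grid(spec.cell, n, positions, pops, widths)
        scale = total_pop / (float(values.sum()) * vox)
        grid = DensityGrid(strides=strides, values=values * scale)
        atoms = tuple(
            AtomRecord(index=i, element=e, position=positions[i],
                       core_charge=default_core_charge(e))
            for i, e in enumerate(elements)
        )
        frames.append(VolumetricFrame(cell=spec.cell, atoms=atoms, grid=grid, frame_index=t))
    return frames


def _warn_on_overlap(spec, base_positions, widths, mol_sizes):
    """Warn when distinct molecules overlap beyond their Gaussian cores."""
    centers = [m.mean(axis=0) for m in base_positions]
    extents = []
    start = 0
    for size, mol in zip(mol_sizes, base_positions):
        radius = np.linalg.norm(mol - mol.mean(axis=0), axis=1).max()
        extents.append(radius + 2.0 * widths[start:start + size].max())
        start += size
    inv = np.linalg.inv(spec.cell.matrix)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            frac = (centers[j] - centers[i]) @ inv
            frac -= np.round(frac)
            d = float(np.linalg.norm(frac @ spec.cell.matrix))
            if d < 0.8 * (extents[i] + extents[j]):
                warnings.warn(
                    f"molecules {i} and {j} overlap strongly (separation {d:.0f} pm)",
                    stacklevel=3,
                )
                return


# ---------------------------------------------------------------------------
# Ready-made systems
# ---------------------------------------------------------------------------

def _gaussian_1d(pop: float, sigma: float, d: float) -> float:
    return pop / ((2 * math.pi) ** 1.5 * sigma**3) * math.exp(-0.5 * d * d / sigma**2)


def density_crossing(pop_a: float, pop_b: float, width_a: float, width_b: float,
                     separation: float) -> float:
    """Distance from A at which the two spherical densities are equal.

    Closed-form 1-D root on the A-B axis; this is the plane where an
    ideal partition of the pair density would place the boundary.
    """
    f = lambda x: (_gaussian_1d(pop_a, width_a, x)  # noqa: E731
                   - _gaussian_1d(pop_b, width_b, separation - x))
    xs = np.linspace(1e-6, separation - 1e-6, 4001)
    vals = np.array([f(x) for x in xs])
    sign = np.sign(vals)
    exact = np.flatnonzero(sign == 0)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if crossings.size == 0 and exact.size == 0:
        raise ValueError("densities do not cross between the sites")
    mid = separation / 2.0
    candidates = []
    if exact.size:
        k = exact[np.argmin(np.abs(xs[exact] - mid))]
        candidates.append(float(xs[k]))
    if crossings.size:
        k = crossings[np.argmin(np.abs(xs[crossings] - mid))]
        candidates.append(float(brentq(f, xs[k], xs[k + 1])))
    return min(candidates, key=lambda x: abs(x - mid))


def build_two_site_system(pop_a: float, pop_b: float, width_a: float, width_b: float,
                          separation: float, grid_n: int,
                          cell_length: float | None = None,
                          elements: tuple[str, str] = ("O", "He"),
                          ) -> tuple[VolumetricFrame, float]:
    """Two-atom frame plus the analytic density-equality boundary (from A)."""
    if cell_length is None:
        cell_length = 4.0 * separation
    if not separation < cell_length / 2:
        raise ValueError("separation must be smaller than half the cell")
    cell = UnitCell(np.eye(3) * cell_length)
    mid = cell_length / 2.0
    tpl = MoleculeTemplate(elements=(elements[0],), coords=np.zeros((1, 3)),
                           populations=np.array([pop_a]), widths=np.array([width_a]))
    tpl_b = MoleculeTemplate(elements=(elements[1],), coords=np.zeros((1, 3)),
                             populations=np.array([pop_b]), widths=np.array([width_b]))
    spec = SyntheticSpec(
        cell=cell, templates=(tpl, tpl_b),
        placements=((0, (mid - separation / 2, mid, mid)),
                    (1, (mid + separation / 2, mid, mid))),
        grid_n=(grid_n,) * 3, n_frames=1, jitter_pm=0.0,
    )
    frame = build_gaussian_density(spec)[0]
    w_true = density_crossing(pop_a, pop_b, width_a, width_b, separation)
    return frame, w_true


#: Rigid water geometry: O-H 95.7 pm, H-O-H 104.5 degrees.
WATER_COORDS = np.array([
    [0.0, 0.0, 0.0],
    [95.7 * math.cos(math.radians(52.25)), 95.7 * math.sin(math.radians(52.25)), 0.0],
    [95.7 * math.cos(math.radians(52.25)), -95.7 * math.sin(math.radians(52.25)), 0.0],
])


def water_template(o_population: float = 6.7, o_width: float = 50.0,
                   h_width: float = 30.0) -> MoleculeTemplate:
    """Neutral valence-density water: 8 electrons split o_population / rest."""
    h_pop = (8.0 - o_population) / 2.0
    return MoleculeTemplate(
        elements=("O", "H", "H"), coords=WATER_COORDS,
        populations=np.array([o_population, h_pop, h_pop]),
        widths=np.array([o_width, h_width, h_width]),
    )


def build_water_box(n_molecules: int, grid_n: int = 32, n_frames: int = 4,
                    seed: int = 0, jitter_pm: float = 8.0,
                    cell_length: float | None = None, o_population: float = 6.7,
                    ) -> tuple[list[VolumetricFrame], dict]:
    """Periodic box of rigid water molecules on a jittered sublattice.

    Each molecule holds exactly 8 valence electrons, so every molecular
    charge is 0 by construction; the per-atom ground truth is
    q_O = 6 - o_population and q_H = 1 - (8 - o_population)/2.
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    m = math.ceil(n_molecules ** (1.0 / 3.0))
    while m**3 < n_molecules:
        m += 1
    if cell_length is None:
        cell_length = 500.0 * m
    cell = UnitCell(np.eye(3) * cell_length)
    spacing = cell_length / m
    tpl = water_template(o_population=o_population)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    placements, orientations = [], []
    sites = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    for i, j, k in sites[:n_molecules]:
        center = ((np.array([i, j, k]) + 0.5) * spacing).tolist()
        placements.append((0, tuple(center)))
        orientations.append(_rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * math.pi)))
    spec = SyntheticSpec(
        cell=cell, templates=(tpl,), placements=tuple(placements),
        grid_n=(grid_n,) * 3, n_frames=n_frames, jitter_pm=jitter_pm, seed=seed,
        orientations=tuple(orientations),
    )
    frames = build_gaussian_density(spec)
    h_pop = (8.0 - o_population) / 2.0
    truth = {
        "atom_populations": np.tile([o_population, h_pop, h_pop], n_molecules),
        "atom_charges": np.tile([6.0 - o_population, 1.0 - h_pop, 1.0 - h_pop], n_molecules),
        "molecule_charges": np.zeros(n_molecules),
        "n_atom_classes": 2,
    }
    return frames, truth


def build_alternating_chain(n_pairs: int = 2, spacing: float = 400.0, grid_n: int = 48,
                            n_frames: int = 8, seed: int = 0, jitter_pm: float = 10.0,
                            pop_a: float = 8.0, pop_b: float = 2.0,
                            width_a: float = 50.0, width_b: float = 34.0,
                            elements: tuple[str, str] = ("Ne", "He"),
                            ) -> tuple[list[VolumetricFrame], dict]:
    """Alternating chain of two single-atom species with a known boundary.

    Atoms A, B, A, B, ... sit along x at equal spacing, the chain closing
    on itself across the periodic boundary, so every A-B gap is
    equivalent. The ground-truth molecular boundary is the pair density
    crossing w*, equivalent to the squared-radius difference
    r_A^2 - r_B^2 = 2 R w* - R^2.
    """
    cell_length = 2 * n_pairs * spacing
    cell = UnitCell(np.eye(3) * cell_length)
    mid = cell_length / 2.0
    tpl_a = MoleculeTemplate(elements=(elements[0],), coords=np.zeros((1, 3)),
                             populations=np.array([pop_a]), widths=np.array([width_a]))
    tpl_b = MoleculeTemplate(elements=(elements[1],), coords=np.zeros((1, 3)),
                             populations=np.array([pop_b]), widths=np.array([width_b]))
    placements = []
    for i in range(2 * n_pairs):
        placements.append((i % 2, ((i + 0.5) * spacing, mid, mid)))
    spec = SyntheticSpec(
        cell=cell, templates=(tpl_a, tpl_b), placements=tuple(placements),
        grid_n=(grid_n,) * 3, n_frames=n_frames, jitter_pm=jitter_pm, seed=seed,
    )
    frames = build_gaussian_density(spec)
    w_true = density_crossing(pop_a, pop_b, width_a, width_b, spacing)
    truth = {
        "w_true": w_true,
        "spacing": spacing,
        "delta_r2_true": 2.0 * spacing * w_true - spacing**2,
        "stride_pm": cell_length / grid_n,
    }
    return frames, truth
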