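"""Radius optimization by noise-robust conjugate gradient.

The charge-variance objective is evaluated on a discrete grid, so it is
piecewise constant in the radii and carries discretization noise. The
gradient is therefore estimated per parameter from seven equidistant
objective samples (three on each side of the center, max displacement
0.15 pm by default): a line is fitted to all seven, the sample with the
largest absolute residual is discarded, and the slope refitted on the
remaining six is the gradient component. Directions follow the
Polak-Ribiere nonlinear conjugate gradient

    beta_k = r_{k+1}^T (r_{k+1} - r_k) / (r_k^T r_k)

with a plain downhill (steepest-descent) reset whenever beta < 0. Steps
come from a golden-section bracketing line search; a step that would
increase the objective is rejected and the search repeated with a shrunk
bracket, falling back to a downhill line search once the bracket
underflows, and declaring convergence when even that gains less than the
improvement threshold. Accepted objective values are strictly
non-increasing by construction.

Because the tessellation is invariant under r_i -> sqrt(r_i^2 + C), the
objective has an exactly flat direction; after each accepted step the
radii are re-anchored by such a gauge shift so that the mean of r^2
stays at its initial value, which pins the flat mode without touching
the objective. Radii are floored at 0 by projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .elements import covalent_radius, vdw_radius
from .integration import ChargeTable, RefinedGrid
from .statistics import (
    ChargeStatistics,
    atomic_statistics,
    charge_variance,
    molecular_statistics,
)
from .tessellation import RadiiSet, min_image_sq_distances, restricted_argmin
from .topology import (
    AtomTypeClasses,
    MoleculeAssignment,
    classify_equivalent_atoms,
    detect_bonds,
    find_molecules,
    group_equivalent_molecules,
)
from .volumetric import VolumetricFrame


@dataclass(frozen=True)
class OptimizerConfig:
    max_displacement: float = 0.15  # pm, outermost gradient sample
    samples_per_side: int = 3
    initial_bracket: float = 5.0  # pm, line-search interval
    bracket_shrink_factor: float = 0.5
    min_bracket: float = 0.01  # pm
    improvement_threshold: float = 1e-5  # e
    max_iterations: int = 100
    frames_per_evaluation: int | None = None  # None = all frames

    def __post_init__(self):
        if self.max_displacement <= 0 or self.initial_bracket <= 0 or self.min_bracket <= 0:
            raise ValueError("displacements and brackets must be positive")
        if not 0 < self.bracket_shrink_factor < 1:
            raise ValueError("bracket_shrink_factor must be in (0, 1)")
        if self.samples_per_side < 2:
            raise ValueError("need at least two gradient samples per side")


@dataclass(frozen=True)
class GradientEstimate:
    slopes: np.ndarray  # e/pm per parameter
    samples: tuple  # per parameter: tuple of (displacement pm, objective e)
    dropped: tuple  # per parameter: index of the discarded sample


class ZeroGradientError(RuntimeError):
    """Previous gradient vanished: the optimizer is converged, beta is undefined."""


# ---------------------------------------------------------------------------
# Gradient, beta, line search
# ---------------------------------------------------------------------------

def estimate_gradient(objective_fn: Callable[[np.ndarray], float], x: np.ndarray,
                      config: OptimizerConfig = OptimizerConfig(),
                      f_center: float | None = None) -> GradientEstimate:
    """Outlier-robust finite-difference gradient (7 samples, drop 1, refit)."""
    x = np.asarray(x, dtype=float)
    s = config.samples_per_side
    h = config.max_displacement / s
    disps = np.arange(-s, s + 1) * h
    if f_center is None:
        f_center = float(objective_fn(x))
    slopes = np.empty(x.size)
    all_samples, dropped = [], []
    for i in range(x.size):
        ys = np.empty(disps.size)
        for k, d in enumerate(disps):
            if d == 0.0:
                ys[k] = f_center
            else:
                xi = x.copy()
                xi[i] += d
                ys[k] = float(objective_fn(xi))
            if not np.isfinite(ys[k]):
                raise ValueError(
                    f"objective is non-finite at radius index {i}, displacement {d:+.3f} pm"
                )
        coeff = np.polyfit(disps, ys, 1)
        resid = ys - np.polyval(coeff, disps)
        drop = int(np.argmax(np.abs(resid)))
        keep = np.ones(disps.size, dtype=bool)
        keep[drop] = False
        slopes[i] = np.polyfit(disps[keep], ys[keep], 1)[0]
        all_samples.append(tuple(zip(disps.tolist(), ys.tolist())))
        dropped.append(drop)
    return GradientEstimate(slopes=slopes, samples=tuple(all_samples), dropped=tuple(dropped))


def polak_ribiere_beta(r_k: np.ndarray, r_k1: np.ndarray) -> float:
    """beta = r_{k+1}^T (r_{k+1} - r_k) / (r_k^T r_k)."""
    r_k = np.asarray(r_k, dtype=float)
    r_k1 = np.asarray(r_k1, dtype=float)
    denom = float(r_k @ r_k)
    if denom == 0.0:
        raise ZeroGradientError("previous gradient is zero; treat as converged")
    return float(r_k1 @ (r_k1 - r_k)) / denom


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def golden_section_line_search(objective_fn: Callable[[np.ndarray], float],
                               x: np.ndarray, direction: np.ndarray, bracket: float,
                               min_bracket: float = 0.01) -> tuple[float, float]:
    """Minimize along ``x + s * direction/|direction|`` for s in [0, bracket].

    Shrinks the interval by the golden ratio until its width drops below
    ``min_bracket`` and returns the best *sampled* (step, objective) pair,
    step 0 included — an uphill ray therefore comes back with step 0.
    """
    direction = np.asarray(direction, dtype=float)
    nd = float(np.linalg.norm(direction))
    if nd == 0.0 or bracket <= 0:
        raise ValueError("line search needs a nonzero direction and positive bracket")
    u = direction / nd
    x = np.asarray(x, dtype=float)

    def f(s: float) -> float:
        return float(objective_fn(x + s * u))

    a, b = 0.0, float(bracket)
    samples = [(a, f(a)), (b, f(b))]
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    samples += [(c, fc), (d, fd)]
    while (b - a) > min_bracket:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
            samples.append((c, fc))
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
            samples.append((d, fd))
    best = min(samples, key=lambda t: (t[1], t[0]))
    return best


# ---------------------------------------------------------------------------
# CG driver
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    x: np.ndarray
    objective: float
    history: list[float]  # accepted objective values, non-increasing
    trace: list[dict]
    converged: bool
    n_evaluations: int


def minimize_cg(objective_fn: Callable[[np.ndarray], float], x0: np.ndarray,
                config: OptimizerConfig = OptimizerConfig(),
                postprocess: Callable[[np.ndarray], np.ndarray] | None = None,
                ) -> OptimizationResult:
    """Noise-robust Polak-Ribiere CG with golden-section line search.

    ``postprocess`` is applied to the iterate after each accepted step and
    must be objective-neutral (e.g. a gauge re-anchoring); it is verified
    cheaply by construction, not re-evaluated.
    """
    n_eval = 0

    def f(v: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        val = float(objective_fn(v))
        if not np.isfinite(val):
            raise ValueError(f"objective is non-finite at {v!r}")
        return val

    x = np.asarray(x0, dtype=float).copy()
    if postprocess is not None:
        x = postprocess(x)
    fx = f(x)
    history = [fx]
    trace: list[dict] = []

    g = estimate_gradient(f, x, config, f_center=fx).slopes
    d = -g
    converged = False
    for it in range(config.max_iterations):
        if not np.any(g):
            converged = True
            break
        mode = "cg"
        step, fs = _bracketing_search(f, x, d, config)
        if step is None and np.any(d + g):  # CG direction failed; try pure downhill
            mode = "downhill"
            step, fs = _bracketing_search(f, x, -g, config)
        if step is None:
            converged = True
            break
        if mode == "downhill" and fx - fs <= config.improvement_threshold:
            # even the downhill reset gains less than the threshold: accept
            # the final sub-threshold step and stop
            x = _advance(x, -g, step, postprocess)
            fx = fs
            history.append(fx)
            trace.append({"iteration": it, "objective": fx, "beta": np.nan,
                          "step": step, "mode": "downhill+final"})
            converged = True
            break
        u = (d if mode == "cg" else -g)
        x = _advance(x, u, step, postprocess)
        fx = fs
        history.append(fx)
        g_new = estimate_gradient(f, x, config, f_center=fx).slopes
        try:
            beta = polak_ribiere_beta(-g, -g_new)
        except ZeroGradientError:
            beta = 0.0
        if mode == "downhill" or beta < 0:
            beta_used = 0.0
            d = -g_new
        else:
            beta_used = beta
            d = -g_new + beta * d
        trace.append({"iteration": it, "objective": fx, "beta": beta_used,
                      "step": step, "mode": mode})
        g = g_new
    return OptimizationResult(x=x, objective=fx, history=history, trace=trace,
                              converged=converged, n_evaluations=n_eval)


def _advance(x, direction, step, postprocess):
    u = direction / np.linalg.norm(direction)
    x = x + step * u
    if postprocess is not None:
        x = postprocess(x)
    return x


def _bracketing_search(f, x, direction, config) -> tuple[float | None, float | None]:
    """Line search with rejection: shrink the bracket until a step improves."""
    if not np.any(direction):
        return None, None
    fx = f(x)  # center reference; cached by callers via closure in practice
    bracket = config.initial_bracket
    while bracket >= config.min_bracket:
        step, fs = golden_section_line_search(f, x, direction, bracket,
                                              min_bracket=config.min_bracket)
        if step > 0 and fs < fx:
            return step, fs
        bracket *= config.bracket_shrink_factor
    return None, None


# ---------------------------------------------------------------------------
# Radius parameterization
# ---------------------------------------------------------------------------

def initial_radii(classes: AtomTypeClasses, elements: Sequence[str], role: str) -> RadiiSet:
    """Starting radii: van der Waals per element for the molecular set,
    covalent per element for the atomic set."""
    table = vdw_radius if role == "molecular" else covalent_radius
    if role not in ("molecular", "atomic"):
        raise ValueError(f"unknown radii role {role!r}")
    values = np.empty(classes.n_classes)
    for c, members in enumerate(classes.members):
        values[c] = table(elements[members[0]])
    return RadiiSet(values=values, role=role)


def gauge_anchor(target_mean_r2: float) -> Callable[[np.ndarray], np.ndarray]:
    """Postprocess pinning mean(r^2) via an objective-neutral gauge shift."""

    def anchor(v: np.ndarray) -> np.ndarray:
        v = np.maximum(np.asarray(v, dtype=float), 0.0)
        r2 = v**2
        c = target_mean_r2 - float(r2.mean())
        c = max(c, -float(r2.min()))  # keep all r^2 non-negative
        return np.sqrt(r2 + c)

    return anchor


# ---------------------------------------------------------------------------
# The charge system: cached per-frame geometry and the two objectives
# ---------------------------------------------------------------------------

class _FrameCache:
    """Per-frame distance matrix and refined density values.

    The squared minimum-image distances from every (refined) grid point
    to every atom do not depend on the radii, so they are computed once;
    each objective evaluation is then an argmin over columns shifted by
    -r^2 plus a weighted bincount.
    """

    def __init__(self, frame: VolumetricFrame, mol_assign: MoleculeAssignment, factor: int):
        self.frame = frame
        self.factor = factor
        self.mol_of_atom = mol_assign.molecule_id
        self.n_molecules = mol_assign.n_molecules
        fine = RefinedGrid(frame.grid, factor)
        d_blocks, v_blocks = [], []
        for _, pts, vals in fine.blocks():
            d_blocks.append(min_image_sq_distances(pts, frame.positions, frame.cell))
            v_blocks.append(vals.ravel())
        self.dist2 = np.vstack(d_blocks)
        self.values = np.concatenate(v_blocks)
        self.fine_voxel_volume = fine.voxel_volume_pm3
        self.frozen_dist2: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.dist2.shape[1]

    def atom_populations_one_step(self, r2_per_atom: np.ndarray) -> np.ndarray:
        owners = np.argmin(self.dist2 - r2_per_atom[None, :], axis=1)
        pops = np.bincount(owners, weights=self.values, minlength=self.n_atoms)
        return pops * self.fine_voxel_volume

    def molecule_populations_one_step(self, r2_per_atom: np.ndarray) -> np.ndarray:
        owners = np.argmin(self.dist2 - r2_per_atom[None, :], axis=1)
        mol = self.mol_of_atom[owners]
        pops = np.bincount(mol, weights=self.values, minlength=self.n_molecules)
        return pops * self.fine_voxel_volume

    def freeze_molecular(self, r2_mol_per_atom: np.ndarray) -> None:
        """Fix the molecular owner map; later atomic argmins are restricted to it."""
        owners = np.argmin(self.dist2 - r2_mol_per_atom[None, :], axis=1)
        mol_owner = self.mol_of_atom[owners]
        masked = self.dist2.copy()
        masked[mol_owner[:, None] != self.mol_of_atom[None, :]] = np.inf
        self.frozen_dist2 = masked

    def atom_populations_two_step(self, r2_atom_per_atom: np.ndarray) -> np.ndarray:
        if self.frozen_dist2 is None:
            raise RuntimeError("molecular owner map not frozen yet")
        owners = np.argmin(self.frozen_dist2 - r2_atom_per_atom[None, :], axis=1)
        pops = np.bincount(owners, weights=self.values, minlength=self.n_atoms)
        return pops * self.fine_voxel_volume

    def atom_populations_two_step_free(self, r2_mol: np.ndarray,
                                       r2_atom: np.ndarray) -> np.ndarray:
        """Full two-step populations without frozen maps (reference path)."""
        owners = np.argmin(self.dist2 - r2_mol[None, :], axis=1)
        mol_owner = self.mol_of_atom[owners]
        ao = restricted_argmin(self.dist2 - r2_atom[None, :], mol_owner, self.mol_of_atom)
        pops = np.bincount(ao, weights=self.values, minlength=self.n_atoms)
        return pops * self.fine_voxel_volume


class ChargeSystem:
    """Frames + topology + cached geometry; evaluates the two objectives.

    Topology (bonds, molecules, equivalence classes) is derived from the
    first frame and held fixed; frames whose bond graph differs raise a
    warning rather than being reclassified.
    """

    def __init__(self, frames: Sequence[VolumetricFrame], refinement: int = 2,
                 bond_scale: float = 1.15):
        if not frames:
            raise ValueError("need at least one frame")
        self.frames = list(frames)
        self.refinement = int(refinement)
        self.bond_graph = detect_bonds(self.frames[0], scale_factor=bond_scale)
        self.molecule_assignment = find_molecules(self.bond_graph, self.frames[0])
        self.classes = classify_equivalent_atoms(self.bond_graph, self.frames[0].elements)
        self.species_groups = group_equivalent_molecules(self.molecule_assignment)
        ref_edges = set(self.bond_graph.edges())
        for fr in self.frames[1:]:
            if set(detect_bonds(fr, scale_factor=bond_scale).edges()) != ref_edges:
                warnings.warn(
                    f"frame {fr.frame_index}: bond graph differs from frame 0; "
                    "topology from frame 0 is kept", stacklevel=2,
                )
        self.caches = [
            _FrameCache(fr, self.molecule_assignment, self.refinement) for fr in self.frames
        ]
        mols = self.molecule_assignment.molecules
        core = self.frames[0].core_charges
        self.molecule_core = np.array([core[list(m)].sum() for m in mols])
        self.atom_core = core

    # -- helpers -----------------------------------------------------------
    def _r2_per_atom(self, radii_values: np.ndarray) -> np.ndarray:
        v = np.maximum(np.asarray(radii_values, dtype=float), 0.0)
        return (v**2)[self.classes.class_id]

    def _eval_caches(self, config: OptimizerConfig | None = None):
        if config is not None and config.frames_per_evaluation is not None:
            return self.caches[: config.frames_per_evaluation]
        return self.caches

    # -- objectives --------------------------------------------------------
    def sigma_mol(self, radii_values: np.ndarray,
                  config: OptimizerConfig | None = None) -> float:
        """Molecular charge fluctuation under one-step molecular assignment."""
        r2 = self._r2_per_atom(radii_values)
        caches = self._eval_caches(config)
        charges = np.stack(
            [self.molecule_core - c.molecule_populations_one_step(r2) for c in caches]
        )  # (T, n_mol)
        samples = [charges[:, group] for group in self.species_groups]
        return charge_variance(samples)[1]

    def sigma_atom_frozen(self, radii_values: np.ndarray,
                          config: OptimizerConfig | None = None) -> float:
        """Atomic charge fluctuation with the molecular maps held fixed."""
        r2 = self._r2_per_atom(radii_values)
        caches = self._eval_caches(config)
        charges = np.stack(
            [self.atom_core - c.atom_populations_two_step(r2) for c in caches]
        )
        samples = [charges[:, list(m)] for m in self.classes.members]
        return charge_variance(samples)[1]

    def sigma_atom_one_step(self, radii_values: np.ndarray,
                            config: OptimizerConfig | None = None) -> float:
        """Atomic charge fluctuation under a plain one-step tessellation."""
        r2 = self._r2_per_atom(radii_values)
        caches = self._eval_caches(config)
        charges = np.stack(
            [self.atom_core - c.atom_populations_one_step(r2) for c in caches]
        )
        samples = [charges[:, list(m)] for m in self.classes.members]
        return charge_variance(samples)[1]

    def freeze_molecular(self, rmol: RadiiSet) -> None:
        r2 = self._r2_per_atom(rmol.values)
        for c in self.caches:
            c.freeze_molecular(r2)

    # -- final charges -----------------------------------------------------
    def charge_tables(self, rmol: RadiiSet, ratom: RadiiSet) -> list[ChargeTable]:
        """Two-step charges for every frame at the given radius sets."""
        r2m = self._r2_per_atom(rmol.values)
        r2a = self._r2_per_atom(ratom.values)
        tables = []
        for fr, c in zip(self.frames, self.caches):
            pops = c.atom_populations_two_step_free(r2m, r2a)
            q_atom = self.atom_core - pops
            q_mol = np.array(
                [q_atom[list(m)].sum() for m in self.molecule_assignment.molecules]
            )
            tables.append(ChargeTable(frame_index=fr.frame_index, atom_populations=pops,
                                      atom_charges=q_atom, molecule_charges=q_mol))
        return tables

    def charge_tables_one_step(self, radii: RadiiSet) -> list[ChargeTable]:
        r2 = self._r2_per_atom(radii.values)
        tables = []
        for fr, c in zip(self.frames, self.caches):
            pops = c.atom_populations_one_step(r2)
            q_atom = self.atom_core - pops
            q_mol = np.array(
                [q_atom[list(m)].sum() for m in self.molecule_assignment.molecules]
            )
            tables.append(ChargeTable(frame_index=fr.frame_index, atom_populations=pops,
                                      atom_charges=q_atom, molecule_charges=q_mol))
        return tables


# ---------------------------------------------------------------------------
# High-level drivers
# ---------------------------------------------------------------------------

def optimize_radii(system: ChargeSystem, objective_kind: str, initial: RadiiSet,
                   config: OptimizerConfig = OptimizerConfig(),
                   frozen: bool = False) -> tuple[RadiiSet, OptimizationResult]:
    """Minimize one charge-variance objective over per-class radii.

    ``objective_kind`` is 'molecular' or 'atomic'; with ``frozen`` the
    atomic objective uses the previously frozen molecular owner maps.
    """
    if objective_kind == "molecular":
        fn = lambda v: system.sigma_mol(v, config)  # noqa: E731
    elif objective_kind == "atomic":
        fn = (lambda v: system.sigma_atom_frozen(v, config)) if frozen else (
            lambda v: system.sigma_atom_one_step(v, config))
    else:
        raise ValueError(f"unknown objective kind {objective_kind!r}")
    x0 = np.asarray(initial.values, dtype=float)
    anchor = gauge_anchor(float(np.mean(x0**2)))
    result = minimize_cg(fn, x0, config, postprocess=anchor)
    return RadiiSet(values=np.maximum(result.x, 0.0), role=initial.role), result


@dataclass
class TwoStepResult:
    rmol: RadiiSet
    ratom: RadiiSet
    charge_tables: list[ChargeTable]
    molecular_stats: ChargeStatistics
    atomic_stats: ChargeStatistics
    stage1: OptimizationResult
    stage2: OptimizationResult
    system: ChargeSystem = field(repr=False, default=None)


def run_two_step_optimization(frames: Sequence[VolumetricFrame],
                              config: OptimizerConfig = OptimizerConfig(),
                              refinement: int = 2,
                              bond_scale: float = 1.15,
                              system: ChargeSystem | None = None) -> TwoStepResult:
    """Full pipeline: optimize rMol against the molecular objective, freeze
    the molecular owner maps, optimize rAtom against the atomic objective,
    and emit final charges and statistics."""
    if system is None:
        system = ChargeSystem(frames, refinement=refinement, bond_scale=bond_scale)
    elements = system.frames[0].elements
    rmol0 = initial_radii(system.classes, elements, "molecular")
    rmol, res1 = optimize_radii(system, "molecular", rmol0, config)
    system.freeze_molecular(rmol)
    ratom0 = initial_radii(system.classes, elements, "atomic")
    ratom, res2 = optimize_radii(system, "atomic", ratom0, config, frozen=True)
    tables = system.charge_tables(rmol, ratom)
    return TwoStepResult(
        rmol=rmol, ratom=ratom, charge_tables=tables,
        molecular_stats=molecular_statistics(tables, system.species_groups),
        atomic_stats=atomic_statistics(tables, system.classes),
        stage1=res1, stage2=res2, system=system,
    )
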