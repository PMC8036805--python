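"""Bond perception, molecule detection and topological equivalence classes.

Bonds are assigned by the standard covalent-radius criterion under the
minimum-image convention; molecules are the connected components of the
bond graph; atoms are grouped into equivalence classes by iterative
neighbourhood-signature refinement (Morgan / 1-Weisfeiler-Leman style),
starting from the element label. Each class becomes one radius parameter
of the optimizer, so e.g. a methyl and a hydroxyl hydrogen in methanol
end up in different classes while the three methyl hydrogens share one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .elements import UnknownElementError, covalent_radius
from .volumetric import VolumetricFrame


@dataclass(frozen=True)
class BondGraph:
    graph: nx.Graph  # nodes: atom indices; edge attr "distance": min-image pm

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges]


@dataclass(frozen=True)
class MoleculeAssignment:
    molecule_id: np.ndarray  # per atom
    molecules: tuple[tuple[int, ...], ...]  # atom indices per molecule
    species_id: np.ndarray  # per molecule

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_species(self) -> int:
        return int(self.species_id.max()) + 1 if self.n_molecules else 0


@dataclass(frozen=True)
class AtomTypeClasses:
    class_id: np.ndarray  # per atom, 0-based
    members: tuple[tuple[int, ...], ...]  # atom indices per class

    @property
    def n_classes(self) -> int:
        return len(self.members)

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.members]


def minimum_image_distance(cell, p: np.ndarray, q: np.ndarray) -> float:
    """Minimum-image distance between two points in a parallelepiped cell."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    frac = cell.to_fractional(d)
    frac -= np.round(frac)
    best = np.inf
    # the rounded fractional image is exact for orthorhombic cells; scan
    # the surrounding shell to cover skewed cells
    for shift in np.ndindex(3, 3, 3):
        s = np.array(shift) - 1
        cand = cell.to_cartesian(frac + s)
        best = min(best, float(np.dot(cand, cand)))
    return float(np.sqrt(best))


def detect_bonds(frame: VolumetricFrame, scale_factor: float = 1.15) -> BondGraph:
    """Bond (a, b) iff min-image distance <= scale_factor * (rcov_a + rcov_b)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    g = nx.Graph()
    rcov = np.empty(frame.n_atoms)
    for a in frame.atoms:
        try:
            rcov[a.index] = covalent_radius(a.element)
        except UnknownElementError:
            raise UnknownElementError(
                f"no covalent radius for element {a.element!r} (atom {a.index})"
            ) from None
        g.add_node(a.index, element=a.element)
    pos = frame.positions
    for i in range(frame.n_atoms):
        for j in range(i + 1, frame.n_atoms):
            cutoff = scale_factor * (rcov[i] + rcov[j])
            # cheap reject on the rounded-image distance before the shell scan
            d = minimum_image_distance(frame.cell, pos[i], pos[j])
            if d <= cutoff:
                g.add_edge(i, j, distance=d)
    return BondGraph(graph=g)


def find_molecules(bond_graph: BondGraph, frame: VolumetricFrame) -> MoleculeAssignment:
    """Connected components, with species by element-respecting isomorphism."""
    comps = [tuple(sorted(c)) for c in nx.connected_components(bond_graph.graph)]
    comps.sort(key=lambda c: c[0])
    mol_id = np.full(frame.n_atoms, -1, dtype=int)
    for m, comp in enumerate(comps):
        for a in comp:
            mol_id[a] = m

    subgraphs = [bond_graph.graph.subgraph(c) for c in comps]
    species = np.full(len(comps), -1, dtype=int)
    reps: list[int] = []  # molecule index representing each species
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    for m, sg in enumerate(subgraphs):
        for s, r in enumerate(reps):
            if nx.is_isomorphic(sg, subgraphs[r], node_match=nm):
                species[m] = s
                break
        else:
            species[m] = len(reps)
            reps.append(m)
    return MoleculeAssignment(molecule_id=mol_id, molecules=tuple(comps), species_id=species)


def classify_equivalent_atoms(bond_graph: BondGraph, elements: list[str]) -> AtomTypeClasses:
    """Iterative signature refinement of atom labels.

    Start from the element symbol; repeatedly replace each label by the
    pair (own label, sorted multiset of neighbour labels) until the
    induced partition is stable. Signatures are re-indexed by sorted
    order each round, which makes class ids deterministic and
    independent of the atom input order.
    """
    n = len(elements)
    order = sorted(set(elements))
    labels = np.array([order.index(e) for e in elements], dtype=int)
    for _ in range(max(n, 1)):
        sigs = []
        for i in range(n):
            nbrs = tuple(sorted(int(labels[j]) for j in bond_graph.graph.neighbors(i)))
            sigs.append((int(labels[i]), nbrs))
        uniq = sorted(set(sigs))
        new_labels = np.array([uniq.index(s) for s in sigs], dtype=int)
        if _same_partition(labels, new_labels):
            labels = new_labels
            break
        labels = new_labels
    members = tuple(
        tuple(int(i) for i in np.flatnonzero(labels == c)) for c in range(labels.max() + 1)
    )
    return AtomTypeClasses(class_id=labels, members=members)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label vectors induce the same partition of indices."""
    seen: dict[int, int] = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if x in seen:
            if seen[x] != y:
                return False
        else:
            seen[x] = y
    return len(set(seen.values())) == len(seen)


def group_equivalent_molecules(assignment: MoleculeAssignment) -> list[list[int]]:
    """Molecule ids per species; member count N_i feeds the molecular variance."""
    if assignment.n_molecules == 0:
        return []
    groups: list[list[int]] = [[] for _ in range(assignment.n_species)]
    for m, s in enumerate(assignment.species_id.tolist()):
        groups[s].append(m)
    return groups
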