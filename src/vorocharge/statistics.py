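"""Charge-variance objectives over equivalence classes and frames.

The objective minimized by the radius optimizer is the mean over classes
of the population variance of the member charges, pooled over all frames:

    Var = (1/K) sum_i (1/(T N_i)) sum_t sum_j (q_{i,t,j} - mu_i)^2
    mu_i = (1/(T N_i)) sum_t sum_j q_{i,t,j}

with K classes, N_i members per class and T frames. No Bessel correction
is applied (divisor T*N_i). Results are reported as sigma = sqrt(Var) to
stay in units of charge. For the *molecular* objective the classes are
molecule species and the samples are molecular charges; for the *atomic*
objective the classes are topological atom types and the samples are
atomic partial charges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .integration import ChargeTable
from .topology import AtomTypeClasses


@dataclass(frozen=True)
class ChargeStatistics:
    n_classes: int
    class_sizes: tuple[int, ...]
    n_frames: int
    means: np.ndarray  # mu_i, e
    class_variances: np.ndarray  # e^2, population convention
    variance: float  # e^2
    sigma: float  # e

    @property
    def class_sigmas(self) -> np.ndarray:
        return np.sqrt(self.class_variances)


def _as_class_arrays(samples: Sequence) -> list[np.ndarray]:
    arrays = []
    for i, s in enumerate(samples):
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError(f"class {i} has no charge samples")
        arrays.append(a)
    if not arrays:
        raise ValueError("no classes given")
    return arrays


def class_means(samples: Sequence) -> np.ndarray:
    """mu_i: mean over all T*N_i samples of each class."""
    return np.array([a.mean() for a in _as_class_arrays(samples)])


def charge_variance(samples: Sequence) -> tuple[float, float]:
    """(Var, sigma): mean over classes of the population variance."""
    arrays = _as_class_arrays(samples)
    per_class = np.array([np.mean((a - a.mean()) ** 2) for a in arrays])
    var = float(per_class.mean())
    return var, float(np.sqrt(var))


def compute_statistics(samples: Sequence, n_frames: int) -> ChargeStatistics:
    arrays = _as_class_arrays(samples)
    mu = np.array([a.mean() for a in arrays])
    per_class = np.array([np.mean((a - a.mean()) ** 2) for a in arrays])
    var = float(per_class.mean())
    sizes = tuple(a.size // n_frames for a in arrays)
    return ChargeStatistics(
        n_classes=len(arrays), class_sizes=sizes, n_frames=n_frames, means=mu,
        class_variances=per_class, variance=var, sigma=float(np.sqrt(var)),
    )


def molecular_samples(tables: Sequence[ChargeTable],
                      species_groups: Sequence[Sequence[int]]) -> list[np.ndarray]:
    """Per-species (T, N_i) arrays of molecular charges."""
    return [
        np.array([[t.molecule_charges[m] for m in group] for t in tables])
        for group in species_groups
    ]


def atomic_samples(tables: Sequence[ChargeTable],
                   classes: AtomTypeClasses) -> list[np.ndarray]:
    """Per-class (T, N_i) arrays of atomic charges."""
    return [
        np.array([[t.atom_charges[a] for a in members] for t in tables])
        for members in classes.members
    ]


def molecular_objective(tables: Sequence[ChargeTable],
                        species_groups: Sequence[Sequence[int]]) -> float:
    """sigma_mol: Eq-style objective with classes = molecule species."""
    if not tables:
        raise ValueError("need at least one frame of charges")
    _, sigma = charge_variance(molecular_samples(tables, species_groups))
    return sigma


def atomic_objective(tables: Sequence[ChargeTable],
                     classes: AtomTypeClasses) -> float:
    """sigma_atom: objective with classes = topological atom types."""
    if not tables:
        raise ValueError("need at least one frame of charges")
    _, sigma = charge_variance(atomic_samples(tables, classes))
    return sigma


def molecular_statistics(tables: Sequence[ChargeTable],
                         species_groups: Sequence[Sequence[int]]) -> ChargeStatistics:
    return compute_statistics(molecular_samples(tables, species_groups), len(tables))


def atomic_statistics(tables: Sequence[ChargeTable],
                      classes: AtomTypeClasses) -> ChargeStatistics:
    return compute_statistics(atomic_samples(tables, classes), len(tables))
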