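"""Periodic atomic + electron-density snapshots and Gaussian CUBE I/O.

A snapshot (:class:`VolumetricFrame`) couples a periodic parallelepiped
cell, a list of atoms, and the total electron density sampled on a
regular grid. Internally every length is in picometres and density
values are stored in e/pm**3, so that ``values.sum() * voxel_volume``
is the electron count of the box. Unit conversion happens only at I/O.

Grid points are defined at lattice nodes ``origin + i*v1 + j*v2 + k*v3``
with periodic index arithmetic; the cell vectors are ``a_k = n_k * v_k``.
"""

from __future__ import annotations

import glob as _glob
import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import ATOMIC_NUMBERS, BOHR_PM, SYMBOLS, default_core_charge


class CubeParseError(ValueError):
    """Malformed CUBE header or data block."""


@dataclass(frozen=True)
class UnitCell:
    """Periodic parallelepiped cell spanned by rows of ``matrix`` (pm)."""

    matrix: np.ndarray  # (3, 3), rows a1, a2, a3

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("cell matrix must be 3x3")
        object.__setattr__(self, "matrix", m)
        if self.volume <= 0.0:
            raise ValueError("cell vectors must be right-handed with positive volume")

    @property
    def volume(self) -> float:
        """Scalar triple product a1·(a2×a3) in pm³."""
        return float(np.linalg.det(self.matrix))

    @property
    def is_orthorhombic(self) -> bool:
        off = self.matrix - np.diag(np.diag(self.matrix))
        return bool(np.all(np.abs(off) < 1e-9 * np.abs(np.diag(self.matrix)).max()))

    def to_fractional(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ np.linalg.inv(self.matrix)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def wrap(self, xyz: np.ndarray) -> np.ndarray:
        """Wrap cartesian positions into the cell [0, 1)³ in fractional space."""
        frac = self.to_fractional(xyz) % 1.0
        return self.to_cartesian(frac)


@dataclass(frozen=True)
class AtomRecord:
    index: int
    element: str
    position: np.ndarray  # (3,) pm, wrapped into the cell
    core_charge: float  # e, positive

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        object.__setattr__(self, "position", p)
        if self.element not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element symbol {self.element!r}")


@dataclass(frozen=True)
class DensityGrid:
    """Density values on a periodic lattice; strides v_k = a_k / n_k (pm)."""

    strides: np.ndarray  # (3, 3), rows v1, v2, v3 in pm
    values: np.ndarray  # (n1, n2, n3), e/pm³
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        s = np.asarray(self.strides, dtype=float)
        v = np.asarray(self.values, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        if s.shape != (3, 3) or v.ndim != 3:
            raise ValueError("strides must be 3x3 and values a 3-d array")
        if np.isnan(v).any():
            raise ValueError("density grid contains NaN values")
        object.__setattr__(self, "strides", s)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", o)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume_pm3(self) -> float:
        return voxel_volume(self)

    @property
    def electron_count(self) -> float:
        return float(self.values.sum() * self.voxel_volume_pm3)

    def value_at(self, i: int, j: int, k: int) -> float:
        """Periodic lookup: indices wrap modulo the resolution."""
        n1, n2, n3 = self.shape
        return float(self.values[i % n1, j % n2, k % n3])

    def point_positions(self) -> np.ndarray:
        """Cartesian node positions (N, 3) in origin-relative coordinates.

        All internal geometry (atom positions included) is expressed
        relative to the grid origin; the origin is reapplied only when
        writing CUBE output.
        """
        n1, n2, n3 = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return idx.astype(float) @ self.strides


def voxel_volume(grid: DensityGrid) -> float:
    """Volume |v1·(v2×v3)| of one voxel in pm³."""
    return float(abs(np.linalg.det(grid.strides)))


@dataclass(frozen=True)
class VolumetricFrame:
    cell: UnitCell
    atoms: tuple[AtomRecord, ...]
    grid: DensityGrid
    frame_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        n = np.array(self.grid.shape, dtype=float)
        implied = self.grid.strides * n[:, None]
        if not np.allclose(implied, self.cell.matrix, rtol=1e-6, atol=1e-6):
            raise ValueError("grid strides are inconsistent with the cell vectors")
        if self.atoms:
            ncore = sum(a.core_charge for a in self.atoms)
            nelec = self.grid.electron_count
            if ncore > 0 and abs(nelec - ncore) > 0.05 * ncore:
                warnings.warn(
                    f"frame {self.frame_index}: electron count {nelec:.3f} deviates "
                    f"from total core charge {ncore:.3f} (non-neutral frame?)",
                    stacklevel=2,
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def core_charges(self) -> np.ndarray:
        return np.array([a.core_charge for a in self.atoms], dtype=float)


# ---------------------------------------------------------------------------
# CUBE I/O
# ---------------------------------------------------------------------------

_UNIT_CONVENTIONS = ("bohr_density", "raw_counts")


def read_cube(stream, unit_convention: str = "bohr_density",
              core_charges: dict[str, float] | None = None,
              frame_index: int = 0) -> VolumetricFrame:
    """Parse one Gaussian CUBE snapshot into a :class:`VolumetricFrame`.

    ``bohr_density`` interprets values as e/bohr³ (the Gaussian convention);
    ``raw_counts`` treats each value as the electron count of its voxel.
    Lengths in the file are bohr and are converted to pm. Molecular-orbital
    cubes (negative atom count) are rejected.
    """
    if unit_convention not in _UNIT_CONVENTIONS:
        raise ValueError(f"unit_convention must be one of {_UNIT_CONVENTIONS}")
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())

    def _line() -> str:
        ln = stream.readline()
        if not ln:
            raise CubeParseError("unexpected end of CUBE stream in header")
        return ln

    _line()  # two comment lines
    _line()
    try:
        head = _line().split()
        natom = int(head[0])
        origin_bohr = np.array([float(x) for x in head[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeParseError(f"malformed natom/origin line: {exc}") from exc
    if natom < 0:
        raise CubeParseError("negative atom count: molecular-orbital cubes are not supported")

    res = np.empty(3, dtype=int)
    strides_bohr = np.empty((3, 3))
    for k in range(3):
        parts = _line().split()
        try:
            res[k] = int(parts[0])
            strides_bohr[k] = [float(x) for x in parts[1:4]]
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"malformed axis line {k + 1}: {exc}") from exc
        if res[k] <= 0:
            raise CubeParseError("axis voxel counts must be positive (Angstrom cubes unsupported)")

    atoms = []
    for i in range(natom):
        parts = _line().split()
        try:
            z = int(parts[0])
            file_charge = float(parts[1])
            pos_bohr = np.array([float(x) for x in parts[2:5]])
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"malformed atom line {i}: {exc}") from exc
        symbol = SYMBOLS.get(z)
        if symbol is None:
            raise CubeParseError(f"unknown atomic number {z} on atom line {i}")
        atoms.append((symbol, file_charge, pos_bohr * BOHR_PM))

    try:
        raw = np.array(stream.read().split(), dtype=float)
    except ValueError as exc:
        raise CubeParseError(f"non-numeric CUBE data block: {exc}") from exc
    nval = int(res[0] * res[1] * res[2])
    if raw.size < nval:
        raise CubeParseError(f"expected {nval} density values, found {raw.size}")
    extra = raw.size - nval
    if extra:
        # tolerate trailing whitespace-only junk but nothing numeric
        raise CubeParseError(f"{extra} unexpected trailing values in CUBE data block")
    if np.isnan(raw).any():
        raise CubeParseError("NaN values in CUBE data block")
    values = raw.reshape(tuple(res))  # outer loop axis 1, inner axis 3 == C order

    strides_pm = strides_bohr * BOHR_PM
    vol_pm3 = float(abs(np.linalg.det(strides_pm)))
    if unit_convention == "bohr_density":
        values = values / BOHR_PM**3  # e/bohr³ -> e/pm³
    else:  # raw_counts
        values = values / vol_pm3

    cell = UnitCell(strides_pm * res[:, None].astype(float))
    grid = DensityGrid(strides=strides_pm, values=values, origin=origin_bohr * BOHR_PM)

    records = []
    for i, (symbol, file_charge, pos_pm) in enumerate(atoms):
        if core_charges is not None and symbol in core_charges:
            q = core_charges[symbol]
        elif file_charge > 0:
            q = file_charge
        else:
            q = default_core_charge(symbol)
        records.append(AtomRecord(index=i, element=symbol,
                                  position=cell.wrap(pos_pm - grid.origin),
                                  core_charge=q))
    return VolumetricFrame(cell=cell, atoms=tuple(records), grid=grid,
                           frame_index=frame_index)


def write_cube(frame: VolumetricFrame, stream, unit_convention: str = "bohr_density",
               comment: str = "vorocharge density") -> None:
    """Write a frame as a Gaussian CUBE (lengths in bohr)."""
    if unit_convention not in _UNIT_CONVENTIONS:
        raise ValueError(f"unit_convention must be one of {_UNIT_CONVENTIONS}")
    grid = frame.grid
    res = grid.shape
    origin_bohr = grid.origin / BOHR_PM
    stream.write(f"{comment}\n")
    stream.write(f"frame {frame.frame_index}\n")
    stream.write(f"{frame.n_atoms:5d} {origin_bohr[0]:18.12f} {origin_bohr[1]:18.12f} {origin_bohr[2]:18.12f}\n")
    for k in range(3):
        v = grid.strides[k] / BOHR_PM
        stream.write(f"{res[k]:5d} {v[0]:18.12f} {v[1]:18.12f} {v[2]:18.12f}\n")
    for a in frame.atoms:
        p = (a.position + grid.origin) / BOHR_PM
        z = ATOMIC_NUMBERS[a.element]
        stream.write(f"{z:5d} {a.core_charge:15.8f} {p[0]:18.12f} {p[1]:18.12f} {p[2]:18.12f}\n")

    if unit_convention == "bohr_density":
        out = grid.values * BOHR_PM**3
    else:
        out = grid.values * grid.voxel_volume_pm3
    flat = out.reshape(res[0] * res[1], res[2])
    for row in flat:
        for start in range(0, row.size, 6):
            chunk = row[start:start + 6]
            stream.write(" ".join(f"{x:18.11E}" for x in chunk) + "\n")


def read_frames(pattern_or_paths, unit_convention: str = "bohr_density",
                core_charges: dict[str, float] | None = None) -> list[VolumetricFrame]:
    """Read multiple CUBE files.

    A glob pattern expands lexicographically; an explicit list is taken as
    the frame order (a manifest).
    """
    if isinstance(pattern_or_paths, str):
        paths = sorted(_glob.glob(pattern_or_paths))
    else:
        paths = list(pattern_or_paths)
    if not paths:
        raise FileNotFoundError(f"no CUBE frames match {pattern_or_paths!r}")
    frames = []
    for t, path in enumerate(paths):
        with open(path) as fh:
            frames.append(read_cube(fh, unit_convention=unit_convention,
                                    core_charges=core_charges, frame_index=t))
    return frames


def with_frame_index(frame: VolumetricFrame, t: int) -> VolumetricFrame:
    return replace(frame, frame_index=t)
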