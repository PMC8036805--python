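import warnings

import numpy as np
import pytest

from vorocharge import (
    AtomRecord,
    DensityGrid,
    UnitCell,
    VolumetricFrame,
    build_water_box,
)


def make_frame(elements, positions, cell_length=2000.0, grid_n=4, values=None,
               core_charges=None):
    """Minimal frame with a uniform (or given) density for geometry tests."""
    cell = UnitCell(np.eye(3) * cell_length)
    if values is None:
        values = np.full((grid_n,) * 3, 1e-9)
    grid = DensityGrid(strides=cell.matrix / grid_n, values=values)
    atoms = tuple(
        AtomRecord(index=i, element=e, position=np.asarray(p, dtype=float),
                   core_charge=(core_charges[i] if core_charges else 1.0))
        for i, (e, p) in enumerate(zip(elements, positions))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return VolumetricFrame(cell=cell, atoms=atoms, grid=grid)


@pytest.fixture(scope="session")
def water_frames():
    frames, truth = build_water_box(2, grid_n=16, n_frames=2, seed=11, jitter_pm=6.0)
    return frames, truth
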