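"""Power distances, separation planes, gauge invariance and assignment."""

import numpy as np
import pytest

from vorocharge import (
    RadiiSet,
    SiteSet,
    UnitCell,
    assign_one_step,
    assign_two_step,
    detect_bonds,
    find_molecules,
    gauge_shift,
    min_image_sq_distances,
    plane_position,
    power_distance,
)

from conftest import make_frame


CELL = UnitCell(np.eye(3) * 1000.0)


class TestPowerDistance:
    def test_coincident_zero_radius(self):
        p = np.array([100.0, 100.0, 100.0])
        assert power_distance(p, p, 0.0, CELL) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        x = np.array([105.0, 100.0, 100.0])
        p = np.array([100.0, 100.0, 100.0])
        assert power_distance(x, p, 3.0, CELL) == pytest.approx(16.0)

    def test_uses_nearest_periodic_image(self):
        x = np.array([5.0, 0.0, 0.0])
        p = np.array([995.0, 0.0, 0.0])
        assert power_distance(x, p, 0.0, CELL) == pytest.approx(100.0)

    def test_equal_radii_order_is_euclidean(self):
        rng = np.random.default_rng(9)
        sites = rng.uniform(0, 1000, size=(6, 3))
        pts = rng.uniform(0, 1000, size=(50, 3))
        d2 = min_image_sq_distances(pts, sites, CELL)
        power = d2 - 40.0**2  # equal radii shift all columns alike
        assert np.array_equal(np.argmin(power, axis=1), np.argmin(d2, axis=1))


class TestPlanePosition:
    def test_equal_radii_midpoint(self):
        assert plane_position(70.0, 70.0, 321.0) == pytest.approx(160.5)

    def test_direct_evaluation(self):
        assert plane_position(100.0, 0.0, 200.0) == pytest.approx(125.0)

    def test_large_distance_limit(self):
        r = 1e7
        assert plane_position(120.0, 40.0, r) / r == pytest.approx(0.5, abs=1e-6)

    def test_degenerate_regime_beyond_b(self):
        w = plane_position(80.0, 10.0, 50.0)
        assert w == pytest.approx(88.0)
        assert w > 50.0  # plane beyond B: B's pair cell is empty

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            plane_position(10.0, 10.0, 0.0)


class TestGaugeShift:
    def test_identity(self):
        r = RadiiSet(np.array([50.0, 100.0]))
        assert np.array_equal(gauge_shift(r, 0.0).values, r.values)

    def test_sqrt_arithmetic(self):
        r = gauge_shift(RadiiSet(np.array([50.0, 100.0])), 2500.0)
        assert np.allclose(r.values, [np.sqrt(5000.0), np.sqrt(12500.0)])
        assert r.values == pytest.approx([70.7106781, 111.8033989])

    def test_negative_square_rejected(self):
        with pytest.raises(ValueError):
            gauge_shift(RadiiSet(np.array([50.0, 100.0])), -2600.0)

    def test_power_differences_unchanged(self):
        rng = np.random.default_rng(3)
        sites = rng.uniform(0, 1000, (4, 3))
        radii = np.array([30.0, 60.0, 90.0, 120.0])
        x = rng.uniform(0, 1000, 3)
        base = [power_distance(x, p, r, CELL) for p, r in zip(sites, radii)]
        shifted = gauge_shift(RadiiSet(radii), 5000.0).values
        new = [power_distance(x, p, r, CELL) for p, r in zip(sites, shifted)]
        diffs0 = np.subtract.outer(base, base)
        diffs1 = np.subtract.outer(new, new)
        assert np.allclose(diffs0, diffs1, atol=1e-9)

    def test_assignment_bit_identical_under_gauge(self, water_frames):
        frames, _ = water_frames
        f = frames[0]
        radii = np.array([120.0, 152.0, 152.0, 120.0, 120.0, 152.0])
        sites = SiteSet(positions=f.positions, radii=radii, cell=f.cell)
        owners = assign_one_step(f, sites)
        for c in (-radii.min() ** 2, 1.0e4):
            shifted = np.sqrt(radii**2 + c)
            owners_c = assign_one_step(f, SiteSet(f.positions, shifted, f.cell))
            assert np.array_equal(owners, owners_c)


class TestAssignOneStep:
    def test_single_site_owns_everything(self, water_frames):
        frames, _ = water_frames
        f = frames[0]
        sites = SiteSet(positions=f.positions[:1], radii=np.array([50.0]), cell=f.cell)
        owners = assign_one_step(f, sites)
        assert owners.shape == f.grid.shape
        assert np.all(owners == 0)

    def test_symmetric_pair_splits_evenly(self):
        # sites placed so neither separation plane contains lattice points
        f = make_frame(["He", "He"], [(200, 500, 500), (700, 500, 500)],
                       cell_length=1000.0, grid_n=10)
        sites = SiteSet(positions=f.positions, radii=np.array([80.0, 80.0]), cell=f.cell)
        counts = np.bincount(assign_one_step(f, sites).ravel(), minlength=2)
        assert counts[0] == counts[1] == 10**3 // 2

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(21)
        f = make_frame(["He"] * 5, rng.uniform(0, 1000, (5, 3)),
                       cell_length=1000.0, grid_n=10)
        sites = SiteSet(f.positions, rng.uniform(0, 150, 5), f.cell)
        counts = np.bincount(assign_one_step(f, sites).ravel(), minlength=5)
        assert counts.sum() == 10**3

    @pytest.mark.parametrize("ra,rb,sep", [
        (80.0, 80.0, 400.0),
        (120.0, 60.0, 400.0),
        (60.0, 120.0, 400.0),
        (150.0, 30.0, 500.0),
        (100.0, 0.0, 300.0),
    ])
    def test_boundary_matches_plane_position(self, ra, rb, sep):
        n = 40
        cell_length = 1600.0
        stride = cell_length / n
        xa = cell_length / 2 - sep / 2
        f = make_frame(["He", "He"],
                       [(xa, cell_length / 2, cell_length / 2),
                        (xa + sep, cell_length / 2, cell_length / 2)],
                       cell_length=cell_length, grid_n=n)
        sites = SiteSet(f.positions, np.array([ra, rb]), f.cell)
        owners = assign_one_step(f, sites)
        row = owners[:, n // 2, n // 2]
        xs = np.arange(n) * stride
        inside = (xs > xa) & (xs < xa + sep)
        first_b = xs[inside][np.argmax(row[inside] == 1)]
        w = plane_position(ra, rb, sep)
        assert abs((first_b - xa) - w) <= stride

    def test_degenerate_cell_owns_nothing(self):
        # a small site squeezed between two large ones is degenerate: it
        # owns zero points, and assignment proceeds without error
        f = make_frame(["He", "He", "He"],
                       [(75, 100, 100), (100, 100, 100), (125, 100, 100)],
                       cell_length=200.0, grid_n=10)
        sites = SiteSet(f.positions, np.array([80.0, 10.0, 80.0]), f.cell)
        counts = np.bincount(assign_one_step(f, sites).ravel(), minlength=3)
        assert counts[1] == 0
        assert counts.sum() == 10**3

    def test_tie_breaks_to_lowest_index(self):
        f = make_frame(["He", "He"], [(25, 50, 50), (75, 50, 50)],
                       cell_length=100.0, grid_n=10)
        sites = SiteSet(f.positions, np.array([10.0, 10.0]), f.cell)
        owners = assign_one_step(f, sites)
        # the x=50 and x=0 planes are exactly equidistant from both sites
        assert np.all(owners[5, :, :] == 0)
        assert np.all(owners[0, :, :] == 0)


class TestClassicalLimitOracle:
    def test_equal_radii_matches_euclidean_oracle(self):
        rng = np.random.default_rng(17)
        n, n_sites = 20, 12
        f = make_frame(["He"] * n_sites, rng.uniform(0, 1000, (n_sites, 3)),
                       cell_length=1000.0, grid_n=n)
        sites = SiteSet(f.positions, np.full(n_sites, 70.0), f.cell)
        owners = assign_one_step(f, sites).ravel()
        # independent brute force: explicit 27-image Euclidean scan
        pts = f.grid.point_positions()
        shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1)], dtype=float) @ f.cell.matrix
        best = np.full(pts.shape[0], np.inf)
        win = np.zeros(pts.shape[0], dtype=int)
        for j in range(n_sites):
            d2 = np.full(pts.shape[0], np.inf)
            for s in shifts:
                diff = pts - (f.positions[j] + s)
                np.minimum(d2, np.einsum("ij,ij->i", diff, diff), out=d2)
            better = d2 < best
            best[better] = d2[better]
            win[better] = j
        assert np.array_equal(owners, win)


class TestAssignTwoStep:
    @pytest.fixture()
    def two_waters(self, water_frames):
        frames, _ = water_frames
        f = frames[0]
        mols = find_molecules(detect_bonds(f), f)
        return f, mols

    def test_every_point_owned_once(self, two_waters):
        f, mols = two_waters
        rmol = SiteSet(f.positions, np.array([152.0, 120, 120, 152, 120, 120]), f.cell)
        ratom = SiteSet(f.positions, np.array([66.0, 31, 31, 66, 31, 31]), f.cell)
        ca = assign_two_step(f, rmol, ratom, mols)
        assert np.bincount(ca.atom_owner.ravel(), minlength=6).sum() == f.grid.n_points
        # atom owner's molecule is always the molecule owner
        assert np.array_equal(mols.molecule_id[ca.atom_owner], ca.molecule_owner)

    def test_atom_owner_stays_in_owning_molecule(self, two_waters):
        # inflate molecule 0's radii: points near molecule 1's atoms still get
        # atom owners from molecule 0 wherever molecule 0 wins step one
        f, mols = two_waters
        big = np.where(mols.molecule_id == 0, 400.0, 10.0)
        rmol = SiteSet(f.positions, big, f.cell)
        ratom = SiteSet(f.positions, np.full(6, 50.0), f.cell)
        ca = assign_two_step(f, rmol, ratom, mols)
        m0 = ca.molecule_owner == 0
        assert m0.any()
        assert np.all(np.isin(ca.atom_owner[m0], list(mols.molecules[0])))
        # and molecule 1 is squeezed into a (possibly tiny) remainder
        assert set(np.unique(ca.atom_owner[~m0])) <= set(mols.molecules[1]) or not (~m0).any()

    def test_single_atom_molecules_reduce_to_one_step(self):
        rng = np.random.default_rng(6)
        f = make_frame(["Ne", "He", "Ne"],
                       [(200, 300, 400), (700, 650, 300), (450, 100, 800)],
                       cell_length=1000.0, grid_n=8)
        mols = find_molecules(detect_bonds(f), f)
        radii = rng.uniform(40, 140, 3)
        rmol = SiteSet(f.positions, radii, f.cell)
        ca = assign_two_step(f, rmol, rmol, mols)
        one = assign_one_step(f, rmol)
        assert np.array_equal(ca.atom_owner, one)
        assert np.array_equal(ca.molecule_owner, mols.molecule_id[one])

    def test_equal_radius_sets_consistent_with_one_step(self, two_waters):
        f, mols = two_waters
        radii = np.array([152.0, 120, 120, 152, 120, 120])
        sites = SiteSet(f.positions, radii, f.cell)
        ca = assign_two_step(f, sites, sites, mols)
        one = assign_one_step(f, sites)
        assert np.array_equal(mols.molecule_id[one], ca.molecule_owner)

    def test_degenerate_sets_reported(self, two_waters):
        f, mols = two_waters
        radii = np.array([400.0, 0.0, 0.0, 400.0, 0.0, 0.0])
        rmol = SiteSet(f.positions, radii, f.cell)
        ca = assign_two_step(f, rmol, rmol, mols)
        assert all(a in ca.degenerate_atoms for a in (1, 2, 4, 5))


class TestOwnerMapExport:
    def test_owner_labels_roundtrip_through_cube(self, water_frames):
        import io

        from vorocharge import read_cube, write_cube
        from vorocharge.tessellation import owner_map_frame

        frames, _ = water_frames
        f = frames[0]
        sites = SiteSet(f.positions, np.full(6, 80.0), f.cell)
        owners = assign_one_step(f, sites)
        buf = io.StringIO()
        write_cube(owner_map_frame(f, owners), buf, unit_convention="raw_counts")
        buf.seek(0)
        back = read_cube(buf, unit_convention="raw_counts")
        labels = back.grid.values * back.grid.voxel_volume_pm3
        assert np.allclose(labels, owners, atol=1e-6)
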