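"""Fourier synthesis, resampling, voxel arithmetic, masking, MRC I/O."""

import gemmi
import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from diffmapkit import (DensityMap, Pose, ReflectionSet, expand_to_p1,
                        fcalc_direct, full_hkl_list, read_mrc, resample_map,
                        sigma_scale, solvent_mask_map, spacegroup,
                        subtract_maps, synthesize_map, write_mrc)


def coeffs_of(structure, d_min=2.0):
    hkl = full_hkl_list(structure.cell, structure.sg, d_min)
    f = fcalc_direct(structure, hkl)
    df = pd.DataFrame({"H": hkl[:, 0], "K": hkl[:, 1], "L": hkl[:, 2],
                       "F": np.abs(f), "PHI": np.degrees(np.angle(f))})
    return expand_to_p1(
        ReflectionSet(df, structure.cell, structure.sg))


class TestSynthesis:
    def test_zero_coefficients_zero_map(self, p1_cell):
        hkl = np.array([[1, 0, 0], [0, 2, 0]])
        dmap = synthesize_map((hkl, np.zeros(2, dtype=complex)),
                              grid_spacing=1.0, cell=p1_cell)
        assert np.all(dmap.values == 0)

    def test_single_cosine_wave(self):
        cell = gemmi.UnitCell(10, 10, 10, 90, 90, 90)
        hkl = np.array([[1, 0, 0], [-1, 0, 0]])
        f = np.array([1.0 + 0j, 1.0 + 0j])
        dmap = synthesize_map((hkl, f), shape=(16, 16, 16), cell=cell)
        # rho(x) = (1/V)(e^{-2pi i x} + e^{+2pi i x}) = 2 cos(2 pi x)/V
        x = np.arange(16) / 16
        expected = 2.0 * np.cos(2 * np.pi * x) / cell.volume
        assert np.allclose(dmap.values[:, 0, 0], expected, atol=1e-12)
        assert dmap.values[0, 0, 0] == pytest.approx(2.0 / cell.volume)

    def test_peaks_at_atom_sites(self, small_p1_structure):
        dmap = synthesize_map(coeffs_of(small_p1_structure, 2.0),
                              grid_spacing=2.0 / 3)
        n = np.array(dmap.shape)
        # each atom should sit within one grid step of a local maximum
        mx = ndimage.maximum_filter(dmap.values, size=3, mode="wrap")
        peaks = np.argwhere(dmap.values == mx)
        for i, frac in enumerate(small_p1_structure.xyz_frac):
            d = np.abs((peaks / n - frac + 0.5) % 1.0 - 0.5) * n
            assert (d.max(axis=1) <= 1.0 + 1e-9).any()
        # heaviest atom (S) has the tallest peak
        vals = [dmap.values[tuple(np.round(f * n).astype(int) % n)]
                for f in small_p1_structure.xyz_frac]
        assert int(np.argmax(vals)) == 3  # S is atom index 3

    def test_friedel_inconsistent_rejected(self, p1_cell):
        hkl = np.array([[1, 0, 0], [-1, 0, 0]])
        f = np.array([1.0 + 0j, 5.0 + 2j])  # not conjugate
        with pytest.raises(ValueError, match="Friedel"):
            synthesize_map((hkl, f), shape=(12, 12, 12), cell=p1_cell)

    def test_parseval(self, small_p1_structure):
        """sum |F|^2 / V equals the grid integral of rho^2 (F000 excluded
        on both sides)."""
        coeffs = coeffs_of(small_p1_structure, 2.0)
        dmap = synthesize_map(coeffs, grid_spacing=2.0 / 4)
        v = small_p1_structure.cell.volume
        f = coeffs.df["F"].to_numpy()
        lhs = np.sum(f**2) / v
        rho = dmap.values - dmap.values.mean()
        rhs = np.sum(rho**2) * v / rho.size
        assert rhs == pytest.approx(lhs, rel=0.005)


class TestLinearity:
    def test_synthesis_commutes_with_subtraction(self, p1_cell):
        """Subtracting coefficients then transforming equals transforming
        then subtracting maps -- the identity that licenses real-space
        difference maps."""
        rng = np.random.default_rng(12)
        hkl = full_hkl_list(p1_cell, spacegroup("P 1"), 3.0)
        fa = rng.normal(size=len(hkl)) + 1j * rng.normal(size=len(hkl))
        fb = rng.normal(size=len(hkl)) + 1j * rng.normal(size=len(hkl))
        shape = (30, 34, 40)
        map_a = synthesize_map((hkl, fa), shape=shape, cell=p1_cell)
        map_b = synthesize_map((hkl, fb), shape=shape, cell=p1_cell)
        map_diff = synthesize_map((hkl, fa - fb), shape=shape, cell=p1_cell)
        voxelwise = subtract_maps(map_a, map_b)
        assert np.abs(map_diff.values - voxelwise.values).max() \
            < 1e-8 * map_diff.sigma


class TestResampling:
    def test_identity_pose_identical(self, small_p1_structure):
        dmap = synthesize_map(coeffs_of(small_p1_structure), grid_spacing=0.8)
        out = resample_map(dmap, Pose.identity())
        assert np.allclose(out.values, dmap.values, atol=1e-10)

    def test_lattice_commensurate_shift_is_circular_roll(self, p1_cell):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(15, 17, 20))
        dmap = DensityMap(vals, p1_cell, spacegroup("P 1"))
        # shift by exactly 2 grid steps along x: a/15*2 angstroms
        t = np.array([2 * p1_cell.a / 15, 0, 0])
        out = resample_map(dmap, Pose(np.eye(3), t, np.zeros(3)))
        assert np.allclose(out.values, np.roll(vals, 2, axis=0), atol=1e-6)

    def test_rotated_blob_centroid_and_mass(self, p1_cell):
        from scipy.spatial.transform import Rotation
        shape = (45, 51, 60)
        n = np.array(shape)
        center_frac = np.array([0.4, 0.45, 0.5])
        grids = np.meshgrid(*[np.arange(nn) / nn for nn in n], indexing="ij")
        fr = np.stack(grids, axis=-1) - center_frac
        a_mat = np.diag([p1_cell.a, p1_cell.b, p1_cell.c])
        d2 = np.einsum("...i,...i->...", fr @ a_mat, fr @ a_mat)
        blob = np.exp(-d2 / 2.0)
        dmap = DensityMap(blob, p1_cell, spacegroup("P 1"))
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        pivot = np.array([10.0, 12.0, 15.0])
        pose = Pose(rot, np.zeros(3), pivot)
        out = resample_map(dmap, pose)
        # centroid moves to the pose-transformed position
        w = out.values / out.values.sum()
        com = np.array([np.sum(w * g) for g in grids]) * \
            np.array([p1_cell.a, p1_cell.b, p1_cell.c])
        expected = pose.apply(center_frac * [p1_cell.a, p1_cell.b, p1_cell.c])
        step = p1_cell.a / shape[0]
        assert np.linalg.norm(com - expected) < 0.3 * step
        # integrated density conserved
        assert out.values.sum() == pytest.approx(blob.sum(), rel=0.005)

    def test_round_trip_through_pose(self, small_p1_structure):
        from scipy.spatial.transform import Rotation
        dmap = synthesize_map(coeffs_of(small_p1_structure, 3.0),
                              grid_spacing=0.5)
        rot = Rotation.from_euler("y", 18, degrees=True).as_matrix()
        pose = Pose(rot, np.array([1.0, -2.0, 0.5]), np.array([15.0, 17, 20]))
        back = resample_map(resample_map(dmap, pose), pose.inverse())
        err = np.abs(back.values - dmap.values).max()
        # documented interpolation bound on a band-limited map (~6 grid
        # samples per finest Fourier period)
        assert err < 0.05 * np.abs(dmap.values).max()


class TestVoxelArithmetic:
    def test_self_subtraction_zero(self, small_p1_structure):
        dmap = synthesize_map(coeffs_of(small_p1_structure), grid_spacing=0.8)
        assert np.all(subtract_maps(dmap, dmap).values == 0)

    def test_antisymmetry(self, p1_cell):
        rng = np.random.default_rng(0)
        a = DensityMap(rng.normal(size=(8, 8, 8)), p1_cell, spacegroup("P 1"))
        b = DensityMap(rng.normal(size=(8, 8, 8)), p1_cell, spacegroup("P 1"))
        assert np.allclose(subtract_maps(a, b).values,
                           -subtract_maps(b, a).values)

    def test_grid_mismatch_rejected(self, p1_cell):
        a = DensityMap(np.zeros((8, 8, 8)), p1_cell, spacegroup("P 1"))
        b = DensityMap(np.zeros((8, 8, 10)), p1_cell, spacegroup("P 1"))
        with pytest.raises(ValueError, match="mismatch"):
            subtract_maps(a, b)

    def test_constructed_blob_recovered(self, small_p1_structure):
        base = synthesize_map(coeffs_of(small_p1_structure), grid_spacing=0.8)
        blob = base.copy()
        blob.values = blob.values.copy()
        blob.values[5, 6, 7] += 3.0
        diff = subtract_maps(blob, base)
        assert diff.values[5, 6, 7] == pytest.approx(3.0)
        assert np.abs(np.delete(diff.values.ravel(),
                                np.ravel_multi_index((5, 6, 7),
                                                     diff.shape))).max() == 0


class TestMasking:
    def test_huge_radius_keeps_everything(self, small_p1_structure):
        rng = np.random.default_rng(1)
        dmap = DensityMap(rng.normal(size=(16, 18, 20)),
                          small_p1_structure.cell, spacegroup("P 1"))
        out, frac = solvent_mask_map(dmap, small_p1_structure, radius=200.0)
        assert frac == 0.0
        assert np.array_equal(out.values, dmap.values)

    def test_zero_radius_masks_everything(self, small_p1_structure):
        rng = np.random.default_rng(1)
        dmap = DensityMap(rng.normal(size=(16, 18, 20)),
                          small_p1_structure.cell, spacegroup("P 1"))
        out, frac = solvent_mask_map(dmap, small_p1_structure, radius=0.0)
        assert frac == pytest.approx(1.0)

    def test_matches_brute_force_distance_check(self, p1_cell):
        from diffmapkit import Structure
        st = Structure(["C", "O"], np.array([[0.2, 0.3, 0.4],
                                             [0.6, 0.5, 0.35]]),
                       np.array([5.0, 5.0]), np.ones(2), ["A", "A"],
                       np.array([1, 2]), p1_cell, spacegroup("P 1"))
        rng = np.random.default_rng(2)
        dmap = DensityMap(rng.normal(size=(15, 17, 20)) + 10.0, p1_cell,
                          spacegroup("P 1"))
        out, _ = solvent_mask_map(dmap, st, radius=2.0)
        n = np.array(dmap.shape)
        a = np.diag([p1_cell.a, p1_cell.b, p1_cell.c])
        for idx in rng.integers(0, n, size=(200, 3)):
            frac = idx / n
            dmin = np.inf
            for atom_frac in st.xyz_frac:
                d = (frac - atom_frac + 0.5) % 1.0 - 0.5
                dmin = min(dmin, np.linalg.norm(d @ a))
            kept = out.values[tuple(idx)] != 0
            assert kept == (dmin <= 2.0)


class TestSigmaScaling:
    def test_unit_sigma_and_idempotence(self, p1_cell):
        rng = np.random.default_rng(3)
        dmap = DensityMap(rng.normal(size=(10, 10, 10)), p1_cell,
                          spacegroup("P 1"))
        scaled, sigma = sigma_scale(dmap)
        assert scaled.sigma == pytest.approx(1.0)
        again, sigma2 = sigma_scale(scaled)
        assert sigma2 == pytest.approx(1.0)

    def test_region_matches_brute_force(self, p1_cell):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 10, 10))
        vals[:5] = 0.0
        dmap = DensityMap(vals, p1_cell, spacegroup("P 1"))
        region = vals != 0
        _, sigma = sigma_scale(dmap, region=region)
        assert sigma == pytest.approx(vals[region].std())
        _, sigma_all = sigma_scale(dmap)
        assert sigma_all == pytest.approx(vals.std())

    def test_constant_map_rejected(self, p1_cell):
        dmap = DensityMap(np.full((8, 8, 8), 2.5), p1_cell, spacegroup("P 1"))
        with pytest.raises(ValueError, match="constant"):
            sigma_scale(dmap)


class TestMrcIO:
    def test_roundtrip(self, small_p1_structure, tmp_path):
        rng = np.random.default_rng(11)
        dmap = DensityMap(rng.normal(size=(30, 34, 40)),
                          small_p1_structure.cell, spacegroup("P 1"))
        path = tmp_path / "m.ccp4"
        write_mrc(dmap, path)
        back = read_mrc(path)
        assert back.shape == dmap.shape
        assert np.abs(back.values - dmap.values).max() < 1e-6 * dmap.sigma
        assert back.cell.a == pytest.approx(dmap.cell.a, abs=1e-4)

    def test_header_statistics(self, small_p1_structure, tmp_path):
        import struct
        dmap = synthesize_map(coeffs_of(small_p1_structure), grid_spacing=0.8)
        path = tmp_path / "m.ccp4"
        write_mrc(dmap, path)
        raw = path.read_bytes()
        dmean = struct.unpack("<f", raw[84:88])[0]
        assert dmean == pytest.approx(dmap.values.mean(), abs=1e-5)

    def test_independent_reader(self, small_p1_structure, tmp_path):
        """Probe voxels via a hand-rolled MRC2014 header/data parse."""
        import struct
        dmap = synthesize_map(coeffs_of(small_p1_structure), grid_spacing=0.8)
        path = tmp_path / "m.ccp4"
        write_mrc(dmap, path)
        raw = path.read_bytes()
        nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
        nsymbt = struct.unpack("<i", raw[92:96])[0]
        assert mode == 2  # float32
        data = np.frombuffer(raw[1024 + nsymbt:], dtype="<f4")
        data = data.reshape(nz, ny, nx)  # file order: slow to fast
        mapc, mapr, maps_ = struct.unpack("<3i", raw[64:76])
        assert (mapc, mapr, maps_) == (1, 2, 3)  # fast-to-slow = X,Y,Z
        rng = np.random.default_rng(5)
        for _ in range(10):
            i, j, k = (rng.integers(0, s) for s in dmap.shape)
            assert data[k, j, i] == pytest.approx(dmap.values[i, j, k],
                                                  rel=1e-5, abs=1e-8)
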