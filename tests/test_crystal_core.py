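"""Cells, symmetry, coordinate conversions and file round-trips."""

import gemmi
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffmapkit import (ReflectionSet, Structure, expand_to_p1, fcalc_direct,
                        frac_to_orth, orth_to_frac, read_model,
                        read_reflections, resolution_of, spacegroup,
                        write_model, write_reflections)
from diffmapkit.crystal_core import map_to_asu, orth_matrix


def brute_orth_matrix(a, b, c, alpha, beta, gamma):
    """Textbook orthogonalization matrix (a along x, b in x-y plane)."""
    al, be, ga = np.radians([alpha, beta, gamma])
    v = np.sqrt(1 - np.cos(al) ** 2 - np.cos(be) ** 2 - np.cos(ga) ** 2
                + 2 * np.cos(al) * np.cos(be) * np.cos(ga))
    return np.array([
        [a, b * np.cos(ga), c * np.cos(be)],
        [0, b * np.sin(ga),
         c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)],
        [0, 0, c * v / np.sin(ga)],
    ])


class TestCoordinates:
    def test_cubic_center(self):
        cell = gemmi.UnitCell(10, 10, 10, 90, 90, 90)
        assert np.allclose(frac_to_orth(cell, [0.5, 0.5, 0.5]), [5, 5, 5])

    def test_origin_fixed_point(self):
        cell = gemmi.UnitCell(23, 31, 47, 83, 99, 105)
        assert np.allclose(frac_to_orth(cell, [0, 0, 0]), [0, 0, 0])

    def test_monoclinic_against_textbook_matrix(self):
        params = (10, 12, 14, 90, 100, 90)
        cell = gemmi.UnitCell(*params)
        expected = brute_orth_matrix(*params) @ np.array([0.0, 0.0, 1.0])
        assert np.allclose(frac_to_orth(cell, [0, 0, 1]), expected, atol=1e-9)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(Exception):
            orth_matrix(gemmi.UnitCell(10, 10, 10, 90, 90, 179.99999))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_random_cells(self, seed):
        rng = np.random.default_rng(seed)
        cell = gemmi.UnitCell(*(10 + 40 * rng.random(3)),
                              *(60 + 60 * rng.random(3)))
        v = rng.random(3)
        assert np.allclose(orth_to_frac(cell, frac_to_orth(cell, v)), v,
                           atol=1e-10)


class TestResolution:
    @pytest.mark.parametrize("hkl,expected", [((1, 0, 0), 10.0),
                                              ((0, 0, 2), 5.0)])
    def test_cubic_axial(self, hkl, expected):
        cell = gemmi.UnitCell(10, 10, 10, 90, 90, 90)
        assert resolution_of(cell, hkl) == pytest.approx(expected)

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            resolution_of(gemmi.UnitCell(10, 10, 10, 90, 90, 90), (0, 0, 0))

    def test_against_reciprocal_metric_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            cell = gemmi.UnitCell(*(10 + 40 * rng.random(3)),
                                  *(70 + 40 * rng.random(3)))
            hkl = rng.integers(-8, 9, 3)
            if not hkl.any():
                continue
            a = brute_orth_matrix(cell.a, cell.b, cell.c, cell.alpha,
                                  cell.beta, cell.gamma)
            gstar = np.linalg.inv(a) @ np.linalg.inv(a).T
            d_oracle = 1.0 / np.sqrt(hkl @ gstar @ hkl)
            assert resolution_of(cell, hkl) == pytest.approx(d_oracle,
                                                             abs=1e-10)


class TestSpaceGroups:
    def test_known_symbols(self):
        for symbol, n_ops in [("P 1", 1), ("P 21 21 21", 4),
                              ("P 1 21 1", 2), ("C 1 2 1", 4)]:
            sg = spacegroup(symbol)
            assert len(list(sg.operations())) == n_ops

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            spacegroup("Q 5")


class TestModelIO:
    def test_pdb_roundtrip(self, small_p1_structure, tmp_path):
        path = tmp_path / "m.pdb"
        write_model(small_p1_structure, path)
        back = read_model(path)
        # PDB coordinates carry 3 decimals
        assert np.allclose(back.xyz_orth, small_p1_structure.xyz_orth,
                           atol=1e-3)
        assert np.allclose(back.b_iso, small_p1_structure.b_iso, atol=1e-2)
        assert np.allclose(back.occ, small_p1_structure.occ, atol=1e-2)
        assert back.chain_ids == small_p1_structure.chain_ids
        assert list(back.res_seq) == list(small_p1_structure.res_seq)

    def test_formats_agree(self, small_p1_structure, tmp_path):
        write_model(small_p1_structure, tmp_path / "m.pdb")
        write_model(small_p1_structure, tmp_path / "m.cif")
        from_pdb = read_model(tmp_path / "m.pdb")
        from_cif = read_model(tmp_path / "m.cif")
        assert np.allclose(from_pdb.xyz_orth, from_cif.xyz_orth, atol=1e-3)
        assert from_pdb.sg.hm == from_cif.sg.hm

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "nocell.pdb"
        path.write_text(
            "ATOM      1  C1  UNK A   1       1.000   2.000   3.000"
            "  1.00 10.00           C\nEND\n")
        with pytest.raises(ValueError, match="cell"):
            read_model(path)


class TestReflectionIO:
    def test_mtz_roundtrip(self, default_fixture, tmp_path):
        rs = default_fixture.reflections_off
        path = tmp_path / "r.mtz"
        write_reflections(rs, path)
        back = read_reflections(path)
        merged = rs.df.merge(back.df, on=["H", "K", "L"])
        assert len(merged) == len(rs)
        assert np.allclose(merged["F_x"], merged["F_y"], rtol=1e-5)
        assert back.sg.hm == rs.sg.hm

    def test_sfcif_matches_mtz(self, default_fixture, tmp_path):
        rs = default_fixture.reflections_off
        write_reflections(rs, tmp_path / "r.mtz")
        write_reflections(rs, tmp_path / "r.cif")
        from_mtz = read_reflections(tmp_path / "r.mtz")
        from_cif = read_reflections(tmp_path / "r.cif")
        merged = from_mtz.df.merge(from_cif.df, on=["H", "K", "L"])
        assert len(merged) == len(rs)
        assert np.allclose(merged["F_x"], merged["F_y"], rtol=1e-4)

    def test_missing_column_lists_available(self, default_fixture, tmp_path):
        path = tmp_path / "r.mtz"
        write_reflections(default_fixture.reflections_off, path)
        with pytest.raises(KeyError, match="F"):
            read_reflections(path, columns={"F": "FOBS"})


class TestSymmetryExpansion:
    def test_p1_unchanged(self, small_p1_structure):
        from tests.conftest import reflections_from
        rs = reflections_from(small_p1_structure, d_min=3.0, sigf_frac=0)
        expanded = expand_to_p1(rs, friedel=False)
        assert len(expanded) == len(rs)

    def test_phases_match_direct_summation(self, default_fixture):
        """Expanded phases must equal direct-sum structure factors of the
        symmetry-expanded atom set, for every equivalent index."""
        st_off = default_fixture.structure_off
        hkl = default_fixture.reflections_off.hkl[:200]
        f = fcalc_direct(st_off, hkl)
        df = pd.DataFrame({"H": hkl[:, 0], "K": hkl[:, 1], "L": hkl[:, 2],
                           "F": np.abs(f),
                           "PHI": np.degrees(np.angle(f))})
        rs = ReflectionSet(df, st_off.cell, st_off.sg)
        p1 = expand_to_p1(rs)
        # build explicit P1 copy of the crystal
        from diffmapkit.structure_factors import _sym_ops
        frac, elems = [], []
        for rot, tran in _sym_ops(st_off.sg):
            frac.append(st_off.xyz_frac @ rot.T + tran)
            elems.extend(st_off.elements)
        st_p1 = Structure(elems, np.vstack(frac),
                          np.tile(st_off.b_iso, 4), np.tile(st_off.occ, 4),
                          ["A"] * (4 * len(st_off)),
                          np.arange(4 * len(st_off)) + 1,
                          st_off.cell, spacegroup("P 1"))
        f_p1 = fcalc_direct(st_p1, p1.hkl)
        f_exp = p1.df["F"].to_numpy() * np.exp(
            1j * np.radians(p1.df["PHI"].to_numpy()))
        rel = np.abs(f_p1 - f_exp) / np.maximum(np.abs(f_p1), 1e-6)
        assert rel.max() < 1e-8

    def test_amplitudes_invariant(self, default_fixture):
        rs = default_fixture.reflections_off
        expanded = expand_to_p1(rs)
        lookup = {tuple(h): v for h, v in zip(rs.hkl, rs.df["F"])}
        from diffmapkit.structure_factors import _sym_ops
        ops = _sym_ops(rs.sg)
        rng = np.random.default_rng(0)
        exp_lookup = {tuple(h): v for h, v in
                      zip(expanded.hkl, expanded.df["F"])}
        for i in rng.choice(len(rs), 50, replace=False):
            h = rs.hkl[i]
            for rot, _ in ops:
                h_new = tuple(np.rint(h @ rot).astype(int))
                assert exp_lookup[h_new] == pytest.approx(lookup[tuple(h)])

    def test_asu_reduction_preserves_structure_factors(self, default_fixture):
        """Mapping non-ASU indices to the ASU must transform phases so the
        (index, phase) pair still describes the same structure factor."""
        st_off = default_fixture.structure_off
        asu_hkl = default_fixture.reflections_off.hkl[:50]
        from diffmapkit.structure_factors import _sym_ops
        rot, tran = _sym_ops(st_off.sg)[2]
        moved = np.rint(asu_hkl @ rot).astype(int)
        f_moved = fcalc_direct(st_off, moved)
        df = pd.DataFrame({"H": moved[:, 0], "K": moved[:, 1],
                           "L": moved[:, 2], "F": np.abs(f_moved),
                           "PHI": np.degrees(np.angle(f_moved))})
        reduced = map_to_asu(ReflectionSet(df, st_off.cell, st_off.sg))
        f_asu = fcalc_direct(st_off, reduced.hkl)
        phi_expected = np.degrees(np.angle(f_asu))
        dphi = (reduced.df["PHI"].to_numpy() - phi_expected + 180) % 360 - 180
        assert np.abs(dphi).max() < 1e-6
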