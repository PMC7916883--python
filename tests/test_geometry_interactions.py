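"""SASA, close contacts and hydrogen bonds against analytic and brute-force oracles."""

import numpy as np
import pytest

from mdcompare.geometry_interactions import (
    GeometryConfig,
    assign_donors_acceptors,
    close_contacts,
    hydrogen_bonds,
    radii_for,
    sasa,
    trajectory_geometry_summary,
)
from mdcompare.structure_io import Structure
from mdcompare.synthetic_data import add_point_solvent, toy_dimer

from conftest import make_trajectory


def _struct(names, elements, coords, resnames=None, resnums=None, chains=None):
    n = len(names)
    return Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames or ["ALA"] * n, dtype=object),
        resnums=np.array(resnums or list(range(1, n + 1)), dtype=int),
        icodes=np.array([""] * n, dtype=object),
        chain_ids=np.array(chains or ["A"] * n, dtype=object),
        occupancies=np.ones(n),
        coords=np.array(coords, dtype=float),
        is_hetatm=np.zeros(n, dtype=bool),
    )


class TestSASA:
    def test_isolated_sphere_matches_analytic_area(self):
        total, _ = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4)
        analytic = 4 * np.pi * 3.0**2  # 113.097 A^2
        assert total == pytest.approx(analytic, rel=0.005)
        assert total == pytest.approx(113.10, abs=0.5)

    def test_distant_atoms_are_additive(self):
        single, _ = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4)
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        double, per_atom = sasa(coords, np.array([1.6, 1.6]), probe=1.4)
        assert double == pytest.approx(2 * single, rel=1e-12)
        assert double == pytest.approx(per_atom.sum(), rel=1e-12)

    def test_two_intersecting_spheres_match_closed_form(self):
        # equal extended radii R = 1.6 + 1.4 = 3.0, centers 3.0 A apart:
        # each sphere loses a cap of height h = R - d/2
        R, d = 3.0, 3.0
        h = R - d / 2
        expected_per_sphere = 4 * np.pi * R**2 - 2 * np.pi * R * h
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        total, per_atom = sasa(coords, np.array([1.6, 1.6]), probe=1.4)
        np.testing.assert_allclose(per_atom, expected_per_sphere, rtol=0.01)

    def test_buried_atom_has_zero_area(self):
        # small atom fully inside a big one
        coords = np.zeros((2, 3))
        _, per_atom = sasa(coords, np.array([0.5, 3.0]), probe=1.4)
        assert per_atom[0] == 0.0

    def test_unknown_element_listed(self):
        s = _struct(["X1"], ["XX"], [[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="XX"):
            radii_for(s)

    def test_matches_independent_shrake_rupley_implementation(self):
        # cross-check against the Shrake-Rupley implementation shipped with
        # Bio.PDB on the same radii, probe and point count
        import io as _io

        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from mdcompare.structure_io import write_structure

        dimer = toy_dimer(4)
        radii = radii_for(dimer)
        mine, _ = sasa(dimer.coords, radii, probe=1.4, n_points=960)

        bio = PDBParser(QUIET=True).get_structure(
            "t", _io.StringIO(write_structure(dimer)))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52})
        sr.compute(bio, level="S")
        theirs = float(bio.sasa)
        assert mine == pytest.approx(theirs, rel=0.02)


def _contact_oracle(coords, sel_a, sel_b, cutoff):
    pairs = set()
    for i in sel_a:
        for j in sel_b:
            if i != j and np.linalg.norm(coords[i] - coords[j]) < cutoff:
                pairs.add((min(i, j), max(i, j)))
    return len(pairs)


class TestCloseContacts:
    def test_pair_within_cutoff_counts_once(self):
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        assert close_contacts(coords, [0, 1], [0, 1], 6.0) == 1

    def test_pair_exactly_at_cutoff_excluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        assert close_contacts(coords, [0, 1], [0, 1], 6.0) == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_intra_mode_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = 10.0 * rng.random((100, 3))
        all_idx = np.arange(100)
        count = close_contacts(coords, all_idx, all_idx, 6.0)
        assert count == _contact_oracle(coords, all_idx, all_idx, 6.0)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_inter_group_mode_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = 8.0 * rng.random((80, 3))
        a, b = np.arange(40), np.arange(40, 80)
        count, pairs = close_contacts(coords, a, b, 6.0, return_pairs=True)
        assert count == _contact_oracle(coords, a, b, 6.0)
        assert len(pairs) == count

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            close_contacts(np.zeros((2, 3)), [], [0], 6.0)


class TestHydrogenBonds:
    def _dha_frame(self, acceptor_pos):
        # donor N at origin, its H along +x, acceptor carbonyl O elsewhere
        return _struct(
            ["N", "H", "C", "O"], ["N", "H", "C", "O"],
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], list(np.add(acceptor_pos, [0, 0, 1.3])),
             list(acceptor_pos)],
            resnums=[1, 1, 2, 2],
        )

    def test_collinear_bond_at_3p4_counted(self):
        s = self._dha_frame([3.4, 0.0, 0.0])
        table = assign_donors_acceptors(s)
        assert hydrogen_bonds(s.coords, table, s) == 1

    def test_distance_criterion_is_strict(self):
        s = self._dha_frame([3.6, 0.0, 0.0])  # perfect angle, too far
        table = assign_donors_acceptors(s)
        assert hydrogen_bonds(s.coords, table, s) == 0
        s_exact = self._dha_frame([3.5, 0.0, 0.0])  # exactly at cutoff
        table = assign_donors_acceptors(s_exact)
        assert hydrogen_bonds(s_exact.coords, table, s_exact) == 0

    def _acceptor_at(self, angle_deg: float, d_a: float) -> np.ndarray:
        """Acceptor position giving the requested D-H-A angle and D-A distance."""
        # direction of H->A making angle_deg with H->D = (-1, 0, 0)
        theta = np.deg2rad(180.0 - angle_deg)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        b = 2.0 * u[0]  # from |H + L u|^2 = 1 + b L + L^2
        L = (-b + np.sqrt(b**2 + 4.0 * (d_a**2 - 1.0))) / 2.0
        acceptor = np.array([1.0, 0.0, 0.0]) + L * u
        assert np.linalg.norm(acceptor) == pytest.approx(d_a, abs=1e-9)
        return acceptor

    def test_angle_criterion_rejects_110_degrees(self):
        # D-A = 3.0 A but the D-H-A angle is 110 deg < 120 deg
        s = self._dha_frame(list(self._acceptor_at(110.0, 3.0)))
        table = assign_donors_acceptors(s)
        assert hydrogen_bonds(s.coords, table, s) == 0

    @pytest.mark.parametrize("angle,expected", [(119.9, 0), (120.1, 1)])
    def test_angle_cutoff_is_sharp_at_120(self, angle, expected):
        s = self._dha_frame(list(self._acceptor_at(angle, 3.2)))
        table = assign_donors_acceptors(s)
        assert hydrogen_bonds(s.coords, table, s) == expected

    def test_donor_without_hydrogen_skipped(self):
        s = _struct(["N", "O"], ["N", "O"],
                    [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]], resnums=[1, 2])
        table = assign_donors_acceptors(s)
        assert table.donors == ()
        assert 0 in table.skipped_donors
        assert hydrogen_bonds(s.coords, table, s) == 0

    def test_count_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        dimer = toy_dimer(6)
        table = assign_donors_acceptors(dimer)
        base = hydrogen_bonds(dimer.coords, table, dimer)
        R = Rotation.random(random_state=4).as_matrix()
        moved = dimer.coords @ R.T + np.array([10.0, -3.0, 7.0])
        assert hydrogen_bonds(moved, table, dimer) == base
        assert base >= 1  # the toy interface donates by construction

    def test_protein_solvent_mode_counts_water_bonds(self):
        s = _struct(["N", "H"], ["N", "H"],
                    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], resnums=[1, 1])
        solvated = add_point_solvent(s, 0, seed=0)
        # place one water O collinear with the amide by hand
        water = _struct(["OW", "HW1", "HW2"], ["O", "H", "H"],
                        [[3.0, 0.0, 0.0], [3.96, 0.0, 0.0], [2.76, 0.93, 0.0]],
                        resnames=["HOH"] * 3, resnums=[90] * 3, chains=["W"] * 3)
        combined = Structure(
            names=np.concatenate([s.names, water.names]),
            elements=np.concatenate([s.elements, water.elements]),
            resnames=np.concatenate([s.resnames, water.resnames]),
            resnums=np.concatenate([s.resnums, water.resnums]),
            icodes=np.concatenate([s.icodes, water.icodes]),
            chain_ids=np.concatenate([s.chain_ids, water.chain_ids]),
            occupancies=np.concatenate([s.occupancies, water.occupancies]),
            coords=np.vstack([s.coords, water.coords]),
            is_hetatm=np.array([False, False, True, True, True]),
        )
        table = assign_donors_acceptors(combined)
        n = hydrogen_bonds(combined.coords, table, combined, "protein-solvent")
        assert n >= 1
        assert hydrogen_bonds(combined.coords, table, combined,
                              "protein-protein") == 0


class TestTrajectorySummary:
    def test_static_trajectory_has_zero_sds(self):
        dimer = toy_dimer(4)
        coords = np.repeat(dimer.coords[None] / 10.0, 3, axis=0)
        traj = make_trajectory(coords, dimer)
        summary = trajectory_geometry_summary(traj)
        np.testing.assert_allclose(summary["sd"], 0.0, atol=1e-9)

    def test_two_frame_mean_and_sd_match_hand_arithmetic(self):
        dimer = toy_dimer(4)
        frame2 = dimer.coords.copy()
        frame2[:, 0] += 0.8  # uniform shift: SASA/NHB unchanged, Rg unchanged
        coords = np.stack([dimer.coords, frame2]) / 10.0
        traj = make_trajectory(coords, dimer)
        summary, per_frame = trajectory_geometry_summary(traj, per_frame=True)
        for p in ("sasa_A2", "ncic", "rg_A", "nhb_intra"):
            v1, v2 = per_frame[p].to_numpy()
            row = summary[summary.parameter == p].iloc[0]
            assert row["mean"] == pytest.approx((v1 + v2) / 2.0)
            assert row["sd"] == pytest.approx(abs(v1 - v2) / 2.0)

    def test_no_solvent_flagged_and_zero(self):
        dimer = toy_dimer(3)
        traj = make_trajectory(dimer.coords[None] / 10.0, dimer)
        summary = trajectory_geometry_summary(traj)
        assert summary.attrs["solvent_present"] is False
        row = summary[summary.parameter == "nhb_protein_solvent"].iloc[0]
        assert row["mean"] == 0.0
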