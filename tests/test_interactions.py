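import numpy as np
import pytest

from mptraj.interactions import (
    classify_helical,
    enumerate_possible_salt_bridges,
    find_hbonds,
    hbond_incidence,
    salt_bridge_incidence,
)
from mptraj.synthetic_ensemble import (
    EnsembleSpec,
    SegmentSpec,
    build_backbone,
    generate_ensemble,
)
from mptraj.traj_model import Frame, Trajectory

from conftest import AB16, AB40, AB42, random_rigid
from oracles import salt_bridge_recount


def _posed_donor_frame(on_distance):
    """Four-residue frame with N(4)-H aimed straight at O(1).

    Residues 3+4 are translated rigidly (so the amide H of residue 4, built
    from residue 3's carbonyl, keeps its direction) such that N(4) sits on
    the line through its own H toward O(1) at the requested heavy-atom
    distance, giving a 180-degree D-H-A angle.
    """
    top, frame = build_backbone("AAAA", np.tile([-139.0, 135.0], (4, 1)))
    coords = frame.coords.copy()
    o1 = top.atom_index(1, "O")
    c3 = top.atom_index(3, "C")
    o3 = top.atom_index(3, "O")
    n4 = top.atom_index(4, "N")
    w = coords[c3] - coords[o3]          # amide-H direction of residue 4
    w /= np.linalg.norm(w)
    target_n4 = coords[o1] - w * on_distance
    shift = target_n4 - coords[n4]
    tail = [a.index for a in top.atoms if a.residue_index >= 3]
    coords[tail] += shift
    return top, Frame(coords), o1, n4


class TestFindHBonds:
    def test_close_linear_bond_detected(self):
        top, frame, o1, n4 = _posed_donor_frame(2.9)
        bonds = find_hbonds(frame, top)
        pairs = {(b.donor_atom, b.acceptor_atom) for b in bonds}
        assert (n4, o1) in pairs

    def test_long_contact_rejected_by_distance(self):
        top, frame, o1, n4 = _posed_donor_frame(3.6)
        bonds = find_hbonds(frame, top, dist_cutoff_A=3.0)
        assert not any(b.donor_atom == n4 and b.acceptor_atom == o1
                       for b in bonds)

    def test_rigid_motion_invariance(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=1, seed=17,
                            segments=[SegmentSpec(1, 16, "alpha")])
        traj = generate_ensemble(spec)
        frame = traj.frame(0)
        rng = np.random.default_rng(9)
        rot, t = random_rigid(rng)
        moved = Frame(frame.coords @ rot.T + t)
        a = [(b.donor_atom, b.acceptor_atom) for b in
             find_hbonds(frame, traj.topology)]
        b = [(b.donor_atom, b.acceptor_atom) for b in
             find_hbonds(moved, traj.topology)]
        assert a == b

    def test_helical_class_only_for_backbone_pairs(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=2, seed=18,
                            segments=[SegmentSpec(1, 16, "alpha")],
                            dihedral_noise_deg=6.0)
        traj = generate_ensemble(spec)
        for f in range(traj.n_frames):
            for b in find_hbonds(traj.frame(f), traj.topology):
                if b.helical_class != "other":
                    assert b.kind == "backbone-backbone"
                    assert b.donor_res - b.acceptor_res in (3, 4, 5)


class TestIncidence:
    def test_alpha_fixture_i4_bonds_at_full_incidence(self):
        spec = EnsembleSpec(sequence="A" * 12, n_frames=5, seed=0,
                            segments=[SegmentSpec(1, 12, "alpha")],
                            dihedral_noise_deg=0.0)
        traj = generate_ensemble(spec)
        inc = hbond_incidence(traj)
        i4 = inc.table[inc.table["helical_class"] == "i+4"]
        assert len(i4) >= 6
        np.testing.assert_allclose(i4["incidence_pct"].values, 100.0)

    def test_extended_coil_has_zero_bonds(self):
        top, frame = build_backbone("A" * 10, np.tile([-139.0, 135.0], (10, 1)))
        traj = Trajectory(top, np.repeat(frame.coords[None], 3, axis=0))
        inc = hbond_incidence(traj)
        assert inc.n_distinct == 0
        assert (inc.count_stats.ave, inc.count_stats.sd,
                inc.count_stats.min, inc.count_stats.max) == (0, 0, 0, 0)

    def test_per_frame_counts_match_find_hbonds(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=6, seed=4,
                            segments=[SegmentSpec(9, 16, "alpha")],
                            dihedral_noise_deg=10.0)
        traj = generate_ensemble(spec)
        inc = hbond_incidence(traj)
        for f in range(traj.n_frames):
            assert inc.per_frame_counts[f] == len(
                find_hbonds(traj.frame(f), traj.topology))

    def test_incidence_bounded_and_atom_level_at_least_as_many(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=6, seed=4,
                            dihedral_noise_deg=15.0)
        traj = generate_ensemble(spec)
        merged = hbond_incidence(traj)
        atoms = hbond_incidence(traj, atom_level=True)
        assert ((merged.table["incidence_pct"] >= 0)
                & (merged.table["incidence_pct"] <= 100)).all()
        assert atoms.n_distinct >= merged.n_distinct


class TestHelicalClasses:
    def test_alpha_dominated_by_i4(self):
        spec = EnsembleSpec(sequence="A" * 12, n_frames=5, seed=0,
                            segments=[SegmentSpec(1, 12, "alpha")],
                            dihedral_noise_deg=0.0)
        tally = classify_helical(hbond_incidence(generate_ensemble(spec)))
        assert tally["i+4"]["total"] > tally["i+3"]["total"]
        assert tally["i+4"]["total"] > tally["i+5"]["total"]
        assert tally["i+4"]["ge_5pct"] == tally["i+4"]["total"]

    def test_three10_dominated_by_i3(self):
        spec = EnsembleSpec(sequence="A" * 12, n_frames=5, seed=0,
                            segments=[SegmentSpec(1, 12, "three10")],
                            dihedral_noise_deg=0.0)
        tally = classify_helical(hbond_incidence(generate_ensemble(spec)))
        assert tally["i+3"]["total"] > tally["i+4"]["total"]
        assert tally["i+3"]["total"] > tally["i+5"]["total"]

    def test_empty_input_all_zero(self):
        top, frame = build_backbone("A" * 10, np.tile([-139.0, 135.0], (10, 1)))
        traj = Trajectory(top, frame.coords[None])
        tally = classify_helical(hbond_incidence(traj))
        assert all(v["total"] == 0 for v in tally.values())


class TestSaltBridges:
    @pytest.mark.parametrize("sequence,expected", [
        (AB16, 8),      # 4 acidic x 2 basic
        (AB40, 18),     # 6 acidic x 3 basic
        (AB42, 18),
        ("A" * 10, 0),
    ])
    def test_possible_pair_counts(self, sequence, expected):
        top, _ = build_backbone(sequence,
                                np.tile([-70.0, 150.0], (len(sequence), 1)))
        assert len(enumerate_possible_salt_bridges(top)) == expected

    def _posed_pair(self, on_distance):
        """Asp1...Lys4 with the closest O-N pair at the requested distance."""
        top, frame = build_backbone("DAAK", np.tile([-139.0, 135.0], (4, 1)))
        coords = frame.coords.copy()
        od1 = top.atom_index(1, "OD1")
        nz = top.atom_index(4, "NZ")
        direction = coords[nz] - coords[od1]
        direction /= np.linalg.norm(direction)
        shift = (coords[od1] + direction * on_distance) - coords[nz]
        coords[nz] += shift
        # verify the moved NZ is the unique closest O-N contact
        return top, Frame(coords)

    def test_contact_just_inside_cutoff_is_full_incidence(self):
        top, frame = self._posed_pair(3.19)
        traj = Trajectory(top, np.repeat(frame.coords[None], 3, axis=0))
        table = salt_bridge_incidence(traj)
        assert table["incidence_pct"].iloc[0] == 100.0

    def test_contact_at_cutoff_is_excluded(self):
        # the comparison is strictly "less than"; a hair above never counts
        top, frame = self._posed_pair(3.2 + 1e-9)
        traj = Trajectory(top, np.repeat(frame.coords[None], 3, axis=0))
        table = salt_bridge_incidence(traj)
        assert table["incidence_pct"].iloc[0] == 0.0

    def test_randomized_frames_match_bruteforce_recount(self):
        rng = np.random.default_rng(12)
        spec = EnsembleSpec(sequence=AB16, n_frames=8, seed=19,
                            dihedral_noise_deg=25.0)
        traj = generate_ensemble(spec)
        # compress the structures so contacts actually occur
        squeezed = traj.coords * 0.45
        traj = Trajectory(traj.topology, squeezed, traj.dt_ns)
        table = salt_bridge_incidence(traj)
        recount = salt_bridge_recount(traj)
        assert any(v > 0 for v in recount.values())
        for _, row in table.iterrows():
            assert row["incidence_pct"] == pytest.approx(
                recount[(row["acidic_res"], row["basic_res"])])
        del rng

    def test_incidence_monotone_in_cutoff(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=8, seed=19,
                            dihedral_noise_deg=25.0)
        traj = generate_ensemble(spec)
        traj = Trajectory(traj.topology, traj.coords * 0.45, traj.dt_ns)
        t32 = salt_bridge_incidence(traj, 3.2)
        t40 = salt_bridge_incidence(traj, 4.0)
        assert (t40["incidence_pct"].values
                >= t32["incidence_pct"].values).all()
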