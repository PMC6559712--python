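import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mptraj.geometry import (
    DegenerateGeometryError,
    SeriesStats,
    dihedral,
    kabsch_superpose,
    radius_of_gyration,
    ramachandran_histogram,
    rmsd_series,
    rmsf_per_residue,
)
from mptraj.synthetic_ensemble import EnsembleSpec, SegmentSpec, build_backbone, generate_ensemble
from mptraj.traj_model import Frame, Trajectory

from conftest import AB16, random_cloud, random_rigid
from oracles import quaternion_rmsd


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        x = random_cloud(rng)
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = random_cloud(rng, n=8)
        theta = np.deg2rad(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        mobile = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.apply(mobile), ref, atol=1e-9)

    def test_matches_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = random_cloud(rng, n=6)
            b = random_cloud(rng, n=6)
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-8)

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(3)
        a = random_cloud(rng)
        b = random_cloud(rng)
        r1 = kabsch_superpose(a, b).rmsd
        assert kabsch_superpose(b, a).rmsd == pytest.approx(r1, abs=1e-10)
        rot, t = random_rigid(rng)
        assert kabsch_superpose(a @ rot.T + t, b).rmsd == pytest.approx(r1, abs=1e-9)

    def test_reported_rmsd_is_attained_by_transform(self):
        rng = np.random.default_rng(4)
        a, b = random_cloud(rng), random_cloud(rng)
        res = kabsch_superpose(a, b)
        attained = np.sqrt(((res.apply(a) - b) ** 2).sum() / len(a))
        assert attained == pytest.approx(res.rmsd, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("bad", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(bad, bad + 1.0)


class TestRmsdSeries:
    def test_noise_free_ensemble_is_zero(self, alpha_ensemble):
        sel = alpha_ensemble.topology.select("backbone")
        series = rmsd_series(alpha_ensemble, 0, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_single_displaced_atom_formula(self, alpha12):
        top, frame = alpha12
        sel = np.array(top.select("backbone"))
        moved = frame.coords.copy()
        moved[sel[0]] += np.array([1.0, 0.0, 0.0])
        traj = Trajectory(top, np.stack([frame.coords, moved]))
        series = rmsd_series(traj, 0, sel)
        # superposition can only lower the residual below the direct 1/sqrt(N)
        assert series.values[1] <= 1.0 / np.sqrt(len(sel)) + 1e-12
        assert series.values[1] > 0.5 / np.sqrt(len(sel))

    def test_empty_selection_rejected(self, alpha_ensemble):
        with pytest.raises(ValueError):
            rmsd_series(alpha_ensemble, 0, [])

    def test_drifted_series_approaches_plateau_monotonically(self, drifted_ensemble):
        sel = drifted_ensemble.topology.select("backbone")
        series = rmsd_series(drifted_ensemble, 0, sel)
        t = np.asarray(series.index)
        means = np.array([series.values[(t >= lo) & (t < lo + 5.0)].mean()
                          for lo in np.arange(0.0, 20.0, 5.0)])
        final = series.values[t >= 20.0].mean()
        deviations = np.abs(means - final)
        # approach to the plateau: deviations shrink (small slack for the
        # high-noise saturation at the start) and end well below the start
        assert np.all(np.diff(deviations) < 0.05)
        assert deviations[-1] < 0.3 * deviations[0]
        plateau = np.array([series.values[(t >= lo) & (t < lo + 5.0)].mean()
                            for lo in np.arange(20.0, 45.0, 5.0)])
        assert np.all(np.abs(plateau - final) < 0.2)


class TestRmsf:
    def test_identical_frames_zero(self, alpha_ensemble):
        rmsf = rmsf_per_residue(alpha_ensemble)
        np.testing.assert_allclose(rmsf.values, 0.0, atol=1e-10)

    def test_alternating_atom_closed_form(self, alpha12):
        top, frame = alpha12
        d = 0.8
        up = frame.coords.copy()
        down = frame.coords.copy()
        ca0 = top.atom_index(1, "CA")
        up[ca0, 2] += d / 2
        down[ca0, 2] -= d / 2
        traj = Trajectory(top, np.stack([up, down]))
        rmsf = rmsf_per_residue(traj, indices=[ca0], align_to="none")
        assert rmsf.iloc[0] == pytest.approx(d / 2, abs=1e-12)

    def test_single_frame_rejected(self, alpha12):
        top, frame = alpha12
        with pytest.raises(ValueError):
            rmsf_per_residue(Trajectory(top, frame.coords[None]))

    def test_noisier_segment_has_larger_rmsf(self):
        # helical N-terminal half held at low dihedral noise while the
        # C-terminal half is coil-sampled, which has far larger variance
        mixed = EnsembleSpec(sequence=AB16, n_frames=60, dt_ns=0.1, seed=9,
                             segments=[SegmentSpec(1, 8, "alpha")],
                             dihedral_noise_deg=5.0)
        traj = generate_ensemble(mixed)
        rmsf = rmsf_per_residue(traj)
        assert rmsf.iloc[8:].mean() > rmsf.iloc[:8].mean()


class TestRg:
    def test_single_atom_zero(self, alpha12):
        top, frame = alpha12
        assert radius_of_gyration(frame, top, [0]) == 0.0

    def test_two_equal_masses_two_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        rg = radius_of_gyration(Frame(coords), mass_weighted=False)
        assert rg == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_sum(self, ab16_topology):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 5, size=(ab16_topology.n_atoms, 3))
        masses = ab16_topology.masses()
        com = (coords * masses[:, None]).sum(0) / masses.sum()
        direct = np.sqrt(sum(m * ((x - com) ** 2).sum()
                             for m, x in zip(masses, coords)) / masses.sum())
        rg = radius_of_gyration(Frame(coords), ab16_topology)
        assert rg == pytest.approx(direct, abs=1e-10)

    def test_rigid_invariance_and_scaling(self, ab16_topology):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 5, size=(ab16_topology.n_atoms, 3))
        rg = radius_of_gyration(Frame(coords), ab16_topology)
        rot, t = random_rigid(rng)
        assert radius_of_gyration(Frame(coords @ rot.T + t), ab16_topology) == \
            pytest.approx(rg, abs=1e-10)
        assert radius_of_gyration(Frame(coords * 2.0), ab16_topology) == \
            pytest.approx(2.0 * rg, abs=1e-10)


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == \
            pytest.approx(0.0, abs=1e-10)

    def test_trans_is_plus_180(self):
        ang = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert ang == pytest.approx(180.0, abs=1e-10)

    def test_reference_minus_ninety(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == \
            pytest.approx(-90.0, abs=1e-10)

    def test_reversal_symmetry_and_mirror_antisymmetry(self):
        # IUPAC torsions are invariant under atom-order reversal and
        # negated by a mirror reflection
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.normal(0, 3, size=(4, 3))
            a = dihedral(*p)
            assert dihedral(*p[::-1]) == pytest.approx(a, abs=1e-9)
            mirrored = p * np.array([1.0, 1.0, -1.0])
            b = dihedral(*mirrored)
            if abs(abs(a) - 180.0) < 1e-9:
                assert abs(b) == pytest.approx(180.0, abs=1e-9)
            else:
                assert b == pytest.approx(-a, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


class TestRamachandran:
    def test_noise_free_alpha_mass_in_single_bin(self, alpha_ensemble):
        counts, edges = ramachandran_histogram(alpha_ensemble, 10.0)
        total = (alpha_ensemble.topology.n_residues - 2) * alpha_ensemble.n_frames
        assert counts.sum() == total
        i = np.searchsorted(edges, -57.0) - 1
        j = np.searchsorted(edges, -47.0) - 1
        assert counts[i, j] == total

    def test_histogram_mass_conserved_on_noisy_ensemble(self):
        spec = EnsembleSpec(sequence=AB16, n_frames=15, seed=3,
                            dihedral_noise_deg=25.0)
        traj = generate_ensemble(spec)
        counts, _ = ramachandran_histogram(traj, 10.0)
        assert counts.sum() == (16 - 2) * 15

    def test_mixed_spec_bins_proportional_to_segment_lengths(self):
        spec = EnsembleSpec(
            sequence="A" * 16,
            segments=[SegmentSpec(1, 8, "alpha"), SegmentSpec(9, 16, "strand")],
            dihedral_noise_deg=0.0, n_frames=4, seed=0)
        traj = generate_ensemble(spec)
        counts, edges = ramachandran_histogram(traj, 10.0)
        occupied = np.argwhere(counts > 0)
        assert len(occupied) == 2
        values = sorted(counts[tuple(ij)] for ij in occupied)
        # interior residues: 7 alpha (2..8), 7 strand (9..15)
        assert values == [7 * 4, 7 * 4]

    def test_bad_bin_width_rejected(self, alpha_ensemble):
        with pytest.raises(ValueError):
            ramachandran_histogram(alpha_ensemble, 7.0)


class TestRgProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(coords=arrays(np.float64, (12, 3),
                         elements=st.floats(-50.0, 50.0)),
           scale=st.floats(0.1, 10.0))
    def test_rigid_invariance_and_linear_scaling(self, coords, scale):
        frame = Frame(coords)
        rg = radius_of_gyration(frame, mass_weighted=False)
        shifted = Frame(coords + np.array([3.0, -7.0, 11.0]))
        assert radius_of_gyration(shifted, mass_weighted=False) == \
            pytest.approx(rg, abs=1e-8)
        scaled = Frame(coords * scale)
        assert radius_of_gyration(scaled, mass_weighted=False) == \
            pytest.approx(scale * rg, rel=1e-9, abs=1e-8)


class TestSeriesStats:
    def test_population_sd_and_ordering(self):
        s = SeriesStats.from_values([1.0, 2.0, 3.0, 4.0])
        assert s.ave == pytest.approx(2.5)
        assert s.sd == pytest.approx(np.sqrt(1.25))
        assert s.min <= s.ave <= s.max
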