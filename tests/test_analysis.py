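"""Trajectory statistics: distances, RMSD, dihedrals, KDEs, native contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ecph.analysis import (
    backbone_rmsd_distribution,
    chi_dihedral_histogram,
    dihedral_angles,
    hbond_distance_density,
    intersubunit_ca_distance,
    min_sidechain_distance,
    native_contacts_fraction,
    summarize_distribution,
)
from ecph.errors import (
    NoContactsError,
    NoDihedralError,
    NoSidechainError,
    SelectionError,
)
from ecph.fixtures import make_titratable_peptide, make_two_state_trajectory
from ecph.structure import Structure, TrajectoryEnsemble


def _two_chain_traj(dist=95.0, n_frames=2):
    top = Structure(
        ["A", "A", "A", "B", "B", "B"],
        [373, 373, 373, 373, 373, 373],
        ["MET"] * 6,
        ["N", "CA", "C", "N", "CA", "C"],
        ["N", "C", "C", "N", "C", "C"],
        [[-1.4, 0, 0], [0, 0, 0], [1.2, 0.8, 0],
         [dist - 1.4, 2, 0], [dist, 0, 0], [dist + 1.2, 0.8, 0]],
    )
    frames = np.repeat(top.coords[None], n_frames, axis=0)
    return TrajectoryEnsemble(top, frames)


def _rigid_transform(frames, seed=0):
    rng = np.random.default_rng(seed)
    out = np.empty_like(frames)
    for f in range(len(frames)):
        rot = Rotation.random(random_state=rng)
        shift = rng.uniform(-20, 20, 3)
        out[f] = rot.apply(frames[f]) + shift
    return out


class TestIntersubunitDistance:
    def test_static_geometry(self):
        traj = _two_chain_traj(dist=95.0)
        summary = intersubunit_ca_distance(traj, (373, "MET"), "A", "B")
        np.testing.assert_allclose(summary.values, 95.0)
        assert summary.median == pytest.approx(95.0)

    def test_same_chain_rejected(self):
        traj = _two_chain_traj()
        with pytest.raises(SelectionError):
            intersubunit_ca_distance(traj, (373, "MET"), "A", "A")

    def test_missing_atom_names_selection(self):
        traj = _two_chain_traj()
        with pytest.raises(SelectionError, match="999"):
            intersubunit_ca_distance(traj, (999, "MET"), "A", "B")

    def test_rotation_translation_invariant(self):
        traj = _two_chain_traj(dist=95.0, n_frames=5)
        moved = TrajectoryEnsemble(traj.topology, _rigid_transform(traj.frames))
        a = intersubunit_ca_distance(traj, (373, "MET"), "A", "B").values
        b = intersubunit_ca_distance(moved, (373, "MET"), "A", "B").values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_planted_two_state_shift_recovered(self):
        """Difference of ensemble means between two pH-labelled swarms
        recovers the planted shift within 3 standard errors."""
        shift = 3.0
        lo = make_two_state_trajectory(400, shift, (1.0, 0.0), seed=21, noise_sigma=0.2)
        hi = make_two_state_trajectory(400, shift, (0.0, 1.0), seed=22, noise_sigma=0.2)
        d_lo = intersubunit_ca_distance(lo, (1, "ALA"), "A", "B")
        d_hi = intersubunit_ca_distance(hi, (1, "ALA"), "A", "B")
        delta = d_hi.mean - d_lo.mean
        se = np.hypot(
            d_lo.values.std() / np.sqrt(len(d_lo.values)),
            d_hi.values.std() / np.sqrt(len(d_hi.values)),
        )
        assert abs(delta - shift) <= 3 * se

    def test_bimodal_mixture_mean(self):
        traj = make_two_state_trajectory(
            4000, 3.0, (0.5, 0.5), seed=5, base_distance=95.0, noise_sigma=0.1
        )
        summary = intersubunit_ca_distance(traj, (1, "ALA"), "A", "B")
        assert summary.mean == pytest.approx(96.5, abs=0.1)


class TestBackboneRmsd:
    def test_identity_trajectory_zero(self):
        traj = _two_chain_traj(n_frames=4)
        summary = backbone_rmsd_distribution(traj, traj.frames[0])
        np.testing.assert_allclose(summary.values, 0.0, atol=1e-10)

    def test_rigid_motion_removed_by_superposition(self):
        traj = _two_chain_traj(n_frames=6)
        moved = TrajectoryEnsemble(traj.topology, _rigid_transform(traj.frames, seed=4))
        summary = backbone_rmsd_distribution(moved, traj.frames[0])
        np.testing.assert_allclose(summary.values, 0.0, atol=1e-10)

    def test_uniform_displacement_of_decoupled_selection(self):
        """A 1 Å displacement applied to a residue range disjoint from any
        anchored atoms shows up as exactly 1 Å RMSD before alignment; with
        the selection aligned on itself a rigid +x shift still cancels, so
        displace half the selection instead and verify the analytic RMSD."""
        top = Structure(
            ["A"] * 8, np.repeat([1, 2], 4), ["ALA"] * 8,
            ["N", "CA", "C", "O"] * 2, ["N", "C", "C", "O"] * 2,
            np.array([
                [0, 0, 0], [1.4, 0.2, 0], [2.4, 1.2, 0.3], [2.2, 2.4, 0.4],
                [4.0, 0.9, 0], [5.4, 1.1, 0.2], [6.4, 2.1, 0.5], [6.2, 3.3, 0.6],
            ]),
        )
        ref = top.coords.copy()
        frame = ref.copy()
        frame[4:] += [1.0, 0.0, 0.0]  # displace residue 2 only
        traj = TrajectoryEnsemble(top, frame[None])
        # align on residue 1 only, measure over residue 1: zero
        anchored = backbone_rmsd_distribution(traj, ref, residue_range=(1, 1))
        assert anchored.values[0] == pytest.approx(0.0, abs=1e-10)
        # a frame globally shifted by 1 Å has zero RMSD after superposition
        shifted = TrajectoryEnsemble(top, (ref + [1.0, 0, 0])[None])
        assert backbone_rmsd_distribution(shifted, ref).values[0] == pytest.approx(
            0.0, abs=1e-10
        )

    def test_too_few_atoms_rejected(self):
        traj = _two_chain_traj()
        with pytest.raises(Exception):
            backbone_rmsd_distribution(traj, traj.frames[0], atom_names=("CA",),
                                       chains=["A"])


class TestDihedrals:
    def test_planar_zigzag_is_trans(self):
        p0 = np.array([[0.0, 1.0, 0.0]])
        p1 = np.array([[0.0, 0.0, 0.0]])
        p2 = np.array([[1.5, 0.0, 0.0]])
        p3 = np.array([[1.5, 1.0, 0.0]])  # cis arrangement → 0°
        assert dihedral_angles(p0, p1, p2, p3)[0] == pytest.approx(0.0, abs=1e-10)
        p3_trans = np.array([[1.5, -1.0, 0.0]])
        assert abs(dihedral_angles(p0, p1, p2, p3_trans)[0]) == pytest.approx(
            180.0, abs=1e-10
        )

    def test_right_handed_sign_convention(self):
        p0 = np.array([[0.0, 1.0, 0.0]])
        p1 = np.array([[0.0, 0.0, 0.0]])
        p2 = np.array([[1.5, 0.0, 0.0]])
        p3 = np.array([[1.5, 0.0, 1.0]])
        assert dihedral_angles(p0, p1, p2, p3)[0] == pytest.approx(-90.0, abs=1e-9)

    def test_chi_histogram_normalized_and_rotation_invariant(self):
        structure, _ = make_titratable_peptide("GLU", capped=False, seed=2)
        frames = np.repeat(structure.coords[None], 10, axis=0)
        traj = TrajectoryEnsemble(structure, frames)
        hist = chi_dihedral_histogram(traj, "A", 1)
        assert hist.probability.sum() == pytest.approx(1.0, abs=1e-12)
        moved = TrajectoryEnsemble(structure, _rigid_transform(frames, seed=9))
        hist2 = chi_dihedral_histogram(moved, "A", 1)
        np.testing.assert_allclose(hist.chi1, hist2.chi1, atol=1e-8)
        np.testing.assert_allclose(hist.chi2, hist2.chi2, atol=1e-8)

    def test_residue_without_chi2_rejected(self):
        structure, _ = make_titratable_peptide("CYS", capped=False, seed=2)
        traj = TrajectoryEnsemble(structure, structure.coords[None])
        with pytest.raises(NoDihedralError):
            chi_dihedral_histogram(traj, "A", 1)


class TestHbondDensity:
    def test_constant_distance_peaks_at_value(self):
        top = Structure(["A", "A"], [70, 66], ["HIS", "GLY"], ["ND1", "O"],
                        ["N", "O"], [[0, 0, 0], [2.8, 0, 0]])
        traj = TrajectoryEnsemble(top, np.repeat(top.coords[None], 20, axis=0))
        summary = hbond_distance_density(traj, ("A", 70, "ND1"), ("A", 66, "O"))
        assert summary.median == pytest.approx(2.8)
        assert summary.kde_x[np.argmax(summary.kde_density)] == pytest.approx(2.8, abs=0.01)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        top = Structure(["A", "A"], [1, 2], ["ALA", "ALA"], ["O", "N"],
                        ["O", "N"], np.zeros((2, 3)))
        frames = np.zeros((500, 2, 3))
        frames[:, 1, 0] = np.where(rng.random(500) < 0.7, 2.8, 5.5)
        frames += rng.normal(scale=0.05, size=frames.shape)
        traj = TrajectoryEnsemble(top, frames)
        summary = hbond_distance_density(traj, ("A", 1, "O"), ("A", 2, "N"))
        integral = np.trapezoid(summary.kde_density, summary.kde_x)
        assert integral == pytest.approx(1.0, abs=1e-3)
        # bimodal mixture: mass near each mode in ≈7:3 proportion
        mid = 4.15
        lo = np.trapezoid(
            np.where(summary.kde_x < mid, summary.kde_density, 0), summary.kde_x
        )
        assert lo == pytest.approx(0.7, abs=0.07)

    def test_empty_trajectory_rejected(self):
        top = Structure(["A"], [1], ["ALA"], ["O"], ["O"], np.zeros((1, 3)))
        traj = TrajectoryEnsemble(top, np.zeros((0, 1, 3)))
        with pytest.raises(SelectionError):
            hbond_distance_density(traj, ("A", 1, "O"), ("A", 1, "O"))

    def test_frame_reordering_invariance(self):
        traj = make_two_state_trajectory(100, 3.0, (0.5, 0.5), seed=13)
        fwd = intersubunit_ca_distance(traj, (1, "ALA"), "A", "B")
        rev = TrajectoryEnsemble(traj.topology, traj.frames[::-1].copy())
        bwd = intersubunit_ca_distance(rev, (1, "ALA"), "A", "B")
        assert fwd.mean == pytest.approx(bwd.mean, abs=1e-12)
        assert fwd.median == pytest.approx(bwd.median, abs=1e-12)


class TestMinSidechainDistance:
    def _traj(self):
        top = Structure(
            ["A"] * 4 + ["A"] * 4,
            [230] * 4 + [414] * 4,
            ["ARG"] * 4 + ["GLU"] * 4,
            ["N", "CA", "CB", "NH1", "N", "CA", "CB", "OE1"],
            ["N", "C", "C", "N", "N", "C", "C", "O"],
            [[0, 0, 0], [1.5, 0, 0], [2.5, 1, 0], [3.5, 2, 0],
             [10, 0, 0], [8.5, 0, 0], [7.3, 0.8, 0], [6.2, 1.7, 0]],
        )
        return TrajectoryEnsemble(top, np.repeat(top.coords[None], 3, axis=0))

    def test_minimum_over_all_heavy_pairs(self):
        traj = self._traj()
        summary = min_sidechain_distance(traj, ("A", 230), ("A", 414))
        # closest heavy side-chain pair: NH1 (3.5,2,0) – OE1 (6.2,1.7,0)
        expected = np.linalg.norm(np.array([3.5, 2, 0]) - np.array([6.2, 1.7, 0]))
        # brute-force oracle over all side-chain pairs
        sc_a = [[2.5, 1, 0], [3.5, 2, 0]]
        sc_b = [[7.3, 0.8, 0], [6.2, 1.7, 0]]
        brute = min(
            np.linalg.norm(np.array(a) - np.array(b)) for a in sc_a for b in sc_b
        )
        assert expected == pytest.approx(brute)
        np.testing.assert_allclose(summary.values, brute)

    def test_same_residue_rejected(self):
        with pytest.raises(SelectionError):
            min_sidechain_distance(self._traj(), ("A", 230), ("A", 230))

    def test_glycine_rejected(self):
        top = Structure(["A"] * 3 + ["A"], [1] * 3 + [5], ["GLY"] * 3 + ["ALA"],
                        ["N", "CA", "C", "CB"], ["N", "C", "C", "C"],
                        np.arange(12.0).reshape(4, 3))
        traj = TrajectoryEnsemble(top, top.coords[None])
        with pytest.raises(NoSidechainError):
            min_sidechain_distance(traj, ("A", 1), ("A", 5))


class TestNativeContacts:
    def _folded(self):
        # chain of single-atom residues, spaced 2 Å: contacts between
        # residues ≥3 apart require |i−j|·2 ≤ 5 → only |i−j| == 3 pairs...
        # use a folded hairpin so long-range pairs come close instead
        coords = np.array([
            [0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0],
            [6, 2.9, 0], [4, 2.9, 0], [2, 2.9, 0], [0, 2.9, 0],
        ], dtype=float)
        top = Structure(
            ["A"] * 8, np.arange(1, 9), ["GLY"] * 8, ["CA"] * 8, ["C"] * 8, coords
        )
        return top

    def test_identity_trajectory_fraction_one(self):
        top = self._folded()
        traj = TrajectoryEnsemble(top, np.repeat(top.coords[None], 4, axis=0))
        fractions = native_contacts_fraction(traj, top.coords)
        np.testing.assert_array_equal(fractions, 1.0)

    def test_unfolded_limit_fraction_zero(self):
        top = self._folded()
        blown = top.coords * 50.0
        traj = TrajectoryEnsemble(top, blown[None])
        assert native_contacts_fraction(traj, top.coords)[0] == 0.0

    def test_half_stretched_fixture_gives_half(self):
        """Two equal native-contact clusters; stretching one beyond the 5 Å
        cutoff leaves exactly half the reference contacts intact."""
        top = Structure(
            ["A"] * 4, [1, 4, 10, 13], ["GLY"] * 4, ["CA"] * 4, ["C"] * 4,
            [[0, 0, 0], [3, 0, 0], [20, 0, 0], [23, 0, 0]],
        )
        ref = top.coords.copy()  # contacts: (1,4) and (10,13), both at 3 Å
        frame = ref.copy()
        frame[3] = [60.0, 0.0, 0.0]  # stretch the second contact
        traj = TrajectoryEnsemble(top, frame[None])
        assert native_contacts_fraction(traj, ref)[0] == pytest.approx(0.5)

    def test_empty_contact_set_rejected(self):
        top = Structure(["A"] * 2, [1, 9], ["GLY"] * 2, ["CA"] * 2, ["C"] * 2,
                        [[0, 0, 0], [30, 0, 0]])
        traj = TrajectoryEnsemble(top, top.coords[None])
        with pytest.raises(NoContactsError):
            native_contacts_fraction(traj, top.coords)

    def test_rotation_invariance(self):
        top = self._folded()
        frames = np.repeat(top.coords[None], 3, axis=0)
        traj = TrajectoryEnsemble(top, frames)
        moved = TrajectoryEnsemble(top, _rigid_transform(frames, seed=6))
        np.testing.assert_allclose(
            native_contacts_fraction(traj, top.coords),
            native_contacts_fraction(moved, top.coords),
        )


class TestDistributionSummary:
    def test_constant_values_degenerate_kde(self):
        s = summarize_distribution(np.full(10, 2.8))
        assert s.median == 2.8
        assert np.trapezoid(s.kde_density, s.kde_x) == pytest.approx(1.0, abs=1e-3)

    def test_density_nonnegative(self, rng):
        s = summarize_distribution(rng.normal(5, 1, 300))
        assert (s.kde_density >= 0).all()
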