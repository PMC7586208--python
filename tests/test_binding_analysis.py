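"""Geometric trajectory analytics: distances, binding classification, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.spatial.transform import Rotation

from tarp8 import binding_analysis as ba
from tarp8.errors import SelectionError
from tarp8.mol_io import Atom, AtomSelector, Frame

from conftest import make_trajectory


def _frame(coords):
    return Frame(time=0.0, coords=np.asarray(coords, dtype=float))


class TestAtomDistance:
    def test_coincident_atoms(self):
        f = _frame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert ba.atom_distance(f, 0, 1) == 0.0

    def test_pythagorean(self):
        f = _frame([[0, 0, 0], [0.3, 0.4, 0.0]])
        assert ba.atom_distance(f, 0, 1) == pytest.approx(0.5, abs=1e-12)

    def test_index_out_of_range(self):
        f = _frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IndexError):
            ba.atom_distance(f, 0, 2)

    def test_pocket_width_on_synthetic_structure(self, synthetic_pocket_pdb):
        """8.5 Å anchor separation on the synthetic pocket stand-in."""
        from tarp8.mol_io import read_pdb, select_atoms

        traj = read_pdb(synthetic_pocket_pdb)
        (ia,) = select_atoms(traj, AtomSelector(chain_id="E", res_seq=176, atom_name="CA"))
        (ib,) = select_atoms(traj, AtomSelector(chain_id="E", res_seq=209, atom_name="CA"))
        d_nm = ba.atom_distance(traj.frames[0], ia, ib)
        assert round(d_nm * 10, 1) == 8.5


class TestPocketWidthSeries:
    def test_static_trajectory_constant(self):
        coords = np.tile(np.array([[0, 0, 0], [0.9, 0, 0.0]]), (5, 1, 1))
        traj = make_trajectory(coords)
        s = ba.pocket_width_series(
            traj, AtomSelector(res_seq=1), AtomSelector(res_seq=2)
        )
        np.testing.assert_allclose(s.values, 0.9, atol=1e-12)

    def test_breathing_pocket_matches_generator(self):
        """Sinusoidal widths are reproduced to machine precision."""
        times = np.arange(50, dtype=float)
        widths = 0.85 + 0.15 * np.sin(2 * np.pi * times / 20.0)
        coords = np.zeros((50, 2, 3))
        coords[:, 1, 0] = widths
        traj = make_trajectory(coords, times=times)
        s = ba.pocket_width_series(traj, AtomSelector(res_seq=1), AtomSelector(res_seq=2))
        np.testing.assert_allclose(s.values, widths, atol=1e-9)

    def test_ambiguous_selector_rejected(self):
        traj = make_trajectory(np.zeros((1, 3, 3)))
        with pytest.raises(SelectionError, match="3 atoms"):
            ba.pocket_width_series(traj, AtomSelector(chain_id="A"),
                                   AtomSelector(chain_id="A", atom_name="C2"))


class TestCenters:
    def test_site_center_midpoint(self):
        f = _frame([[0, 0, 0], [1, 0, 0]])
        np.testing.assert_allclose(ba.site_center(f, 0, 1), [0.5, 0, 0])

    def test_site_center_random_pair_componentwise(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=3), rng.normal(size=3)
        f = _frame([a, b])
        expected = np.array([(a[k] + b[k]) / 2 for k in range(3)])
        np.testing.assert_allclose(ba.site_center(f, 0, 1), expected, atol=1e-12)

    def test_ligand_com_single_and_equal_masses(self):
        f = _frame([[0, 0, 0], [0.28, 0, 0]])
        np.testing.assert_allclose(ba.ligand_com(f, [0], np.array([12.0, 12.0])), [0, 0, 0])
        np.testing.assert_allclose(
            ba.ligand_com(f, [0, 1], np.array([12.0, 12.0])), [0.14, 0, 0]
        )

    def test_ligand_com_weighted(self):
        # masses 12 and 16 Da at x = 0 and 0.28 nm -> x = 0.16 nm
        f = _frame([[0, 0, 0], [0.28, 0, 0]])
        com = ba.ligand_com(f, [0, 1], np.array([12.0, 16.0]))
        assert com[0] == pytest.approx(0.16, abs=1e-12)

    def test_empty_ligand_selection(self):
        f = _frame([[0, 0, 0]])
        with pytest.raises(SelectionError):
            ba.ligand_com(f, [], np.array([12.0]))


class TestEngagementSeries:
    def _traj(self, com_positions):
        """2 anchors at +-0.425 nm on x plus a 1-atom ligand following com_positions."""
        n = len(com_positions)
        coords = np.zeros((n, 3, 3))
        coords[:, 0, 0] = -0.425
        coords[:, 1, 0] = 0.425
        coords[:, 2, :] = com_positions
        atoms = [
            Atom(1, "CA", "C", "VAL", 176, "A", 12.011),
            Atom(2, "CA", "C", "GLY", 209, "A", 12.011),
            Atom(3, "C1", "C", "LIG", 1, "L", 12.011),
        ]
        return make_trajectory(coords, atoms=atoms)

    def test_pinned_at_center_all_zero(self):
        traj = self._traj(np.zeros((4, 3)))
        s = ba.engagement_series(
            traj, AtomSelector(res_name="LIG"), AtomSelector(res_seq=176),
            AtomSelector(res_seq=209)
        )
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_matches_frame_by_frame_recompute(self):
        rng = np.random.default_rng(5)
        com = rng.normal(scale=0.5, size=(20, 3))
        traj = self._traj(com)
        s = ba.engagement_series(
            traj, AtomSelector(res_name="LIG"), AtomSelector(res_seq=176),
            AtomSelector(res_seq=209)
        )
        expected = np.linalg.norm(com - 0.0, axis=1)  # site centre is the origin
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_empty_ligand_selection_errors(self):
        traj = self._traj(np.zeros((2, 3)))
        with pytest.raises(SelectionError):
            ba.engagement_series(
                traj, AtomSelector(res_name="XXX"), AtomSelector(res_seq=176),
                AtomSelector(res_seq=209)
            )

    def test_rigid_motion_invariance(self):
        """Pocket width and engagement are invariant under global rotation+translation."""
        rng = np.random.default_rng(11)
        com = rng.normal(scale=0.5, size=(10, 3))
        traj = self._traj(com)
        rot = Rotation.from_euler("xyz", [0.4, -1.0, 2.2]).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        moved = make_trajectory(
            np.einsum("fij,kj->fik", traj.coords(), rot) + shift, atoms=traj.atoms
        )
        lig, a, b = (AtomSelector(res_name="LIG"), AtomSelector(res_seq=176),
                     AtomSelector(res_seq=209))
        np.testing.assert_allclose(
            ba.engagement_series(moved, lig, a, b).values,
            ba.engagement_series(traj, lig, a, b).values, atol=1e-9,
        )
        np.testing.assert_allclose(
            ba.pocket_width_series(moved, a, b).values,
            ba.pocket_width_series(traj, a, b).values, atol=1e-9,
        )


def bound_runs_oracle(times, values, cutoff, min_dwell):
    """Brute-force run scan: maximal sub-cutoff runs with dwell >= min_dwell."""
    runs, start = [], None
    for i, v in enumerate(values):
        if v < cutoff and start is None:
            start = i
        elif v >= cutoff and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return [
        (times[i], times[j])
        for i, j in runs
        if times[j] > times[i] and times[j] - times[i] >= min_dwell
    ]


class TestClassifyBound:
    def test_all_below_single_interval(self):
        s = ba.DistanceSeries(times=np.arange(10.0), values=np.full(10, 0.3))
        bi = ba.classify_bound(s, cutoff=0.8, min_dwell=0.0)
        assert bi.intervals == [(0.0, 9.0)]

    def test_all_above_empty(self):
        s = ba.DistanceSeries(times=np.arange(10.0), values=np.full(10, 2.0))
        assert ba.classify_bound(s, cutoff=0.8, min_dwell=0.0).intervals == []

    def test_injected_runs_with_min_dwell(self):
        """Runs of 2, 7 and 30 ns; only those >= 5 ns dwell survive."""
        times = np.arange(100.0)
        values = np.full(100, 2.0)
        values[5:8] = 0.3  # 2 ns span
        values[20:28] = 0.3  # 7 ns span
        values[50:81] = 0.3  # 30 ns span
        s = ba.DistanceSeries(times=times, values=values)
        bi = ba.classify_bound(s, cutoff=0.8, min_dwell=5.0)
        assert bi.intervals == [(20.0, 27.0), (50.0, 80.0)]
        assert bi.intervals == bound_runs_oracle(times, values, 0.8, 5.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(0, 10_000),
        cutoff=st.floats(0.2, 1.5),
        min_dwell=st.sampled_from([0.0, 1.0, 3.0, 5.0]),
    )
    def test_equals_run_length_oracle(self, seed, cutoff, min_dwell):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        times = np.cumsum(rng.uniform(0.1, 2.0, n))
        values = rng.uniform(0, 2, n)
        s = ba.DistanceSeries(times=times, values=values)
        bi = ba.classify_bound(s, cutoff=cutoff, min_dwell=min_dwell)
        assert bi.intervals == bound_runs_oracle(times, values, cutoff, min_dwell)


class TestHBond:
    def _traj(self, h_offsets):
        """Donor N / H / acceptor O triplet; H at given x offsets from acceptor."""
        n = len(h_offsets)
        coords = np.zeros((n, 3, 3))
        coords[:, 0, 0] = np.asarray(h_offsets) + 0.1  # donor N beyond H
        coords[:, 1, 0] = h_offsets  # hydrogen
        # acceptor fixed at origin
        atoms = [
            Atom(1, "N1", "N", "LIG", 1, "L", 14.007),
            Atom(2, "H1", "H", "LIG", 1, "L", 1.008),
            Atom(3, "OD1", "O", "ASN", 172, "A", 15.999),
        ]
        return make_trajectory(coords, atoms=atoms)

    def _spec(self, mode, cutoff=None):
        return ba.HBondSpec(
            donor=AtomSelector(atom_name="N1"),
            hydrogen=AtomSelector(atom_name="H1"),
            acceptor=AtomSelector(atom_name="OD1"),
            mode=mode,
            cutoff=cutoff,
        )

    def test_constant_h_acceptor_distance(self):
        traj = self._traj([0.2, 0.2, 0.2])
        s = ba.hbond_series(traj, self._spec(ba.HBondMode.H_TO_ACCEPTOR))
        np.testing.assert_allclose(s.values, 0.2, atol=1e-12)

    def test_heavy_mode_measures_donor_not_hydrogen(self):
        traj = self._traj([0.2, 0.2])
        s = ba.hbond_series(traj, self._spec(ba.HBondMode.HEAVY_TO_HEAVY))
        np.testing.assert_allclose(s.values, 0.3, atol=1e-12)  # N is 0.1 beyond H

    def test_mode_default_cutoffs(self):
        assert self._spec(ba.HBondMode.H_TO_ACCEPTOR).cutoff == 0.25
        assert self._spec(ba.HBondMode.HEAVY_TO_HEAVY).cutoff == 0.36

    def test_h_mode_requires_hydrogen(self):
        with pytest.raises(ValueError, match="hydrogen"):
            ba.HBondSpec(
                donor=AtomSelector(atom_name="N1"),
                acceptor=AtomSelector(atom_name="OD1"),
                mode=ba.HBondMode.H_TO_ACCEPTOR,
            )

    def test_bond_forming_trajectory_matches_generator(self):
        rng = np.random.default_rng(9)
        offsets = np.abs(rng.normal(0.3, 0.15, 30)) + 0.05
        traj = self._traj(offsets)
        s = ba.hbond_series(traj, self._spec(ba.HBondMode.H_TO_ACCEPTOR))
        np.testing.assert_allclose(s.values, offsets, atol=1e-12)


def occupancy_oracle(times, values, cutoff):
    """Explicit interval-sum: each sample owns half-intervals to its neighbours."""
    total = 0.0
    below = 0.0
    for i in range(len(times)):
        w = 0.0
        if i > 0:
            w += (times[i] - times[i - 1]) / 2
        if i < len(times) - 1:
            w += (times[i + 1] - times[i]) / 2
        total += w
        if values[i] < cutoff:
            below += w
    return below / total


class TestOccupancy:
    def test_all_below_is_one(self):
        s = ba.DistanceSeries(times=np.arange(5.0), values=np.full(5, 0.2))
        assert ba.hbond_occupancy(s, 0.25) == 1.0

    def test_all_above_is_zero(self):
        s = ba.DistanceSeries(times=np.arange(5.0), values=np.full(5, 0.4))
        assert ba.hbond_occupancy(s, 0.25) == 0.0

    def test_uneven_spacing_matches_interval_sum_oracle(self):
        times = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 30.0])
        values = np.array([0.2, 0.2, 0.4, 0.2, 0.4, 0.4])
        occ = ba.hbond_occupancy(ba.DistanceSeries(times=times, values=values), 0.25)
        assert occ == pytest.approx(occupancy_oracle(times, values, 0.25), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_limits_and_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        times = np.cumsum(rng.uniform(0.1, 3.0, n))
        values = rng.uniform(0, 1, n)
        s = ba.DistanceSeries(times=times, values=values)
        assert ba.hbond_occupancy(s, 1e9) == 1.0
        assert ba.hbond_occupancy(s, 1e-12) == 0.0
        occs = [ba.hbond_occupancy(s, c) for c in np.linspace(0.01, 1.2, 25)]
        assert all(b >= a for a, b in zip(occs, occs[1:]))


class TestSnapshotSelection:
    def _traj(self, widths):
        coords = np.zeros((len(widths), 2, 3))
        coords[:, 1, 0] = widths
        return make_trajectory(coords)

    def test_increasing_widths_last_frame(self):
        traj = self._traj(np.linspace(0.85, 1.17, 10))
        idx = ba.select_max_width_frame(
            traj, AtomSelector(res_seq=1), AtomSelector(res_seq=2)
        )
        assert idx == 9

    def test_tie_earliest_frame(self):
        traj = self._traj(np.full(6, 0.9))
        assert ba.select_max_width_frame(
            traj, AtomSelector(res_seq=1), AtomSelector(res_seq=2)
        ) == 0

    def test_random_widths_argmax_oracle(self):
        rng = np.random.default_rng(13)
        widths = rng.uniform(0.8, 1.2, 40)
        traj = self._traj(widths)
        idx = ba.select_max_width_frame(
            traj, AtomSelector(res_seq=1), AtomSelector(res_seq=2)
        )
        best = 0
        for i, w in enumerate(widths):
            if w > widths[best]:
                best = i
        assert idx == best


def rmsd_minimization_oracle(ref, mob):
    """Direct numerical minimization over rotations and translations."""

    def objective(p):
        rot = Rotation.from_euler("xyz", p[:3]).as_matrix()
        moved = mob @ rot.T + p[3:]
        return np.sqrt(((ref - moved) ** 2).sum(axis=1).mean())

    best = np.inf
    for x0 in (np.zeros(6), np.full(6, 0.5), np.array([1.0, 2.0, 3.0, 0, 0, 0]),
               np.array([-1.0, 0.5, -2.0, 1, 1, 1])):
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50_000, "maxfev": 50_000},
        )
        best = min(best, res.fun)
    return best * 10.0  # nm -> A


class TestSuperposeRmsd:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        assert ba.superpose_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        b = a @ rot.T + np.array([1.0, 2.0, 3.0])
        assert ba.superpose_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_four_point_toy_matches_minimization_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 3))
        b = a.copy()
        b[2] += np.array([0.3, 0.0, 0.0])
        assert ba.superpose_rmsd(a, b) == pytest.approx(
            rmsd_minimization_oracle(a, b), abs=1e-4
        )

    def test_symmetry_and_upper_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=(7, 3))
            b = a + rng.normal(scale=0.2, size=(7, 3))
            ab, ba_ = ba.superpose_rmsd(a, b), ba.superpose_rmsd(b, a)
            assert ab == pytest.approx(ba_, abs=1e-6)
            unsup = np.sqrt(((a - b) ** 2).sum(axis=1).mean()) * 10
            assert ab <= unsup + 1e-9

    def test_count_mismatch_and_too_few(self):
        a = np.zeros((4, 3))
        with pytest.raises(ValueError):
            ba.superpose_rmsd(a, np.zeros((5, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            ba.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
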