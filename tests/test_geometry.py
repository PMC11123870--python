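"""Size and shape metrics against brute-force oracles and symmetry limits."""

import numpy as np
import pytest

from micellekit.core import Selection
from micellekit.geometry import (FrameInertia, cage_com_distances,
                                 eccentricity, gyration_analysis,
                                 gyration_tensor, inertia_analysis,
                                 inertia_moments, micelle_radius,
                                 radius_of_gyration)
from micellekit.synthetic import (SyntheticSpec, arrangement_vertices,
                                  fibonacci_sphere, generate,
                                  micelle_assignment)

from conftest import cloud_frame, full_selection, point_topology


def rg_oracle(coords, masses):
    """Direct double-loop evaluation of the mass-weighted Rg."""
    com = np.zeros(3)
    for r, m in zip(coords, masses):
        com += m * r
    com /= masses.sum()
    s = 0.0
    for r, m in zip(coords, masses):
        s += m * np.dot(r - com, r - com)
    return np.sqrt(s / masses.sum())


def inertia_oracle(coords, masses):
    """Brute-force inertia tensor assembly + eigen-solve."""
    com = np.average(coords, weights=masses, axis=0)
    r = coords - com
    I = np.zeros((3, 3))
    for k in range(len(masses)):
        x = r[k]
        I += masses[k] * (np.dot(x, x) * np.eye(3) - np.outer(x, x))
    return np.sort(np.linalg.eigvalsh(I))[::-1]


class TestRadiusOfGyration:
    def test_point_mass_zero(self):
        coords = np.ones((4, 3)) * 2.0
        top = point_topology(coords)
        assert radius_of_gyration(full_selection(4), cloud_frame(coords),
                                  top) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        top = point_topology(coords)
        rg = radius_of_gyration(full_selection(2), cloud_frame(coords), top)
        assert rg == pytest.approx(1.0)   # COM at (1,0,0), both atoms 1 nm away

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            coords = rng.normal(size=(50, 3))
            masses = rng.uniform(1.0, 16.0, size=50)
            top = point_topology(coords, masses=masses)
            rg = radius_of_gyration(full_selection(50), cloud_frame(coords + 5),
                                    top)
            assert rg == pytest.approx(rg_oracle(coords, masses), abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1.0, 12.0, size=30)
        top = point_topology(coords, masses=masses)
        sel = full_selection(30)
        rg0 = radius_of_gyration(sel, cloud_frame(coords + 5), top)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = coords @ q.T + np.array([1.0, -2.0, 0.5])
        rg1 = radius_of_gyration(sel, cloud_frame(moved + 5), top)
        assert rg1 == pytest.approx(rg0, rel=1e-9)


class TestMicelleRadius:
    @pytest.mark.parametrize("rg,rs", [(1.13, 1.46), (1.18, 1.52), (1.17, 1.51)])
    def test_hard_sphere_relation_two_decimals(self, rg, rs):
        assert round(micelle_radius(rg), 2) == rs

    def test_zero(self):
        assert micelle_radius(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            micelle_radius(-0.1)


class TestInertia:
    def test_regular_tetrahedron_is_isotropic(self):
        verts = arrangement_vertices("tetrahedral", 1.0) + 5.0
        top = point_topology(verts)
        fi = inertia_moments(full_selection(4), cloud_frame(verts), top)
        assert fi.moments[0] == pytest.approx(fi.moments[2], rel=1e-9)
        assert fi.eccentricity == pytest.approx(0.0, abs=1e-9)

    def test_rod_limit(self):
        coords = np.column_stack([np.linspace(0, 2, 9), np.zeros(9), np.zeros(9)])
        top = point_topology(coords)
        fi = inertia_moments(full_selection(9), cloud_frame(coords + 3), top)
        assert fi.moments[2] == pytest.approx(0.0, abs=1e-12)
        assert fi.degenerate
        assert fi.moments[0] == pytest.approx(fi.moments[1], rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            coords = rng.normal(size=(25, 3)) * 1.5
            masses = rng.uniform(1.0, 35.0, size=25)
            top = point_topology(coords, masses=masses)
            fi = inertia_moments(full_selection(25), cloud_frame(coords + 5), top)
            assert np.allclose(fi.moments, inertia_oracle(coords, masses),
                               rtol=1e-9)


class TestEccentricity:
    def test_equal_moments_sphere(self):
        assert eccentricity(2.0, 2.0) == 0.0

    def test_arithmetic(self):
        assert eccentricity(1.0, 1.25) == pytest.approx(0.2)

    def test_formula_consistency(self):
        moments = np.array([1.6, 1.35, 1.0])
        fi = FrameInertia(moments=moments)
        assert fi.eccentricity == pytest.approx(1.0 - 1.0 / np.mean(moments))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            eccentricity(2.0, 1.0)


class TestGyrationTensor:
    def test_isotropic_shell_unity_ratios(self):
        shell = fibonacci_sphere(400)
        top = point_topology(shell)
        g = gyration_tensor(full_selection(400), cloud_frame(shell + 5), top)
        assert g.ratio_12 == pytest.approx(1.0, abs=0.01)
        assert g.ratio_23 == pytest.approx(1.0, abs=0.01)

    def test_planar_square_smallest_eigenvalue_zero(self):
        sq = arrangement_vertices("planar_square", 1.0) + 5.0
        top = point_topology(sq)
        g = gyration_tensor(full_selection(4), cloud_frame(sq), top)
        assert g.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)

    def test_trace_identity_with_rg(self, rng):
        coords = rng.normal(size=(40, 3))
        masses = rng.uniform(1.0, 12.0, size=40)
        top = point_topology(coords, masses=masses)
        sel = full_selection(40)
        g = gyration_tensor(sel, cloud_frame(coords + 5), top)
        rg = radius_of_gyration(sel, cloud_frame(coords + 5), top)
        assert g.rg == pytest.approx(rg, rel=1e-9)
        assert np.sum(g.eigenvalues) == pytest.approx(rg ** 2, rel=1e-9)


class TestSphericityLimit:
    @pytest.mark.parametrize("jitter", [0.08, 0.02, 0.005])
    def test_jitter_shrinks_anisotropy(self, jitter):
        """A spherically symmetric aggregate approaches Imax/Imin = 1 and
        e = 0 as positional jitter vanishes."""
        rng = np.random.default_rng(99)
        shell = fibonacci_sphere(300)
        results = []
        for _ in range(3):
            coords = shell + rng.normal(0.0, jitter, size=shell.shape)
            top = point_topology(coords)
            fi = inertia_moments(full_selection(300), cloud_frame(coords + 5),
                                 top)
            results.append((fi.ratio_max_min, fi.eccentricity))
        ratio = np.mean([r for r, _ in results])
        ecc = np.mean([e for _, e in results])
        assert ratio < 1.0 + 6.0 * jitter
        assert ecc < 4.0 * jitter


class TestCageComDistances:
    def test_static_tetrahedron_all_edges_equal(self):
        spec = SyntheticSpec(arrangement="tetrahedral", edge=1.2,
                             com_jitter=0.0, n_frames=3, n_cage_atoms=30,
                             chains_per_cage=0, water_density=0.0, seed=3)
        traj, _ = generate(spec)
        assignment = micelle_assignment(traj.topology)
        cd = cage_com_distances(assignment, traj)
        assert len(cd.pair_labels) == 6
        assert np.allclose(cd.distances, 1.2, atol=1e-6)

    def test_matches_per_frame_brute_force(self, small_micelle):
        from micellekit.core import (center_of_mass, minimum_image_distance,
                                     whole_coords)
        traj, truth = small_micelle
        assignment = micelle_assignment(traj.topology)
        cd = cage_com_distances(assignment, traj)
        fr = traj.frames[4]
        coords = whole_coords(traj.topology, fr, cluster=False)
        coms = [center_of_mass(assignment.cages[m], coords, traj.topology)
                for m in assignment.molecule_ids]
        k = 0
        for a in range(4):
            for b in range(a + 1, 4):
                ref = minimum_image_distance(coms[a], coms[b], fr.box)
                assert cd.distances[4, k] == pytest.approx(ref, abs=1e-12)
                k += 1

    def test_mean_sd_recomputable_from_series(self, small_micelle):
        traj, _ = small_micelle
        assignment = micelle_assignment(traj.topology)
        cd = cage_com_distances(assignment, traj, window_fraction=0.5)
        for p, lab in enumerate(cd.pair_labels):
            win = cd.distances[traj.n_frames - traj.n_frames // 2:, p]
            assert cd.stats[lab].mean == pytest.approx(win.mean())
            assert cd.stats[lab].sd == pytest.approx(win.std())


class TestTrajectoryAnalyses:
    def test_window_statistics_match_series(self, small_micelle):
        traj, _ = small_micelle
        sel = traj.topology.select(role=["cage", "chain", "head"])
        g = gyration_analysis(sel, traj, window_fraction=0.25)
        win = g.rg.series[g.rg.window]
        assert g.rg.mean == pytest.approx(win.mean())
        assert g.rg.sd == pytest.approx(win.std())
        assert np.allclose(g.rs.series, np.sqrt(5.0 / 3.0) * g.rg.series)

    def test_component_ordering_every_frame(self, small_micelle):
        traj, _ = small_micelle
        sel = traj.topology.select(role=["cage", "chain", "head"])
        g = gyration_analysis(sel, traj)
        c11 = g.components["Rg11"].series
        c22 = g.components["Rg22"].series
        c33 = g.components["Rg33"].series
        assert np.all(c11 >= c22) and np.all(c22 >= c33)
        ine = inertia_analysis(sel, traj)
        assert np.all(ine.imax.series >= ine.iavg.series)
        assert np.all(ine.iavg.series >= ine.imin.series)
        assert np.all((ine.eccentricity.series >= 0)
                      & (ine.eccentricity.series < 1))
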