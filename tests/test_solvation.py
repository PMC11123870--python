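"""RDF normalisation, hydration counts, hydrogen-bond geometry and C_HB(t)."""

import numpy as np
import pytest

from micellekit.core import Frame, Selection, SelectionError, Topology, Trajectory
from micellekit.solvation import (HbondCriteria, detect_hbonds, hbond_series,
                                  hbond_tcf, hydration_number,
                                  presence_matrix, rdf)
from micellekit.synthetic import PlantedShell, SyntheticSpec, generate

from conftest import cloud_frame, full_selection, point_topology


def _uniform_gas_trajectory(n_target=5000, box=6.0, n_frames=2, seed=77):
    rng = np.random.default_rng(seed)
    coords = np.vstack([[[box / 2, box / 2, box / 2]],
                        rng.uniform(0, box, size=(n_target, 3))])
    top = point_topology(coords)
    frames = [Frame(time=float(t),
                    coords=np.vstack([[[box / 2] * 3],
                                      rng.uniform(0, box, size=(n_target, 3))]),
                    box=np.full(3, box))
              for t in range(n_frames)]
    return Trajectory(top, frames)


class TestRdf:
    def test_ideal_gas_limit_is_unity(self):
        """Self-RDF of a uniform gas (self-pairs excluded) is 1 everywhere."""
        traj = _uniform_gas_trajectory(n_target=2000)
        gas = Selection(tuple(range(1, 2001)), "gas")
        res = rdf(gas, gas, traj, bin_width=0.05)
        sel = (res.bin_centers >= 0.5) & (res.bin_centers <= 2.0)
        assert np.all(np.abs(res.g[sel] - 1.0) < 0.05)

    def test_planted_shell_peak_recovered(self):
        """Targets planted in a thin shell produce a single peak in that bin,
        mirroring a contact-peak analysis at ~0.33 nm."""
        rng = np.random.default_rng(8)
        n = 200
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center = np.full(3, 3.0)
        coords = np.vstack([[center], center + 0.333 * dirs])
        top = point_topology(coords)
        traj = Trajectory(top, [cloud_frame(coords, box=(6.0, 6.0, 6.0))])
        res = rdf(Selection((0,), "ref"), Selection(tuple(range(1, n + 1)), "t"),
                  traj, bin_width=0.01)
        assert res.peak_position() == pytest.approx(0.335, abs=0.0051)
        assert np.count_nonzero(res.g) == 1

    def test_empty_target_is_an_error(self):
        traj = _uniform_gas_trajectory(n_target=10)
        with pytest.raises(SelectionError):
            rdf(Selection((0,), "ref"), Selection((), "empty"), traj)

    def test_rmax_clipped_with_warning(self):
        traj = _uniform_gas_trajectory(n_target=100)
        with pytest.warns(UserWarning, match="clipped"):
            res = rdf(Selection((0,), "r"), Selection(tuple(range(1, 101)), "t"),
                      traj, bin_width=0.05, r_max=5.0)
        assert res.bin_centers[-1] <= 3.0

    def test_integral_counts_pairs(self):
        """sum rho g 4 pi r^2 dr over all bins equals the mean number of
        in-range neighbours per reference atom."""
        traj = _uniform_gas_trajectory(n_target=800, n_frames=1, seed=5)
        ref = Selection((0,), "ref")
        tgt = Selection(tuple(range(1, 801)), "gas")
        res = rdf(ref, tgt, traj, bin_width=0.05)
        from micellekit.core import minimum_image_distance
        fr = traj.frames[0]
        d = minimum_image_distance(fr.coords[0], fr.coords[1:], fr.box)
        expected = np.sum(d <= res.bin_centers[-1] + res.bin_width / 2)
        assert res.integral(res.bin_centers[-1] + res.bin_width) == \
            pytest.approx(expected, rel=1e-9)


class TestHydrationNumber:
    def test_planted_counts_recovered_exactly(self):
        spec = SyntheticSpec(n_frames=5, n_cage_atoms=8, chains_per_cage=1,
                             water_density=0.0,
                             planted_shells=(PlantedShell(label=1, count=4,
                                                          radius=0.3),),
                             seed=21)
        traj, truth = generate(spec)
        target = truth.planted[0]["atom_index"]
        waters = traj.topology.select(role="water", element="O")
        res = hydration_number(Selection((target,), "tag"), waters, traj)
        assert res.mean_counts[0] == 4.0
        assert res.sd_counts[0] == 0.0

    def test_no_water_in_range_is_zero(self):
        """A buried atom with no nearby water has hydration number zero."""
        spec = SyntheticSpec(n_frames=3, n_cage_atoms=8, chains_per_cage=1,
                             water_density=0.2, seed=22)
        traj, truth = generate(spec)
        # label-13 atom sits at the cage surface, inside the exclusion zone
        buried = truth.chain_atom_ids[0][12]
        waters = traj.topology.select(role="water", element="O")
        res = hydration_number(Selection((buried,), "buried"), waters, traj)
        assert res.mean_counts[0] == 0.0

    def test_poisson_density_expectation(self):
        """Uniform water at density rho gives rho * (4/3) pi c^3 neighbours."""
        rho, cutoff = 2.0, 0.35
        spec = SyntheticSpec(n_frames=40, n_cage_atoms=2, chains_per_cage=1,
                             water_density=rho, water_exclusion_radius=0.0,
                             seed=23)
        traj, truth = generate(spec)
        head = truth.chain_atom_ids[0][0]
        waters = traj.topology.select(role="water", element="O")
        res = hydration_number(Selection((head,), "head"), waters, traj)
        expected = rho * 4.0 / 3.0 * np.pi * cutoff ** 3
        se = np.sqrt(expected / 40)     # Poisson counts over 40 frames
        assert abs(res.mean_counts[0] - expected) <= 3 * se

    def test_monotone_in_cutoff(self, small_micelle):
        traj, truth = small_micelle
        tags = Selection(tuple(truth.chain_atom_ids[0][:3]), "tags")
        waters = traj.topology.select(role="water", element="O")
        prev = hydration_number(tags, waters, traj, cutoff=0.25).mean_counts
        for cutoff in (0.35, 0.5, 0.8):
            cur = hydration_number(tags, waters, traj, cutoff=cutoff).mean_counts
            assert np.all(cur >= prev - 1e-12)
            prev = cur


def _water_dimer(oo_distance, angle_from_linear=0.0):
    """Donor water + acceptor oxygen; D-H along +x, acceptor rotated off it."""
    oh = 0.09572
    donor_o = np.array([1.0, 1.0, 1.0])
    h1 = donor_o + [oh, 0.0, 0.0]
    h2 = donor_o + [-0.024, 0.0927, 0.0]
    a = np.radians(angle_from_linear)
    acceptor = donor_o + oo_distance * np.array([np.cos(a), np.sin(a), 0.0])
    coords = np.vstack([donor_o, h1, h2, acceptor])
    top = Topology(names=["OW", "HW1", "HW2", "OA"],
                   elements=["O", "H", "H", "O"],
                   masses=np.array([16.0, 1.0, 1.0, 16.0]),
                   charges=np.zeros(4),
                   molecule_ids=np.array([0, 0, 0, 1]),
                   roles=["water"] * 3 + ["other"],
                   bonds=[(0, 1), (0, 2)])
    return top, cloud_frame(coords, box=(8.0, 8.0, 8.0))


class TestHbondDetection:
    def test_linear_dimer_bonds(self):
        top, fr = _water_dimer(0.28)
        bonds = detect_hbonds(HbondCriteria(), Selection((0,), "don"),
                              Selection((3,), "acc"), fr, top)
        assert bonds == [(0, 1, 3)]

    def test_distance_failure(self):
        top, fr = _water_dimer(0.40)
        bonds = detect_hbonds(HbondCriteria(), Selection((0,), "don"),
                              Selection((3,), "acc"), fr, top)
        assert bonds == []

    def test_angle_failure(self):
        # acceptor at -90 deg off the O-H1 axis, also far from the O-H2
        # direction: both D-H...A angles fall well below 120
        top, fr = _water_dimer(0.28, angle_from_linear=-90.0)
        bonds = detect_hbonds(HbondCriteria(), Selection((0,), "don"),
                              Selection((3,), "acc"), fr, top)
        assert bonds == []

    def test_donor_without_hydrogen_warns(self):
        top, fr = _water_dimer(0.28)
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            bonds = detect_hbonds(HbondCriteria(), Selection((3,), "nonH"),
                                  Selection((0,), "acc"), fr, top)
        assert bonds == []

    def test_matches_brute_force_oracle(self, rng):
        """Randomised donor/acceptor geometries agree with a brute-force
        implementation of the same distance + angle tests."""
        crit = HbondCriteria()
        for _ in range(100):
            top, fr = _water_dimer(rng.uniform(0.2, 0.5),
                                   rng.uniform(0.0, 180.0))
            got = set(detect_hbonds(crit, Selection((0,), "d"),
                                    Selection((3,), "a"), fr, top))
            want = set()
            c = fr.coords
            if np.linalg.norm(c[3] - c[0]) <= 0.35:
                for h in (1, 2):
                    hd, ha = c[0] - c[h], c[3] - c[h]
                    ang = np.degrees(np.arccos(
                        np.dot(hd, ha) / np.linalg.norm(hd) / np.linalg.norm(ha)))
                    if ang >= 120.0:
                        want.add((0, h, 3))
            assert got == want

    def test_hda_convention_equivalent_threshold(self):
        """A geometry passing D-H...A >= 120 within range also passes the
        H-D...A <= 60 reading for near-linear bonds."""
        top, fr = _water_dimer(0.28, angle_from_linear=10.0)
        for conv in ("dha", "hda"):
            crit = HbondCriteria(angle_convention=conv)
            bonds = detect_hbonds(crit, Selection((0,), "d"),
                                  Selection((3,), "a"), fr, top)
            assert bonds == [(0, 1, 3)]

    def test_acceptor_relabel_symmetry(self):
        """Equivalent acceptors at mirrored positions are detected alike."""
        top, fr = _water_dimer(0.28)
        coords = np.vstack([fr.coords, fr.coords[3] + [0.0, 0.002, 0.0]])
        top2 = Topology(names=top.names + ["OB"], elements=top.elements + ["O"],
                        masses=np.append(top.masses, 16.0),
                        charges=np.zeros(5),
                        molecule_ids=np.append(top.molecule_ids, 2),
                        roles=top.roles + ["other"], bonds=top.bonds)
        fr2 = cloud_frame(coords, box=(8.0, 8.0, 8.0))
        bonds = detect_hbonds(HbondCriteria(), Selection((0,), "d"),
                              Selection((3, 4), "acc"), fr2, top2)
        assert {(0, 1, 3), (0, 1, 4)} <= set(bonds)


class TestHbondTcf:
    def test_persistent_bond_stays_one(self):
        h = np.ones((1, 50))
        res = hbond_tcf(h, max_lag=10)
        assert np.allclose(res.c, 1.0)

    def test_single_event_decays_to_zero(self):
        h = np.zeros((1, 50))
        h[0, 0] = 1
        res = hbond_tcf(h, max_lag=10)
        assert res.c[0] == 1.0
        assert np.allclose(res.c[1:], 0.0)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no hydrogen bonds"):
            hbond_tcf(np.zeros((2, 30)), max_lag=5)

    def test_telegraph_process_matches_markov_closed_form(self):
        """A two-state Markov bond with transition probabilities p01/p10 has
        C(t) = pi1 + (1 - pi1) lambda^t with lambda = 1 - p01 - p10."""
        rng = np.random.default_rng(4)
        p01, p10 = 0.08, 0.12          # on/off switching per frame
        T, n_pairs = 10_000, 4
        pi1 = p01 / (p01 + p10)
        lam = 1.0 - p01 - p10
        h = np.zeros((n_pairs, T), dtype=bool)
        state = rng.random(n_pairs) < pi1
        for t in range(T):
            h[:, t] = state
            flip = rng.random(n_pairs)
            state = np.where(state, flip >= p10, flip < p01)
        res = hbond_tcf(h.astype(float), max_lag=40)
        expected = pi1 + (1.0 - pi1) * lam ** np.arange(41)
        # 3 standard errors on the lag-t estimate from n_pairs * origins samples
        n_eff = n_pairs * (T - 40) / 20.0    # generous autocorrelation discount
        se = 3.0 * np.sqrt(expected * (1 - expected) / (pi1 * n_eff) + 1e-12)
        assert np.all(np.abs(res.c - expected) <= np.maximum(se, 0.02))
        assert res.c[0] == 1.0
        assert np.all((res.c >= 0.0) & (res.c <= 1.0 + 1e-12))

    def test_presence_matrix_roundtrip(self):
        frames = [[(0, 1, 9)], [], [(0, 1, 9), (2, 3, 9)]]
        h = presence_matrix(frames)
        assert h.shape == (2, 3)
        assert h[0].tolist() == [True, False, True]
        assert h[1].tolist() == [False, False, True]


def test_hbond_series_counts_sites(small_micelle):
    """End-to-end: tip3p-style waters donate to chain nitrogens."""
    spec = SyntheticSpec(n_frames=3, n_cage_atoms=8, chains_per_cage=2,
                         water_density=0.5, water_model="tip3p", seed=31)
    traj, _ = generate(spec)
    top = traj.topology
    donors = top.select(role="water", element="O", label="waterO")
    sites = top.select(name=["N7", "N8"], label="N")
    series = hbond_series(HbondCriteria(), donors, sites, traj, sites,
                          mode="acceptor")
    assert series.mean_counts.shape == (len(sites.indices),)
    assert np.all(series.mean_counts >= 0.0)
    for frame_bonds, fr in zip(series.frames, traj.frames):
        for d, h, a in frame_bonds:
            assert HbondCriteria().accepts(fr.coords[d], fr.coords[h],
                                           fr.coords[a], fr.box)
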