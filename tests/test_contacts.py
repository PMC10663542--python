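"""Interaction detectors, the contact score, lifetime statistics and the
cross-run consensus network.

Detector correctness is established against exhaustive O(n^2) geometric
enumeration on randomized configurations; lifetime statistics against the
stationary law of the generating telegraph process; the consensus network
against a planted ground truth.
"""

import numpy as np
import pytest

from hingemd.contacts import (InteractionRecord, aggregate_timeline,
                              classify_atoms, cross_run_consensus,
                              detect_contacts_by_class, detect_hbonds,
                              score_kernel, score_residue_pairs)
from hingemd.errors import ConfigError, DomainError
from hingemd.synthetic import TelegraphParams, simulate_contact_telegraph
from hingemd.systems import AtomRecord, MolecularSystem

from conftest import make_trajectory


def _residue(atoms_spec, resname, resnum, chain="A", start_id=1,
             hetero=False):
    """Build AtomRecords for one residue from (name, element, xyz) specs."""
    records, coords = [], []
    for k, (name, element, xyz) in enumerate(atoms_spec):
        records.append(AtomRecord(start_id + k, name, element, resname,
                                  resnum, chain, is_hetero=hetero))
        coords.append(xyz)
    return records, coords


def _build(*residues):
    records, coords = [], []
    for spec in residues:
        r, c = spec
        records.extend(r)
        coords.extend(c)
    return MolecularSystem(records, np.array(coords, dtype=float))


def _phe_ring(center, normal, start_id, resnum, chain="A"):
    """A PHE residue whose 6-ring lies in the plane with the given normal."""
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    helper = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 \
        else np.array([0, 1.0, 0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    spec = []
    for k, name in enumerate(names):
        ang = k * np.pi / 3
        xyz = np.asarray(center) + 1.39 * (np.cos(ang) * u + np.sin(ang) * v)
        spec.append((name, "C", xyz))
    return _residue(spec, "PHE", resnum, chain, start_id)


class TestClassifyAtoms:
    def test_lysine_nitrogen_is_donor_and_cationic(self):
        system = _build(_residue([("NZ", "N", [0, 0, 0])], "LYS", 1))
        classes = classify_atoms(system)
        assert classes.hbond_donor[0] and classes.cationic[0]

    def test_glutamate_oxygens_are_acceptor_and_anionic(self):
        system = _build(_residue([("OE1", "O", [0, 0, 0]),
                                  ("OE2", "O", [2, 0, 0])], "GLU", 1))
        classes = classify_atoms(system)
        assert classes.hbond_acceptor.all() and classes.anionic.all()

    def test_phenylalanine_ring_grouped(self):
        system = _build(_phe_ring([0, 0, 0], [0, 0, 1], 1, 1))
        classes = classify_atoms(system)
        assert len(classes.aromatic_rings) == 1
        assert len(classes.aromatic_rings[0]) == 6

    def test_unknown_residue_gets_empty_classes(self, caplog):
        system = _build(_residue([("X1", "C", [0, 0, 0])], "QQQ", 1))
        with caplog.at_level("WARNING"):
            classes = classify_atoms(system)
        assert not classes.hbond_donor.any()
        assert "QQQ" in caplog.text

    def test_donor_hydrogens_found_by_bonding_distance(self):
        system = _build(_residue([("NZ", "N", [0, 0, 0]),
                                  ("HZ1", "H", [1.0, 0, 0])], "LYS", 1))
        classes = classify_atoms(system)
        assert classes.has_hydrogens
        assert classes.donor_hydrogens[0] == (1,)


class TestDetectHbonds:
    def _donor_acceptor(self, h_acc_dist, angle_deg):
        """LYS N-H donor and a GLU acceptor at the given H...A geometry."""
        theta = np.radians(180.0 - angle_deg)
        acc = np.array([1.0 + h_acc_dist * np.cos(theta),
                        h_acc_dist * np.sin(theta), 0.0])
        return _build(
            _residue([("NZ", "N", [0, 0, 0]), ("HZ1", "H", [1.0, 0, 0])],
                     "LYS", 1, start_id=1),
            _residue([("OE1", "O", acc)], "GLU", 2, start_id=3))

    def test_ideal_geometry_detected(self):
        system = self._donor_acceptor(1.9, 165.0)
        classes = classify_atoms(system)
        pairs = detect_hbonds(system.reference_coordinates, classes)
        assert pairs == {(0, 2)}

    def test_distance_beyond_cutoff_not_detected(self):
        system = self._donor_acceptor(2.6, 165.0)
        classes = classify_atoms(system)
        assert detect_hbonds(system.reference_coordinates, classes) == set()

    def test_angle_below_cutoff_not_detected(self):
        system = self._donor_acceptor(1.9, 100.0)
        classes = classify_atoms(system)
        assert detect_hbonds(system.reference_coordinates, classes) == set()

    def test_heavy_atom_fallback_without_hydrogens(self):
        system = _build(
            _residue([("NZ", "N", [0, 0, 0])], "LYS", 1, start_id=1),
            _residue([("OE1", "O", [3.4, 0, 0])], "GLU", 2, start_id=2))
        classes = classify_atoms(system)
        assert not classes.has_hydrogens
        assert detect_hbonds(system.reference_coordinates, classes) == {(0, 1)}
        far = system.reference_coordinates.copy()
        far[1, 0] = 3.6
        assert detect_hbonds(far, classes) == set()

    def test_nonpositive_cutoff_rejected(self):
        system = self._donor_acceptor(1.9, 165.0)
        classes = classify_atoms(system)
        with pytest.raises(ConfigError):
            detect_hbonds(system.reference_coordinates, classes,
                          h_dist_cutoff=-1.0)

    def test_matches_brute_force_on_random_placements(self):
        """30 random donor/acceptor constellations vs exhaustive O(n^2)."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            residues, rid, aid = [], 1, 1
            for _k in range(rng.integers(3, 7)):
                pos = rng.uniform(-6, 6, size=3)
                hdir = rng.normal(size=3)
                hdir /= np.linalg.norm(hdir)
                residues.append(_residue(
                    [("NZ", "N", pos), ("HZ1", "H", pos + hdir)],
                    "LYS", rid, start_id=aid))
                rid, aid = rid + 1, aid + 2
            for _k in range(rng.integers(3, 7)):
                residues.append(_residue(
                    [("OE1", "O", rng.uniform(-6, 6, size=3))],
                    "GLU", rid, start_id=aid))
                rid, aid = rid + 1, aid + 1
            system = _build(*residues)
            classes = classify_atoms(system)
            coords = system.reference_coordinates
            got = detect_hbonds(coords, classes)
            expected = set()
            for d in np.flatnonzero(classes.hbond_donor):
                for h in classes.donor_hydrogens.get(int(d), ()):
                    for a in np.flatnonzero(classes.hbond_acceptor):
                        if system.atoms[a].residue_key == \
                                system.atoms[d].residue_key:
                            continue
                        if np.linalg.norm(coords[h] - coords[a]) > 2.5:
                            continue
                        v1 = coords[d] - coords[h]
                        v2 = coords[a] - coords[h]
                        cosang = v1 @ v2 / (np.linalg.norm(v1)
                                            * np.linalg.norm(v2))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                                >= 120.0:
                            expected.add((int(d), int(a)))
            assert got == expected


class TestTypedContacts:
    def test_saltbridge_at_3p5(self):
        system = _build(
            _residue([("NH1", "N", [0, 0, 0])], "ARG", 1, start_id=1),
            _residue([("OD1", "O", [3.5, 0, 0])], "ASP", 2, start_id=2))
        classes = classify_atoms(system)
        pairs = detect_contacts_by_class(system.reference_coordinates,
                                         classes, "saltbridge")
        assert pairs == {(("A", 1, ""), ("A", 2, ""))}

    def test_parallel_rings_stack_far_rings_do_not(self):
        near = _build(_phe_ring([0, 0, 0], [0, 0, 1], 1, 1),
                      _phe_ring([0, 0, 4.0], [0, 0, 1], 7, 2))
        classes = classify_atoms(near)
        assert detect_contacts_by_class(near.reference_coordinates, classes,
                                        "pi_stacking") == \
            {(("A", 1, ""), ("A", 2, ""))}
        far = _build(_phe_ring([0, 0, 0], [0, 0, 1], 1, 1),
                     _phe_ring([0, 0, 8.0], [0, 0, 1], 7, 2))
        classes = classify_atoms(far)
        assert detect_contacts_by_class(far.reference_coordinates, classes,
                                        "pi_stacking") == set()

    def test_t_shaped_rings_stack(self):
        system = _build(_phe_ring([0, 0, 0], [0, 0, 1], 1, 1),
                        _phe_ring([0, 0, 5.0], [1, 0, 0], 7, 2))
        classes = classify_atoms(system)
        assert len(detect_contacts_by_class(system.reference_coordinates,
                                            classes, "pi_stacking")) == 1

    def test_hydrophobic_contact(self):
        system = _build(
            _residue([("CB", "C", [0, 0, 0])], "ALA", 1, start_id=1),
            _residue([("CB", "C", [3.9, 0, 0])], "ALA", 2, start_id=2))
        classes = classify_atoms(system)
        assert len(detect_contacts_by_class(system.reference_coordinates,
                                            classes, "hydrophobic")) == 1

    def test_unknown_class_rejected(self):
        system = _build(_residue([("CB", "C", [0, 0, 0])], "ALA", 1))
        classes = classify_atoms(system)
        with pytest.raises(ConfigError):
            detect_contacts_by_class(system.reference_coordinates, classes,
                                     "vanderwaals")

    def test_matches_brute_force_on_random_configurations(self):
        """Salt-bridge / pi-stacking / hydrophobic detectors vs exhaustive
        enumeration on 100 random <=200-atom configurations."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            residues, rid, aid = [], 1, 1
            for _k in range(rng.integers(1, 4)):
                residues.append(_residue(
                    [("NH1", "N", rng.uniform(-8, 8, 3))], "ARG", rid,
                    start_id=aid))
                rid, aid = rid + 1, aid + 1
            for _k in range(rng.integers(1, 4)):
                residues.append(_residue(
                    [("OD1", "O", rng.uniform(-8, 8, 3))], "ASP", rid,
                    start_id=aid))
                rid, aid = rid + 1, aid + 1
            for _k in range(rng.integers(1, 4)):
                residues.append(_residue(
                    [("CB", "C", rng.uniform(-8, 8, 3))], "ALA", rid,
                    start_id=aid))
                rid, aid = rid + 1, aid + 1
            for _k in range(rng.integers(2, 4)):
                n = rng.normal(size=3)
                residues.append(_phe_ring(rng.uniform(-8, 8, 3), n, aid,
                                          rid))
                rid, aid = rid + 1, aid + 6
            system = _build(*residues)
            classes = classify_atoms(system)
            coords = system.reference_coordinates
            atoms = system.atoms

            def pair(i, j):
                ki, kj = atoms[i].residue_key, atoms[j].residue_key
                return (ki, kj) if ki <= kj else (kj, ki)

            exp_salt = set()
            for i in np.flatnonzero(classes.cationic):
                for j in np.flatnonzero(classes.anionic):
                    if atoms[i].residue_key != atoms[j].residue_key and \
                            np.linalg.norm(coords[i] - coords[j]) <= 4.0:
                        exp_salt.add(pair(i, j))
            assert detect_contacts_by_class(coords, classes,
                                            "saltbridge") == exp_salt

            exp_hyd = set()
            hyd = np.flatnonzero(classes.hydrophobic)
            for x, i in enumerate(hyd):
                for j in hyd[x + 1:]:
                    if atoms[i].residue_key != atoms[j].residue_key and \
                            np.linalg.norm(coords[i] - coords[j]) <= 4.0:
                        exp_hyd.add(pair(int(i), int(j)))
            assert detect_contacts_by_class(coords, classes,
                                            "hydrophobic") == exp_hyd

            exp_pi = set()
            rings = classes.aromatic_rings
            for x in range(len(rings)):
                for y in range(x + 1, len(rings)):
                    ra, rb = rings[x], rings[y]
                    if atoms[ra[0]].residue_key == atoms[rb[0]].residue_key:
                        continue
                    ca, cb = coords[ra].mean(0), coords[rb].mean(0)
                    if np.linalg.norm(ca - cb) > 5.5:
                        continue

                    def normal(pts):
                        c = pts - pts.mean(0)
                        return np.linalg.svd(c)[2][2]

                    ang = np.degrees(np.arccos(np.clip(
                        abs(normal(coords[ra]) @ normal(coords[rb])), 0, 1)))
                    if ang <= 30.0 or 60.0 <= ang <= 90.0:
                        exp_pi.add(pair(int(ra[0]), int(rb[0])))
            assert detect_contacts_by_class(coords, classes,
                                            "pi_stacking") == exp_pi


class TestScoreKernel:
    def test_midpoint_and_monotonicity(self):
        assert score_kernel(4.0) == pytest.approx(0.5)
        d = np.linspace(0, 10, 200)
        w = score_kernel(d)
        assert np.all(np.diff(w) < 0)
        assert np.all(w >= 0)


class TestScoreResiduePairs:
    def _pair_system(self, hetero_b=False):
        return _build(
            _residue([("CB", "C", [0, 0, 0])], "ALA", 1, chain="A",
                     start_id=1),
            _residue([("CB", "C", [4.0, 0, 0])], "ALA", 1, chain="B",
                     start_id=2, hetero=hetero_b))

    def test_sigmoid_midpoint_thresholds(self):
        system = self._pair_system()
        traj = make_trajectory(system,
                               np.repeat(system.reference_coordinates[None],
                                         5, axis=0))
        classes = classify_atoms(system)
        at_protein = score_residue_pairs(traj, [0], [1], classes,
                                         threshold=1.0)
        assert at_protein == []
        at_ligand = score_residue_pairs(traj, [0], [1], classes,
                                        threshold=0.1)
        assert len(at_ligand) == 1
        assert at_ligand[0].mean_score == pytest.approx(0.5)
        np.testing.assert_allclose(at_ligand[0].per_frame_score, 0.5)

    def test_ligand_threshold_chosen_for_hetero_group(self):
        system = self._pair_system(hetero_b=True)
        traj = make_trajectory(system,
                               np.repeat(system.reference_coordinates[None],
                                         3, axis=0))
        classes = classify_atoms(system)
        records = score_residue_pairs(traj, [0], [1], classes)
        assert len(records) == 1  # 0.5 > 0.1 ligand threshold

    def test_distant_pair_excluded(self):
        system = _build(
            _residue([("CB", "C", [0, 0, 0])], "ALA", 1, chain="A",
                     start_id=1),
            _residue([("CB", "C", [20.0, 0, 0])], "ALA", 1, chain="B",
                     start_id=2))
        traj = make_trajectory(system, system.reference_coordinates[None])
        classes = classify_atoms(system)
        assert score_residue_pairs(traj, [0], [1], classes,
                                   threshold=0.1) == []

    def test_matches_hand_computed_sums(self):
        """3-residue toy trajectory vs direct per-frame summation."""
        rng = np.random.default_rng(4)
        system = _build(
            _residue([("CB", "C", [0, 0, 0]), ("CG", "C", [1.2, 0, 0])],
                     "LEU", 1, chain="A", start_id=1),
            _residue([("CB", "C", [3.5, 0, 0])], "ALA", 2, chain="A",
                     start_id=3),
            _residue([("CB", "C", [3.0, 2.0, 0]), ("CG2", "C", [4, 2, 0])],
                     "THR", 1, chain="B", start_id=4))
        base = system.reference_coordinates
        frames = base[None] + rng.normal(scale=0.3, size=(4,) + base.shape)
        traj = make_trajectory(system, frames)
        classes = classify_atoms(system)
        ga, gb = np.array([0, 1, 2]), np.array([3, 4])
        records = score_residue_pairs(traj, ga, gb, classes, threshold=0.0,
                                      classify=False)
        expected = {}
        for f in range(4):
            for i in ga:
                for j in gb:
                    d = np.linalg.norm(frames[f, i] - frames[f, j])
                    if d <= 6.0:
                        key = (system.atoms[i].residue_key,
                               system.atoms[j].residue_key)
                        expected.setdefault(key, np.zeros(4))[f] += \
                            1.0 / (1.0 + np.exp(5.0 * (d - 4.0)))
        assert len(records) == len([k for k, v in expected.items()
                                    if v.mean() > 0])
        for rec in records:
            key = ((rec.residue_a[0], rec.residue_a[1], ""),
                   (rec.residue_b[0], rec.residue_b[1], ""))
            np.testing.assert_allclose(rec.per_frame_score, expected[key],
                                       atol=1e-9)

    def test_hbond_class_takes_precedence(self):
        system = _build(
            _residue([("NZ", "N", [0, 0, 0]), ("HZ1", "H", [1.0, 0, 0])],
                     "LYS", 1, chain="A", start_id=1),
            _residue([("OE1", "O", [2.9, 0, 0])], "GLU", 1, chain="B",
                     start_id=3))
        traj = make_trajectory(system,
                               np.repeat(system.reference_coordinates[None],
                                         3, axis=0))
        classes = classify_atoms(system)
        records = score_residue_pairs(traj, [0, 1], [2], classes,
                                      threshold=0.05)
        assert len(records) == 1
        assert records[0].interaction_class == "hbond"

    def test_overlapping_groups_rejected(self):
        system = self._pair_system()
        traj = make_trajectory(system, system.reference_coordinates[None])
        classes = classify_atoms(system)
        with pytest.raises(DomainError):
            score_residue_pairs(traj, [0, 1], [1], classes)


def _record_from_scores(scores, thr=0.5):
    return InteractionRecord(
        residue_a=("A", 1, "ALA"), residue_b=("B", 2, "ALA"),
        interaction_class="other", per_frame_score=np.asarray(scores,
                                                              dtype=float),
        presence_threshold=thr)


class TestAggregateTimeline:
    def test_always_present_single_episode(self):
        stats = aggregate_timeline(_record_from_scores(np.ones(2000)))
        assert stats.lifetime_fraction == 1.0
        assert stats.episodes == ((0, 1999),)

    def test_400_of_2000_frames_is_20_percent(self):
        scores = np.zeros(2000)
        scores[100:500] = 1.0
        stats = aggregate_timeline(_record_from_scores(scores))
        assert stats.lifetime_fraction == pytest.approx(0.20)
        assert stats.episodes == ((100, 499),)

    def test_episode_lengths_partition_present_frames(self):
        rng = np.random.default_rng(9)
        scores = (rng.random(500) < 0.3).astype(float)
        stats = aggregate_timeline(_record_from_scores(scores))
        total = sum(e - s + 1 for s, e in stats.episodes)
        assert total == int(scores.sum())
        assert 0.0 <= stats.lifetime_fraction <= 1.0

    def test_telegraph_recovery_of_stationary_law(self):
        """Lifetime fraction within 3 SE of the stationary on-probability
        and mean episode length within 5% of 1/p_off at 1e5 frames."""
        params = TelegraphParams(n_frames=100_000, p_on=0.02, p_off=0.08,
                                 seed=101)
        sim = simulate_contact_telegraph(params)
        rec = _record_from_scores(score_kernel(sim.distances))
        stats = aggregate_timeline(rec)
        p = params.stationary_on
        n_episodes = len(stats.episodes)
        se = np.sqrt(p * (1 - p) / n_episodes)
        assert abs(stats.lifetime_fraction - p) <= 3 * se
        assert stats.mean_episode_length == pytest.approx(1 / params.p_off,
                                                          rel=0.05)


class TestCrossRunConsensus:
    def _planted_runs(self, n_runs=10):
        """10 runs sharing a planted 17-pair consensus, 8 of class hbond,
        plus run-specific extras that never appear in every run."""
        rng = np.random.default_rng(55)
        consensus = []
        for k in range(17):
            cls = "hbond" if k < 8 else "hydrophobic"
            consensus.append((("A", k + 1, "LYS"), ("B", k + 1, "GLU"), cls))
        runs = []
        for r in range(n_runs):
            records = [
                InteractionRecord(a, b, cls,
                                  per_frame_score=np.ones(10),
                                  lifetime_fraction=float(rng.random()))
                for a, b, cls in consensus]
            for _ in range(int(rng.integers(0, 4))):
                num = 100 + int(rng.integers(0, 50))
                records.append(InteractionRecord(
                    ("A", num, "ALA"), ("B", num, "ALA"), "other",
                    per_frame_score=np.ones(10),
                    lifetime_fraction=0.1))
            rng.shuffle(records)
            runs.append(records)
        expected = {(a, b) for a, b, _c in consensus}
        return runs, expected

    def test_planted_consensus_recovered_exactly(self):
        runs, expected = self._planted_runs()
        network = cross_run_consensus(runs)
        assert network.in_all_runs == expected
        n_hbond = sum(
            1 for key in network.in_all_runs
            if network.pairs[key].interaction_class == "hbond")
        assert n_hbond == 8

    def test_pair_absent_in_one_run_excluded(self):
        runs, expected = self._planted_runs()
        removed = runs[3][0].pair_key
        runs[3] = runs[3][1:]
        network = cross_run_consensus(runs)
        assert removed not in network.in_all_runs
        assert network.pairs[removed].runs_present == 9

    def test_invariant_to_run_ordering(self):
        runs, _ = self._planted_runs()
        a = cross_run_consensus(runs)
        b = cross_run_consensus(list(reversed(runs)))
        assert a.in_all_runs == b.in_all_runs
        for key in a.pairs:
            assert a.pairs[key].runs_present == b.pairs[key].runs_present
            assert a.pairs[key].mean_lifetime == \
                pytest.approx(b.pairs[key].mean_lifetime)

    def test_persistent_counting(self):
        rec_hi = InteractionRecord(("A", 1, "X"), ("B", 1, "X"), "hbond",
                                   per_frame_score=np.ones(4),
                                   lifetime_fraction=0.95)
        rec_lo = InteractionRecord(("A", 2, "X"), ("B", 2, "X"), "hbond",
                                   per_frame_score=np.ones(4),
                                   lifetime_fraction=0.5)
        network = cross_run_consensus([[rec_hi, rec_lo]])
        assert network.persistent_per_run_counts([[rec_hi, rec_lo]]) == [1]
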