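"""Contact detection, dual-cutoff residence, enrichment, bridging lipids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_contacts
from poremetrics.lipid_contacts import (adjacent_interfaces, analysis_window,
                                        bridging_lipids,
                                        contacts_over_trajectory,
                                        heavy_atom_contacts,
                                        intervals_from_distances, occupancy,
                                        residence_intervals,
                                        species_enrichment)
from poremetrics.structures import (Atom, Frame, MolecularSystem,
                                    assign_leaflets, assign_subunits)
from poremetrics.synthetic import ContactEvent, synth_contact_traces


def two_bead_system(distance: float):
    atoms = [Atom("CA", "ALA", 1), Atom("P", "POPC", 2)]
    system = MolecularSystem(atoms)
    frame = Frame(time=0, positions=[[2.0, 2.0, 2.0],
                                     [2.0 + distance, 2.0, 2.0]],
                  box=[8.0, 8.0, 8.0])
    return system, frame


class TestContactDetection:
    def test_within_cutoff_is_a_contact(self):
        system, frame = two_bead_system(0.30)
        contacts = heavy_atom_contacts(frame, system)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(0.30)

    def test_just_outside_cutoff_is_not(self):
        system, frame = two_bead_system(0.37)
        assert heavy_atom_contacts(frame, system) == []

    def test_minimum_image_across_boundary(self):
        atoms = [Atom("CA", "ALA", 1), Atom("P", "POPC", 2)]
        system = MolecularSystem(atoms)
        frame = Frame(time=0, positions=[[0.1, 4.0, 4.0], [7.9, 4.0, 4.0]],
                      box=[8.0, 8.0, 8.0])
        contacts = heavy_atom_contacts(frame, system)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(0.2)

    def test_box_smaller_than_twice_cutoff_raises(self):
        atoms = [Atom("CA", "ALA", 1), Atom("P", "POPC", 2)]
        system = MolecularSystem(atoms)
        frame = Frame(time=0, positions=[[0.1, 0.1, 0.1], [0.3, 0.3, 0.3]],
                      box=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="minimum-image"):
            heavy_atom_contacts(frame, system)

    @pytest.mark.parametrize("seed", range(5))
    def test_kdtree_equals_brute_force_on_random_frames(self, seed):
        """Periodic KD-tree contact map must match all-pairs minimum-image
        arithmetic exactly on dense random bead systems."""
        rng = np.random.default_rng(seed)
        atoms = []
        rid = 0
        for _ in range(60):     # protein residues, 3 heavy atoms each
            rid += 1
            atoms += [Atom("CA", "ALA", rid), Atom("CB", "ALA", rid),
                      Atom("CG", "ALA", rid)]
        for _ in range(100):    # single-bead lipids
            rid += 1
            atoms.append(Atom("P", "POPC", rid))
        system = MolecularSystem(atoms)
        frame = Frame(time=0, positions=rng.uniform(0, 5.0, (len(atoms), 3)),
                      box=[5.0, 5.0, 5.0])
        got = {(c.lipid, c.protein_residue): c.distance
               for c in heavy_atom_contacts(frame, system)}
        expected = brute_force_contacts(frame, system)
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-12)


class TestResidence:
    def test_excursion_bridged_by_dual_cutoff(self):
        d = np.array([0.3] * 10 + [0.45] * 5 + [0.6] * 5)
        assert intervals_from_distances(d) == [(0, 15)]
        # single-cutoff segmentation splits at the excursion
        assert intervals_from_distances(d, release_cutoff=0.36) == [(0, 10)]

    def test_planted_excursion_schedule(self):
        ev = ContactEvent(lipid=0, residues=(3,), start=10, end=25,
                          excursions=((15, 17, 0.45),))
        _, _, dists, _ = synth_contact_traces([ev], n_frames=40, n_protein=6)
        d = dists[(6, 3)]
        assert intervals_from_distances(d) == [(10, 25)]
        naive = intervals_from_distances(d, release_cutoff=0.36)
        assert naive == [(10, 15), (17, 25)]
        assert [e - s for s, e in naive] == [5, 8]

    def test_never_bound(self):
        assert intervals_from_distances(np.full(20, 0.55)) == []

    def test_release_below_start_raises(self):
        with pytest.raises(ValueError):
            intervals_from_distances(np.zeros(3), 0.36, 0.30)

    @given(st.lists(st.floats(0.1, 1.0), min_size=1, max_size=60),
           st.floats(0.5, 0.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_duration_monotone_in_release_cutoff(self, dists, release):
        """Dual-cutoff total residence never falls below the single-cutoff
        total, and grows with the release cutoff."""
        d = np.array(dists)
        tight = sum(e - s for s, e in
                    intervals_from_distances(d, 0.36, 0.36))
        loose = sum(e - s for s, e in
                    intervals_from_distances(d, 0.36, release))
        looser = sum(e - s for s, e in
                     intervals_from_distances(d, 0.36, release + 0.1))
        assert tight <= loose <= looser

    def test_residence_interval_records(self):
        ev = ContactEvent(lipid=0, residues=(2,), start=5, end=12)
        _, _, dists, _ = synth_contact_traces([ev], n_frames=20, n_protein=4,
                                              dt_ns=2.0)
        ivs = residence_intervals(dists, dt_ns=2.0)
        assert len(ivs) == 1
        assert (ivs[0].start_frame, ivs[0].end_frame) == (5, 12)
        assert ivs[0].duration_ns == pytest.approx(14.0)

    def test_analysis_window_drops_early_frames(self):
        frames = [Frame(time=float(t), positions=[[1, 1, 1]], box=[5, 5, 5])
                  for t in range(0, 1000, 100)]
        kept = analysis_window(frames, discard_ns=500.0)
        assert [f.time for f in kept] == [500.0, 600.0, 700.0, 800.0, 900.0]


class TestOccupancyEnrichment:
    def test_half_occupied_residue(self):
        ev = ContactEvent(lipid=0, residues=(1,), start=0, end=10)
        system, frames, _, _ = synth_contact_traces([ev], n_frames=20,
                                                    n_protein=3)
        contacts = contacts_over_trajectory(frames, system)
        occ = occupancy(contacts, system)
        row = occ[(occ.protein_residue == 1) & (occ.species == "POPC")]
        assert row.occupancy.item() == pytest.approx(0.5)

    def test_null_model_enrichment_near_one(self):
        """Contacts drawn proportionally to abundance give enrichment ~1."""
        rng = np.random.default_rng(0)
        from poremetrics.lipid_contacts import ContactPair
        atoms = [Atom("CA", "ALA", 1)]
        species = ["PAPS"] * 20 + ["POPC"] * 60 + ["PIP2"] * 20
        for i, sp in enumerate(species):
            atoms.append(Atom("P", sp, i + 2))
        system = MolecularSystem(atoms)
        system.leaflet[system.lipid_residues()] = "inner"
        contacts = [[ContactPair(lipid=int(rng.integers(1, 101)),
                                 protein_residue=0, frame=t, distance=0.3)
                     for _ in range(30)] for t in range(200)]
        enr = species_enrichment(contacts, system)
        for _, row in enr.iterrows():
            assert row.enrichment == pytest.approx(1.0, abs=0.15)

    def test_planted_threefold_enrichment(self):
        from poremetrics.lipid_contacts import ContactPair
        atoms = [Atom("CA", "ALA", 1)]
        # PIP2 is 10% of the leaflet but receives 30% of contacts
        species = ["PIP2"] * 10 + ["POPC"] * 90
        for i, sp in enumerate(species):
            atoms.append(Atom("P", sp, i + 2))
        system = MolecularSystem(atoms)
        system.leaflet[system.lipid_residues()] = "inner"
        contacts = [[ContactPair(lipid=l, protein_residue=0, frame=0,
                                 distance=0.3)
                     for l in ([1, 2, 3] + list(range(11, 18)))]]
        enr = species_enrichment(contacts, system)
        pip2 = enr[enr.species == "PIP2"].enrichment.item()
        assert pip2 == pytest.approx(3.0)

    def test_absent_species_is_undefined(self):
        from poremetrics.lipid_contacts import ContactPair
        atoms = [Atom("CA", "ALA", 1), Atom("P", "PIP2", 2),
                 Atom("P", "POPC", 3)]
        system = MolecularSystem(atoms)
        system.leaflet[1] = "outer"   # PIP2 sits in the other leaflet
        system.leaflet[2] = "inner"
        contacts = [[ContactPair(lipid=1, protein_residue=0, frame=0,
                                 distance=0.3)]]
        enr = species_enrichment(contacts, system, leaflet="inner")
        assert np.isnan(enr[enr.species == "PIP2"].enrichment.item())


class TestBridging:
    def test_planted_bridge_on_one_interface(self):
        ev = ContactEvent(lipid=0, residues=(4, 5), start=3, end=23)
        system, frames, _, _ = synth_contact_traces([ev], n_frames=30,
                                                    n_protein=8)
        contacts = contacts_over_trajectory(frames, system)
        records, per_frame, per_iface = bridging_lipids(contacts, system,
                                                        ring_closed=False)
        assert per_iface["4-5"].sum() == 20
        other = [c for c in per_iface.columns if c not in ("frame", "4-5")]
        assert per_iface[other].to_numpy().sum() == 0
        assert per_frame.n_bridging.sum() == 20

    def test_single_subunit_touch_is_not_bridging(self):
        ev = ContactEvent(lipid=0, residues=(4,), start=0, end=10)
        system, frames, _, _ = synth_contact_traces([ev], n_frames=10,
                                                    n_protein=8)
        contacts = contacts_over_trajectory(frames, system)
        _, per_frame, _ = bridging_lipids(contacts, system, ring_closed=False)
        assert per_frame.n_bridging.sum() == 0

    def test_rotation_symmetry_of_ring_labels(self):
        """Relabeling subunits by a ring rotation permutes the interface
        counts accordingly."""
        ev = ContactEvent(lipid=0, residues=(2, 3), start=0, end=5)
        system, frames, _, _ = synth_contact_traces([ev], n_frames=5,
                                                    n_protein=6)
        contacts = contacts_over_trajectory(frames, system)
        _, _, before = bridging_lipids(contacts, system, ring_closed=True)
        k = 2
        system.subunit[system.protein_residues()] = \
            (system.subunit[system.protein_residues()] + k) % 6
        _, _, after = bridging_lipids(contacts, system, ring_closed=True)
        assert before["2-3"].sum() == after["4-5"].sum() == 5

    def test_bridge_count_bounded_by_contacting_lipids(self):
        ev1 = ContactEvent(lipid=0, residues=(1, 2), start=0, end=10)
        ev2 = ContactEvent(lipid=1, residues=(3,), start=0, end=10)
        system, frames, _, _ = synth_contact_traces([ev1, ev2], n_frames=10,
                                                    n_protein=5)
        contacts = contacts_over_trajectory(frames, system)
        _, per_frame, _ = bridging_lipids(contacts, system, ring_closed=False)
        for fidx, frame_contacts in enumerate(contacts):
            n_touching = len({c.lipid for c in frame_contacts})
            assert per_frame.n_bridging[fidx] <= n_touching

    def test_fewer_than_two_subunits_raises(self):
        with pytest.raises(ValueError, match="2 subunits"):
            adjacent_interfaces(1)
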