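"""Contact detection, density profiles and spatial clouds vs brute force."""

import numpy as np
import pytest

from chesel.pdbqt_io import Receptor, ReceptorAtom
from chesel.residue_proximity import (
    ProximityCutoffs,
    accumulate_profile,
    export_cloud,
    find_contacts,
    top_residues,
)
from chesel.synthetic import generate_proximity_fixture
from conftest import make_atom, make_ligand


def _random_receptor(rng, n_residues=20, atoms_per_residue=3, scale=8.0):
    atoms = []
    serial = 0
    for r in range(n_residues):
        center = rng.uniform(-scale, scale, size=3)
        for a in range(atoms_per_residue):
            serial += 1
            pos = center + rng.normal(0, 0.8, size=3)
            atoms.append(
                ReceptorAtom(
                    serial=serial, atom_name=f"X{a}", residue_name="ALA",
                    residue_number=r + 1, chain="A",
                    x=pos[0], y=pos[1], z=pos[2],
                    partial_charge=0.0, element="C", ad_type="C",
                )
            )
    return Receptor(target_name="mock", atoms=atoms)


def _random_ligand(rng, n_atoms=50, scale=8.0):
    atoms = [
        make_atom(i + 1, ("H", "O", "N", "C")[int(rng.integers(4))],
                  rng.uniform(-scale, scale, size=3), charge=float(rng.normal(0, 0.2)))
        for i in range(n_atoms)
    ]
    return make_ligand("rand", (-8.0,), atoms=atoms)


def _brute_force_events(ligand, receptor, cutoffs):
    """Exhaustive all-pairs oracle: min distance per (atom, residue)."""
    events = set()
    for atom in ligand.mode1_atoms:
        if atom.element not in cutoffs.elements:
            continue
        per_res = {}
        for rec in receptor.atoms:
            d = np.sqrt((atom.x - rec.x) ** 2 + (atom.y - rec.y) ** 2
                        + (atom.z - rec.z) ** 2)
            key = (rec.chain, rec.residue_number, rec.residue_name)
            per_res[key] = min(per_res.get(key, np.inf), d)
        for key, d in per_res.items():
            if d <= cutoffs[atom.element]:
                events.add((atom.serial, key, round(float(d), 9)))
    return events


def test_coincident_atom_gives_zero_distance_event():
    rec = Receptor("mock", [ReceptorAtom(1, "OG", "SER", 1, "A", 1.0, 2.0, 3.0,
                                         -0.4, "O", "OA")])
    lig = make_ligand("x", (-8.0,), atoms=[make_atom(1, "O", (1.0, 2.0, 3.0))])
    (event,) = find_contacts(lig, rec)
    assert event.min_distance == 0.0
    assert event.residue_name == "SER"


def test_per_element_cutoffs_discriminate():
    """At 1.6 Å an O (cutoff 1.5) misses but an N (cutoff 2.5) hits."""
    rec = Receptor("mock", [ReceptorAtom(1, "CB", "SER", 1, "A", 0.0, 0.0, 0.0,
                                         0.0, "C", "C")])
    spot = (1.6, 0.0, 0.0)
    lig_o = make_ligand("o", (-8.0,), atoms=[make_atom(1, "O", spot)])
    lig_n = make_ligand("n", (-8.0,), atoms=[make_atom(1, "N", spot)])
    assert find_contacts(lig_o, rec) == []
    assert len(find_contacts(lig_n, rec)) == 1


def test_cutoff_boundary_is_inclusive():
    rec = Receptor("mock", [ReceptorAtom(1, "CB", "ALA", 1, "A", 0.0, 0.0, 0.0,
                                         0.0, "C", "C")])
    lig = make_ligand("h", (-8.0,), atoms=[make_atom(1, "H", (1.5, 0.0, 0.0))])
    events = find_contacts(lig, rec)
    assert len(events) == 1 and events[0].min_distance == pytest.approx(1.5)


def test_missing_atoms_error():
    rec = Receptor("mock", [ReceptorAtom(1, "CB", "ALA", 1, "A", 0, 0, 0, 0, "C")])
    with pytest.raises(ValueError, match="mode-1 atoms"):
        find_contacts(make_ligand("empty", (-8.0,)), rec)


def test_contacts_match_exhaustive_oracle(rng):
    """1,000 random fixtures, including synthetic boundary-distance cases."""
    cutoffs = ProximityCutoffs()
    for trial in range(1000):
        rec = _random_receptor(rng, n_residues=6, atoms_per_residue=2, scale=4.0)
        lig = _random_ligand(rng, n_atoms=10, scale=4.0)
        if trial % 10 == 0:  # plant an exactly-at-cutoff pair
            a0 = rec.atoms[0]
            lig.mode1_atoms[0] = make_atom(1, "H", (a0.x + 1.5, a0.y, a0.z))
        got = {
            (e.atom_serial, e.residue_key, round(e.min_distance, 9))
            for e in find_contacts(lig, rec, cutoffs)
        }
        assert got == _brute_force_events(lig, rec, cutoffs)


def test_shrinking_cutoffs_never_adds_events(rng):
    rec = _random_receptor(rng, n_residues=10, scale=5.0)
    lig = _random_ligand(rng, n_atoms=40, scale=5.0)
    wide = len(find_contacts(lig, rec, ProximityCutoffs({"H": 2.0, "O": 2.0, "N": 3.0})))
    narrow = len(find_contacts(lig, rec, ProximityCutoffs({"H": 1.0, "O": 1.0, "N": 2.0})))
    assert narrow <= wide


def test_per_receptor_atom_counts_at_least_per_pair(rng):
    rec = _random_receptor(rng, n_residues=8, scale=4.0)
    lig = _random_ligand(rng, n_atoms=30, scale=4.0)
    per_pair = find_contacts(lig, rec)
    per_atom = find_contacts(lig, rec, per_receptor_atom=True)
    assert len(per_atom) >= len(per_pair)


class TestProfile:
    def test_additivity_over_ligands(self):
        rec = Receptor("mock", [ReceptorAtom(1, "CB", "SER", 7, "A", 0, 0, 0, 0.0, "C", "C")])
        events = []
        for lid in ("l1", "l2"):
            lig = make_ligand(lid, (-8.0,), atoms=[make_atom(1, "H", (1.0, 0, 0))])
            events.extend(find_contacts(lig, rec))
        profile = accumulate_profile(events)
        assert profile.count(("A", 7, "SER"), "H") == 2

    def test_empty_contacts_give_empty_profile(self):
        profile = accumulate_profile([])
        assert profile.counts == {} and profile.n_ligands == 0

    def test_mixed_targets_error(self):
        rec1 = Receptor("t1", [ReceptorAtom(1, "CB", "SER", 1, "A", 0, 0, 0, 0.0, "C", "C")])
        rec2 = Receptor("t2", [ReceptorAtom(1, "CB", "SER", 1, "A", 0, 0, 0, 0.0, "C", "C")])
        lig = make_ligand("x", (-8.0,), atoms=[make_atom(1, "H", (1.0, 0, 0))])
        events = find_contacts(lig, rec1) + find_contacts(lig, rec2)
        with pytest.raises(ValueError, match="mix"):
            accumulate_profile(events)

    def test_permutation_invariance(self, rng):
        rec = _random_receptor(rng, n_residues=8, scale=4.0)
        ligands = [_random_ligand(rng, n_atoms=20, scale=4.0) for _ in range(5)]
        events = [e for lig in ligands for e in find_contacts(lig, rec)]
        shuffled = list(events)
        rng.shuffle(shuffled)
        assert accumulate_profile(events).counts == accumulate_profile(shuffled).counts

    def test_planted_multiplicities_recovered_exactly(self):
        planted = [(0, "H", 1.2, 3), (1, "O", 1.4, 2), (2, "N", 2.2, 4)]
        rec, lig, truth = generate_proximity_fixture(4, planted, seed=11)
        profile = accumulate_profile(find_contacts(lig, rec))
        for residue, element, mult, _dist in truth.contacts:
            assert profile.count(residue, element) == mult
        assert sum(profile.counts.values()) == 3 + 2 + 4


class TestTopResidues:
    def test_tie_broken_by_lower_residue_number(self):
        rec, lig, _ = generate_proximity_fixture(
            3, [(0, "H", 1.2, 5), (1, "O", 1.3, 3), (2, "N", 2.0, 3)], seed=1
        )
        profile = accumulate_profile(find_contacts(lig, rec))
        ranked = top_residues(profile, k=2)
        assert ranked[0][1] == 5
        assert ranked[1][0][1] == 2  # residue 2 beats residue 3 on the tie

    def test_k_larger_than_residues_returns_all(self):
        rec, lig, _ = generate_proximity_fixture(2, [(0, "H", 1.2, 1)], seed=1)
        profile = accumulate_profile(find_contacts(lig, rec))
        assert len(top_residues(profile, k=50)) == 1

    def test_unique_planted_residue_ranks_first_for_hydrogen(self):
        """The one residue all ligand H atoms sit near tops the H ranking."""
        rec, lig, _ = generate_proximity_fixture(
            5, [(2, "H", 1.1, 6), (4, "O", 1.2, 2)], seed=7
        )
        profile = accumulate_profile(find_contacts(lig, rec))
        (first,) = top_residues(profile, k=1, elements={"H"})
        assert first[0][1] == 3 and first[1] == 6

    def test_ranking_matches_brute_force(self, rng):
        rec = _random_receptor(rng, n_residues=12, scale=5.0)
        ligands = [_random_ligand(rng, n_atoms=25, scale=5.0) for _ in range(8)]
        events = [e for lig in ligands for e in find_contacts(lig, rec)]
        profile = accumulate_profile(events)
        got = top_residues(profile, k=5)
        totals = {}
        for (residue, _el), c in profile.counts.items():
            totals[residue] = totals.get(residue, 0) + c
        expect = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0][1]))[:5]
        assert got == expect


class TestCloud:
    def test_counts_oxygens_across_ligands(self):
        ligands = [
            make_ligand("a", (-8.0,), atoms=[make_atom(1, "O", (0, 0, 0)),
                                             make_atom(2, "O", (1, 1, 1))]),
            make_ligand("b", (-8.0,), atoms=[make_atom(1, "C", (0, 0, 0))]),
            make_ligand("c", (-8.0,), atoms=[make_atom(1, "O", (2, 2, 2), charge=-0.4)]),
        ]
        cloud = export_cloud(ligands, "O")
        assert cloud.n_points == 3
        assert -0.4 in cloud.points[:, 3]  # charges pass through unchanged

    def test_absent_element_warns_and_is_empty(self):
        ligands = [make_ligand("a", (-8.0,), atoms=[make_atom(1, "C", (0, 0, 0))])]
        with pytest.warns(UserWarning):
            cloud = export_cloud(ligands, "halogen")
        assert cloud.n_points == 0

    def test_bounding_box_matches_brute_force(self, rng):
        ligands = [_random_ligand(rng, n_atoms=30) for _ in range(4)]
        cloud = export_cloud(ligands, "N")
        lo, hi = cloud.bounding_box()
        pts = np.array([
            (a.x, a.y, a.z) for lig in ligands for a in lig.mode1_atoms
            if a.element == "N"
        ])
        assert np.allclose(lo, pts.min(axis=0)) and np.allclose(hi, pts.max(axis=0))
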