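"""Contact typing: protonation, ring planes, rule evaluation, and the
brute-force oracle over randomized scenes."""

import itertools
import json
import math
import random

import numpy as np
import pytest

from ligandkit.bound_molecules import infer_bound_molecules
from ligandkit.errors import ProtonationModeError
from ligandkit.interactions import (
    InteractionRuleSet,
    PreparedStructure,
    add_polar_hydrogens,
    compute_contacts,
    detect_ring_planes,
    interactions_report,
    vdw_radius,
)
from ligandkit.io_formats import (
    AssemblyStructure,
    AtomSite,
    ComponentAtom,
    ComponentBond,
    ComponentInstance,
    ComponentRecord,
)

from conftest import make_instance


def _hexagon_instance(comp, chain, num, kind, z=0.0, tilt=0.0):
    sites = []
    for i in range(6):
        x = 1.39 * math.cos(i * math.pi / 3)
        y = 1.39 * math.sin(i * math.pi / 3)
        # rotate about the x axis by `tilt` (degrees)
        t = math.radians(tilt)
        sites.append(AtomSite(f"C{i+1}", "C", (x, y * math.cos(t) - z * 0 + 0.0, y * math.sin(t) + z)))
    return ComponentInstance(comp, chain, str(num), kind, sites)


class TestPolarHydrogens:
    def test_carbonyl_oxygen_gets_no_hydrogen(self):
        # C=O at 1.23 Å: the oxygen is an acceptor, not a donor
        inst = make_instance("GLY", "P", 1, [
            ("C", "C", (0.0, 0.0, 0.0)), ("O", "O", (1.23, 0.0, 0.0)),
        ], kind="polymer-residue")
        out = add_polar_hydrogens(AssemblyStructure([inst]))
        assert all(a.element != "H" for a in out.instances[0].atoms)

    def test_hydroxyl_hydrogen_placed_at_096(self):
        inst = make_instance("SER", "P", 2, [
            ("CB", "C", (0.0, 0.0, 0.0)), ("OG", "O", (1.4, 0.0, 0.0)),
        ], kind="polymer-residue")
        out = add_polar_hydrogens(AssemblyStructure([inst]))
        hs = [a for a in out.instances[0].atoms if a.element == "H"]
        assert len(hs) == 1
        assert math.dist(hs[0].xyz, (1.4, 0.0, 0.0)) == pytest.approx(0.96)
        # anti to the C-O bond
        assert hs[0].xyz[0] > 1.4

    def test_idempotent_on_protonated_input(self):
        inst = make_instance("SER", "P", 2, [
            ("CB", "C", (0.0, 0.0, 0.0)), ("OG", "O", (1.4, 0.0, 0.0)),
        ], kind="polymer-residue")
        once = add_polar_hydrogens(AssemblyStructure([inst]))
        twice = add_polar_hydrogens(once)
        assert [a.atom_id for i in twice.instances for a in i.atoms] == [
            a.atom_id for i in once.instances for a in i.atoms
        ]

    def test_disabled_returns_input(self):
        asm = AssemblyStructure([make_instance("LIG", "A", 1, [("O1", "O", (0.0, 0.0, 0.0))])])
        assert add_polar_hydrogens(asm, enabled=False) is asm


class TestRingPlanes:
    def test_flat_hexagon_is_a_plane(self):
        prep = PreparedStructure(AssemblyStructure([
            _hexagon_instance("BNZ", "A", 101, "non-polymer")
        ]))
        planes = detect_ring_planes(prep)
        assert len(planes) == 1
        assert planes[0].rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(planes[0].normal) == pytest.approx(1.0)

    def test_chair_cyclohexane_is_not_planar(self):
        # ideal chair: alternating +/- 0.25 Å puckering
        sites = []
        for i in range(6):
            x = 1.46 * math.cos(i * math.pi / 3)
            y = 1.46 * math.sin(i * math.pi / 3)
            sites.append(AtomSite(f"C{i+1}", "C", (x, y, 0.25 if i % 2 else -0.25)))
        prep = PreparedStructure(AssemblyStructure([
            ComponentInstance("CHX", "A", "101", "non-polymer", sites)
        ]))
        assert detect_ring_planes(prep) == []

    def test_five_membered_aromatic_ring_detected(self):
        sites = [
            AtomSite(a, e, (1.33 * math.cos(2 * math.pi * i / 5),
                            1.33 * math.sin(2 * math.pi * i / 5), 0.0))
            for i, (a, e) in enumerate(
                [("N1", "N"), ("C2", "C"), ("N3", "N"), ("C4", "C"), ("C5", "C")]
            )
        ]
        prep = PreparedStructure(AssemblyStructure([
            ComponentInstance("IMD", "A", "101", "non-polymer", sites)
        ]))
        assert len(detect_ring_planes(prep)) == 1


class TestContactRules:
    def _hbond_scene(self, n_to_o=2.9):
        lig = make_instance("LIG", "A", 101, [
            ("N1", "N", (0.0, 0.0, 0.0)), ("C1", "C", (-1.47, 0.0, 0.0)),
        ])
        res = make_instance("GLY", "P", 1, [
            ("C", "C", (n_to_o + 1.23, 0.0, 0.0)), ("O", "O", (n_to_o, 0.0, 0.0)),
        ], kind="polymer-residue")
        comps = {"LIG": ComponentRecord("LIG",
                 atoms=[ComponentAtom("N1", "N"), ComponentAtom("C1", "C")],
                 bonds=[ComponentBond("N1", "C1")])}
        return AssemblyStructure([lig, res]), comps

    def test_distant_atoms_produce_no_contacts(self):
        asm, comps = self._hbond_scene(n_to_o=10.0)
        prep = PreparedStructure(asm, comps)
        bm = infer_bound_molecules(asm, components=comps)[0]
        assert compute_contacts(prep, bm) == []

    def test_constructed_hbond_geometry(self):
        asm, comps = self._hbond_scene()
        protonated = add_polar_hydrogens(asm, comps)
        prep = PreparedStructure(protonated, comps)
        bm = infer_bound_molecules(asm, components=comps)[0]
        subtypes = {
            (c.subtype, c.ligand.get("atom_id"), c.partner.get("atom_id"))
            for c in compute_contacts(prep, bm)
        }
        assert ("hbond", "N1", "O") in subtypes
        assert ("vdw", "N1", "O") in subtypes
        assert not any(s == "clash" for s, _, _ in subtypes)

    def test_distance_only_mode_without_hydrogens(self):
        asm, comps = self._hbond_scene()
        prep = PreparedStructure(asm, comps)
        bm = infer_bound_molecules(asm, components=comps)[0]
        subtypes = {c.subtype for c in compute_contacts(prep, bm, hbond_angles="auto")}
        assert "hbond" in subtypes

    def test_angle_mode_requires_protonation(self):
        asm, comps = self._hbond_scene()
        prep = PreparedStructure(asm, comps)
        bm = infer_bound_molecules(asm, components=comps)[0]
        with pytest.raises(ProtonationModeError):
            compute_contacts(prep, bm, hbond_angles="require")

    def test_clash_is_exclusive(self):
        lig = make_instance("LIG", "A", 101, [("C1", "C", (0.0, 0.0, 0.0))])
        res = make_instance("GLY", "P", 1, [("CA", "C", (2.0, 0.0, 0.0))],
                            kind="polymer-residue")
        asm = AssemblyStructure([lig, res])
        prep = PreparedStructure(asm)
        bm = infer_bound_molecules(asm)[0]
        contacts = compute_contacts(prep, bm)
        assert {c.subtype for c in contacts} == {"clash"}

    def test_parallel_rings_stack_face_to_face(self):
        b1 = _hexagon_instance("BNZ", "A", 101, "non-polymer")
        b2 = ComponentInstance("PHE", "P", "1", "polymer-residue", [
            AtomSite(a.atom_id, a.element, (a.xyz[0], a.xyz[1], 3.8))
            for a in b1.atoms
        ])
        asm = AssemblyStructure([b1, b2])
        prep = PreparedStructure(asm)
        bm = infer_bound_molecules(asm)[0]
        pp = [c for c in compute_contacts(prep, bm) if c.category == "plane-plane"]
        assert [c.subtype for c in pp] == ["pi-pi-FF"]
        assert pp[0].distance == pytest.approx(3.8)

    def test_perpendicular_rings_are_edge_to_edge(self):
        b1 = _hexagon_instance("BNZ", "A", 101, "non-polymer")
        sites = [
            AtomSite(f"C{i+1}", "C", (1.39 * math.cos(i * math.pi / 3) + 5.0,
                                      0.0, 1.39 * math.sin(i * math.pi / 3)))
            for i in range(6)
        ]
        b2 = ComponentInstance("PHE", "P", "1", "polymer-residue", sites)
        asm = AssemblyStructure([b1, b2])
        prep = PreparedStructure(asm)
        bm = infer_bound_molecules(asm)[0]
        pp = [c for c in compute_contacts(prep, bm) if c.category == "plane-plane"]
        assert [c.subtype for c in pp] == ["pi-pi-EE"]

    def test_cation_pi_detected(self):
        b1 = _hexagon_instance("BNZ", "A", 101, "non-polymer")
        lys = make_instance("LYS", "P", 1, [("NZ", "N", (0.0, 0.0, 3.5))],
                            kind="polymer-residue")
        comps = {"LYS-NZ": None}
        asm = AssemblyStructure([b1, lys])
        prep = PreparedStructure(asm)
        # lone N has <= 2 heavy neighbors: donor; charge unknown -> type as
        # cation via explicit record charge instead
        lys_rec = ComponentRecord("LYS", atoms=[ComponentAtom("NZ", "N", 1)])
        prep = PreparedStructure(asm, {"LYS": lys_rec})
        bm = infer_bound_molecules(asm)[0]
        ap = [c for c in compute_contacts(prep, bm) if c.category == "atom-plane"]
        assert ("cation-pi" in {c.subtype for c in ap})

    def test_metal_contact(self):
        lig = make_instance("LIG", "A", 101, [("O1", "O", (0.0, 0.0, 0.0))])
        mg = make_instance("MG", "A", 200, [("MG", "Mg", (2.1, 0.0, 0.0))])
        asm = AssemblyStructure([lig, mg])
        prep = PreparedStructure(asm)
        bm = [b for b in infer_bound_molecules(asm) if b.component_multiset["LIG"]][0]
        assert "metal" in {c.subtype for c in compute_contacts(prep, bm)}

    def test_amide_group_versus_ring(self):
        b1 = _hexagon_instance("BNZ", "A", 101, "non-polymer")
        asn = make_instance("ASN", "P", 1, [
            ("CG", "C", (0.0, 0.0, 3.5)), ("OD1", "O", (1.23, 0.0, 3.5)),
            ("ND2", "N", (-0.7, 1.1, 3.5)),
        ], kind="polymer-residue")
        asm = AssemblyStructure([b1, asn])
        prep = PreparedStructure(asm)
        bm = infer_bound_molecules(asm)[0]
        pg = [c for c in compute_contacts(prep, bm) if c.category == "plane-group"]
        assert "amide-ring" in {c.subtype for c in pg}


class TestOracleAndInvariants:
    def _random_scene(self, seed, n_ligand=8, n_env=40):
        rng = random.Random(seed)
        elements = ["C", "N", "O", "S"]
        lig_atoms = [
            (f"L{i}", rng.choice(elements),
             (rng.uniform(0, 8), rng.uniform(0, 8), rng.uniform(0, 8)))
            for i in range(n_ligand)
        ]
        env_atoms = [
            (f"E{i}", rng.choice(elements),
             (rng.uniform(-6, 14), rng.uniform(-6, 14), rng.uniform(-6, 14)))
            for i in range(n_env)
        ]
        lig = make_instance("LIG", "A", 101, lig_atoms)
        env = make_instance("ENV", "P", 1, env_atoms, kind="polymer-residue")
        return AssemblyStructure([lig, env])

    @pytest.mark.parametrize("seed", range(8))
    def test_atom_atom_contacts_match_bruteforce_all_pairs(self, seed):
        """Grid-accelerated search equals a naive all-pairs evaluation of the
        same distance rules, re-implemented here independently."""
        asm = self._random_scene(seed)
        rules = InteractionRuleSet()
        prep = PreparedStructure(asm)
        bm = infer_bound_molecules(asm)[0]
        got = {
            (c.ligand["atom_id"], c.partner["atom_id"], c.subtype)
            for c in compute_contacts(prep, bm, rules)
            if c.category == "atom-atom"
        }
        expected = set()
        idx = {a.atom_id: a for a in prep.atoms}
        lig = [a for a in prep.atoms if a.instance_key[0] == "LIG"]
        env = [a for a in prep.atoms if a.instance_key[0] == "ENV"]
        for a in lig:
            for b in env:
                if (min(a.index, b.index), max(a.index, b.index)) in prep.bonds:
                    continue
                d = math.dist(a.xyz, b.xyz)
                vdw_sum = vdw_radius(a.element) + vdw_radius(b.element)
                ta, tb = prep.types[a.index], prep.types[b.index]
                if d <= rules.metal_dist_max and (
                    ("metal" in ta and b.element in "NOS") or ("metal" in tb and a.element in "NOS")
                ):
                    expected.add((a.atom_id, b.atom_id, "metal"))
                    continue
                if d < vdw_sum - rules.clash_tolerance:
                    expected.add((a.atom_id, b.atom_id, "clash"))
                    continue
                if d <= vdw_sum + rules.vdw_tolerance:
                    expected.add((a.atom_id, b.atom_id, "vdw"))
                elif d <= rules.proximal_dist_max:
                    expected.add((a.atom_id, b.atom_id, "proximal"))
                if d <= rules.hbond_dist_max and (
                    ("donor" in ta and "acceptor" in tb) or ("donor" in tb and "acceptor" in ta)
                ):
                    expected.add((a.atom_id, b.atom_id, "hbond"))
                if d <= rules.weak_hbond_dist_max and (
                    ("weak-donor" in ta and "acceptor" in tb)
                    or ("weak-donor" in tb and "acceptor" in ta)
                ):
                    expected.add((a.atom_id, b.atom_id, "weak-hbond"))
                if d <= rules.ionic_dist_max and (
                    ("cation" in ta and "anion" in tb) or ("cation" in tb and "anion" in ta)
                ):
                    expected.add((a.atom_id, b.atom_id, "ionic"))
                if d <= rules.hydrophobic_dist_max and "hydrophobe" in ta and "hydrophobe" in tb:
                    expected.add((a.atom_id, b.atom_id, "hydrophobic"))
                if d <= rules.halogen_dist_max and (
                    ("halogen" in ta and "acceptor" in tb) or ("halogen" in tb and "acceptor" in ta)
                ):
                    expected.add((a.atom_id, b.atom_id, "halogen"))
        assert got == expected

    def test_enlarging_a_cutoff_never_removes_contacts(self):
        asm = self._random_scene(99)
        bm = infer_bound_molecules(asm)[0]
        base_rules = InteractionRuleSet()
        wide_rules = InteractionRuleSet(hydrophobic_dist_max=5.5)
        base = {
            (c.ligand["atom_id"], c.partner["atom_id"])
            for c in compute_contacts(PreparedStructure(asm), bm, base_rules)
            if c.subtype == "hydrophobic"
        }
        wide = {
            (c.ligand["atom_id"], c.partner["atom_id"])
            for c in compute_contacts(PreparedStructure(asm), bm, wide_rules)
            if c.subtype == "hydrophobic"
        }
        assert base <= wide

    def test_symmetric_subtypes_survive_role_swap(self):
        asm = self._random_scene(7, n_ligand=6, n_env=6)
        # make the environment a second non-polymer so both can play "ligand"
        inst1, inst2 = asm.instances
        inst2 = ComponentInstance(inst2.component_id, inst2.chain,
                                  inst2.residue_number, "non-polymer", inst2.atoms)
        asm = AssemblyStructure([inst1, inst2])
        prep = PreparedStructure(asm)
        bm1, bm2 = infer_bound_molecules(asm)
        def pairs(bm, subtypes):
            return {
                frozenset((c.ligand["atom_id"], c.partner["atom_id"]))
                for c in compute_contacts(prep, bm)
                if c.subtype in subtypes
            }
        for subtype in ({"vdw"}, {"hydrophobic"}, {"proximal"}):
            assert pairs(bm1, subtype) == pairs(bm2, subtype)


class TestReport:
    def test_entry_without_ligands_is_empty(self):
        env = make_instance("GLY", "P", 1, [("CA", "C", (0.0, 0.0, 0.0))],
                            kind="polymer-residue")
        prep = PreparedStructure(AssemblyStructure([env]))
        report = interactions_report(prep, [])
        assert report["bound_molecules"] == []

    def test_contact_accounting_identity_and_json_roundtrip(self):
        asm = AssemblyStructure([
            make_instance("LIG", "A", 101, [("N1", "N", (0.0, 0.0, 0.0))]),
            make_instance("GLY", "P", 1, [("O", "O", (2.9, 0.0, 0.0)),
                                          ("C", "C", (4.13, 0.0, 0.0))],
                          kind="polymer-residue"),
        ])
        prep = PreparedStructure(asm)
        bound = infer_bound_molecules(asm)
        report = interactions_report(prep, bound)
        entry = report["bound_molecules"][0]
        assert entry["n_contacts"] == sum(
            len(v) for v in entry["contacts_by_atom"].values()
        )
        assert json.loads(json.dumps(report)) == report
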