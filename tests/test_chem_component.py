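"""Molecule model: sanitization, descriptors, scaffolds, fragments,
substructure search and depiction scoring."""

import math

import pytest
from rdkit import Chem

from ligandkit.chem_component import (
    Atom,
    Bond,
    Molecule,
    brics_fragments,
    compute_descriptors,
    depiction_penalty,
    from_smiles,
    murcko_scaffold,
    sanitize,
    select_depiction,
    substructure_search,
)
from ligandkit.errors import EmptyMoleculeError, MissingCoordinatesError
from ligandkit.fixtures import FixtureSpec, gen_molecule

from conftest import subgraph_hit_oracle


class TestSanitize:
    def test_benzene_is_a_fixed_point(self, benzene_2d):
        out, report = sanitize(benzene_2d)
        assert report.converged and not report.actions
        assert [(b.a, b.b, b.order) for b in out.bonds] == [
            (b.a, b.b, b.order) for b in benzene_2d.bonds
        ]

    def test_tetravalent_nitrogen_gets_positive_charge(self):
        mol = Molecule(
            atoms=[Atom("N")] + [Atom("C") for _ in range(4)],
            bonds=[Bond(0, i, 1.0) for i in range(1, 5)],
        )
        out, report = sanitize(mol)
        assert out.atoms[0].charge == 1
        assert [a.action for a in report.actions] == ["charge-set"]

    def test_haem_like_metal_bonds_are_retyped(self):
        # Fe bonded to four pyridine-type nitrogens, each already trivalent
        # within its ring fragment: the Fe-N bonds become coordination bonds
        atoms = [Atom("Fe")]
        bonds = []
        for k in range(4):
            n = len(atoms)
            atoms += [Atom("N"), Atom("C"), Atom("C")]
            bonds += [Bond(n, n + 1, 2.0), Bond(n, n + 2, 1.0), Bond(0, n, 1.0)]
        out, report = sanitize(Molecule(atoms=atoms, bonds=bonds))
        assert report.converged
        assert {a.action for a in report.actions} == {"bond-retyped"}
        assert sum(1 for b in out.bonds if b.order == 0.0) == 4
        assert all(a.charge == 0 for a in out.atoms)

    def test_bond_order_lowering_when_no_charge_fits(self):
        # carbon with two double bonds and two single bonds (valence 6)
        mol = Molecule(
            atoms=[Atom("C"), Atom("C"), Atom("C"), Atom("C"), Atom("C")],
            bonds=[Bond(0, 1, 2.0), Bond(0, 2, 2.0), Bond(0, 3, 1.0), Bond(0, 4, 1.0)],
        )
        out, report = sanitize(mol)
        assert report.converged
        assert any(a.action == "bond-order-lowered" for a in report.actions)
        assert out.bond_order_sum(0) <= 4

    @pytest.mark.parametrize("seed", range(25))
    def test_idempotent_on_generated_molecules(self, seed):
        mol = gen_molecule(FixtureSpec(seed=seed))
        once, r1 = sanitize(mol)
        twice, r2 = sanitize(once)
        assert not r1.actions and not r2.actions  # valence-correct by construction


class TestDescriptors:
    def test_water_formula(self):
        d = compute_descriptors(Molecule(atoms=[Atom("O")]))
        assert d.formula == "H2O"

    def test_canonical_smiles_invariant_under_relabeling(self):
        mol = from_smiles("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        perm = list(range(mol.n_atoms))[::-1]
        inverse = {old: new for new, old in enumerate(perm)}
        relabeled = Molecule(
            atoms=[mol.atoms[i] for i in perm],
            bonds=[Bond(inverse[b.a], inverse[b.b], b.order, b.aromatic) for b in mol.bonds],
        )
        assert (
            compute_descriptors(mol).canonical_smiles
            == compute_descriptors(relabeled).canonical_smiles
        )

    @pytest.mark.parametrize(
        "smiles", ["CCO", "c1ccccc1", "CC(=O)O", "C1CCNCC1", "O=C(O)c1ccccc1O"]
    )
    def test_inchi_matches_reference_implementation(self, smiles):
        # independent route: RDKit InChI straight from the SMILES parse,
        # bypassing the package's graph model entirely
        expected = Chem.MolToInchi(Chem.MolFromSmiles(smiles))
        got = compute_descriptors(from_smiles(smiles))
        assert got.inchi == expected
        assert len(got.inchikey) == 27 and got.inchikey.count("-") == 2

    def test_empty_molecule_errors(self):
        with pytest.raises(EmptyMoleculeError):
            compute_descriptors(Molecule())


class TestScaffoldsAndFragments:
    def test_acyclic_molecule_has_empty_scaffold(self):
        assert murcko_scaffold(from_smiles("CCC")).n_atoms == 0

    def test_benzene_is_its_own_scaffold(self, benzene_2d):
        assert murcko_scaffold(benzene_2d).n_atoms == 6

    def test_ethylbenzene_reduces_to_benzene(self):
        scaffold = murcko_scaffold(from_smiles("CCc1ccccc1"))
        assert compute_descriptors(scaffold).canonical_smiles == compute_descriptors(
            from_smiles("c1ccccc1")
        ).canonical_smiles

    @pytest.mark.parametrize("seed", range(15))
    def test_scaffold_idempotent(self, seed):
        mol = gen_molecule(FixtureSpec(seed=seed, ring_prob=0.5))
        once = murcko_scaffold(mol)
        twice = murcko_scaffold(once)
        assert [(a.element) for a in twice.atoms] == [(a.element) for a in once.atoms]
        assert len(twice.bonds) == len(once.bonds)

    def test_uncleavable_molecule_is_its_own_fragment_set(self):
        frags = brics_fragments(from_smiles("C"))
        assert len(frags) == 1 and frags[0].heavy_indices() == [0]

    def test_ether_cleaves_keeping_the_ring(self):
        frags = brics_fragments(from_smiles("CCOc1ccccc1"))
        assert len(frags) >= 2
        ring_sizes = [len(f.heavy_indices()) for f in frags]
        assert any(s >= 6 for s in ring_sizes)

    @pytest.mark.parametrize("smiles", ["CCOc1ccccc1", "CC(=O)Nc1ccc(O)cc1", "CCCCCC"])
    def test_heavy_atom_conservation(self, smiles):
        parent = from_smiles(smiles)
        frags = brics_fragments(parent)
        parent_elems = sorted(parent.atoms[i].element for i in parent.heavy_indices())
        frag_elems = sorted(
            f.atoms[i].element for f in frags for i in f.heavy_indices()
        )
        assert frag_elems == parent_elems


class TestSubstructureSearch:
    def test_molecule_matches_itself(self):
        mol = from_smiles("CCO")
        hits = substructure_search(mol, [mol])
        assert len(hits) == 1
        idx, mapping = hits[0]
        assert idx == 0 and len(mapping) == mol.n_atoms

    def test_empty_library(self):
        assert substructure_search(from_smiles("CCO"), []) == []

    def test_benzene_in_ethylbenzene_but_not_cyclohexane(self):
        benzene = from_smiles("c1ccccc1")
        assert substructure_search(from_smiles("CCc1ccccc1"), [benzene])
        assert not substructure_search(from_smiles("C1CCCCC1"), [benzene])

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_bruteforce_oracle(self, seed):
        mol = gen_molecule(FixtureSpec(seed=seed, min_atoms=6, max_atoms=10))
        pattern = gen_molecule(FixtureSpec(seed=seed + 1000, min_atoms=2, max_atoms=4))
        got = bool(substructure_search(mol, [pattern]))
        assert got == subgraph_hit_oracle(mol, pattern)
        # a pattern cut out of the molecule itself must always hit
        sub = mol.subset(range(min(4, mol.n_atoms)))
        assert bool(substructure_search(mol, [sub])) == subgraph_hit_oracle(mol, sub) == True  # noqa: E712


class TestDepiction:
    def test_clean_hexagon_has_zero_penalty(self, benzene_2d):
        score = depiction_penalty(benzene_2d)
        assert score.penalty == 0 and score.crossings == 0 and score.overlaps == 0

    def _crossed_square(self):
        # four atoms bonded 0-1 and 2-3 with segments forced to cross
        return Molecule(
            atoms=[
                Atom("C", xy=(0.0, 0.0)), Atom("C", xy=(1.0, 1.0)),
                Atom("C", xy=(0.0, 1.0)), Atom("C", xy=(1.0, 0.0)),
            ],
            bonds=[Bond(0, 1), Bond(2, 3)],
        )

    def test_crossing_counted(self):
        score = depiction_penalty(self._crossed_square())
        assert score.crossings == 1 and score.penalty > 0

    def test_select_depiction_prefers_clean_layout(self, benzene_2d):
        crossed = self._crossed_square()
        assert select_depiction([crossed, benzene_2d]) is benzene_2d

    def test_tie_break_first_candidate(self, benzene_2d):
        clone = benzene_2d.copy()
        assert select_depiction([benzene_2d, clone]) is benzene_2d

    def test_penalty_invariant_under_uniform_scaling(self):
        crossed = self._crossed_square()
        scaled = crossed.copy()
        for a in scaled.atoms:
            a.xy = (a.xy[0] * 7.5, a.xy[1] * 7.5)
        assert depiction_penalty(crossed) == depiction_penalty(scaled)

    def test_missing_coordinates_error(self):
        with pytest.raises(MissingCoordinatesError):
            depiction_penalty(from_smiles("CC"))
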