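"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import pytest

from ligandkit.chem_component import Atom, Bond, Molecule, from_smiles
from ligandkit.io_formats import (
    AssemblyStructure,
    AtomSite,
    ComponentInstance,
    ComponentRecord,
    CovalentLink,
)


@pytest.fixture
def benzene_2d() -> Molecule:
    """Kekulized benzene with a clean hexagonal 2D layout."""
    atoms = [
        Atom("C", xy=(math.cos(i * math.pi / 3), math.sin(i * math.pi / 3)))
        for i in range(6)
    ]
    bonds = [Bond(i, (i + 1) % 6, 1.0 + (i % 2)) for i in range(6)]
    return Molecule(atoms=atoms, bonds=bonds)


def make_instance(comp_id, chain, resnum, coords_by_atom, kind="non-polymer"):
    return ComponentInstance(
        component_id=comp_id, chain=chain, residue_number=str(resnum), kind=kind,
        atoms=[AtomSite(aid, el, xyz) for aid, el, xyz in coords_by_atom],
    )


def instance_from_record(record: ComponentRecord, chain, resnum, offset=(0.0, 0.0, 0.0),
                         kind="non-polymer"):
    mol = record.to_molecule()
    sites = []
    for a in mol.atoms:
        xyz = a.xyz if a.xyz else (0.0, 0.0, 0.0)
        sites.append(AtomSite(a.atom_id, a.element,
                              tuple(c + o for c, o in zip(xyz, offset))))
    return ComponentInstance(
        component_id=record.component_id, chain=chain, residue_number=str(resnum),
        kind=kind, atoms=sites,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mcs_size_oracle(a: Molecule, b: Molecule) -> int:
    """Exhaustive maximum-common-induced-subgraph size via networkx max clique
    on the modular product graph (independent of the package's own search)."""
    ha, hb = a.heavy_indices(), b.heavy_indices()
    if not ha or not hb:
        return 0
    ea = {i: a.atoms[i].element for i in ha}
    eb = {j: b.atoms[j].element for j in hb}
    ba = {frozenset((x.a, x.b)) for x in a.bonds if x.a in ea and x.b in ea}
    bb = {frozenset((x.a, x.b)) for x in b.bonds if x.a in eb and x.b in eb}
    pairs = [(i, j) for i in ha for j in hb if ea[i] == eb[j]]
    if not pairs:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(len(pairs)))
    for p, q in itertools.combinations(range(len(pairs)), 2):
        i, j = pairs[p]
        k, l = pairs[q]
        if i == k or j == l:
            continue
        if (frozenset((i, k)) in ba) == (frozenset((j, l)) in bb):
            g.add_edge(p, q)
    _, size = nx.max_weight_clique(g, weight=None)
    return size


def subgraph_hit_oracle(mol: Molecule, pattern: Molecule) -> bool:
    """Brute-force subgraph-monomorphism check by enumerating injections
    (practical for patterns of <= 6 atoms)."""
    pn = pattern.n_atoms
    p_bonds = {
        (min(b.a, b.b), max(b.a, b.b)): (b.order, b.aromatic) for b in pattern.bonds
    }
    m_bonds = {
        (min(b.a, b.b), max(b.a, b.b)): (b.order, b.aromatic) for b in mol.bonds
    }
    candidates = [
        [i for i in range(mol.n_atoms) if mol.atoms[i].element == pattern.atoms[p].element]
        for p in range(pn)
    ]
    for assignment in itertools.product(*candidates):
        if len(set(assignment)) != pn:
            continue
        ok = True
        for (pa, pb), (order, arom) in p_bonds.items():
            key = (min(assignment[pa], assignment[pb]), max(assignment[pa], assignment[pb]))
            got = m_bonds.get(key)
            if got is None or arom != got[1] or (not arom and got[0] != order):
                ok = False
                break
        if ok:
            return True
    return False


def union_find_partition(assembly: AssemblyStructure) -> list[frozenset]:
    """Union-find over covalent links among non-polymer instances; the
    reference partition for bound-molecule inference."""
    keys = [i.key for i in assembly.instances if i.kind == "non-polymer"]
    parent = {k: k for k in keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    key_set = set(keys)
    for link in assembly.links:
        k1, k2 = tuple(link.instance_1), tuple(link.instance_2)
        if link.kind == "covalent" and k1 in key_set and k2 in key_set:
            parent[find(k1)] = find(k2)
    groups: dict = {}
    for k in keys:
        groups.setdefault(find(k), set()).add(k)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g))


def chromomycin_like_assembly():
    """Synthetic analogue of a chromomycin-type entry: six sugar/chromophore
    components covalently chained (CDR-CDR-ERI-CPH-1GL-ARI) with a separate
    coordinated Mg.  Component structures are synthetic stand-ins; only the
    connectivity topology mirrors the real entry."""
    from ligandkit.fixtures import FixtureSpec, gen_component_record, linkable_atoms

    spec = FixtureSpec(seed=42, min_atoms=6, max_atoms=9)
    comp_ids = ["CDR", "ERI", "ARI", "1GL", "CPH"]
    comps = {
        cid: gen_component_record(cid, spec, seed=100 + i)
        for i, cid in enumerate(comp_ids)
    }
    instances = [
        instance_from_record(comps["CDR"], "A", 101, (0, 0, 0)),
        instance_from_record(comps["CDR"], "A", 102, (15, 0, 0)),
        instance_from_record(comps["ERI"], "A", 103, (30, 0, 0)),
        instance_from_record(comps["ARI"], "A", 104, (45, 0, 0)),
        instance_from_record(comps["1GL"], "A", 105, (60, 0, 0)),
        instance_from_record(comps["CPH"], "A", 106, (75, 0, 0)),
    ]
    mg = make_instance("MG", "A", 107, [("MG", "Mg", (90.0, 0.0, 0.0))])
    instances.append(mg)
    la = {cid: list(linkable_atoms(comps[cid])) for cid in comp_ids}
    links = [
        CovalentLink(instances[0].key, la["CDR"][0], instances[1].key, la["CDR"][1], "covalent"),
        CovalentLink(instances[1].key, la["CDR"][0], instances[2].key, la["ERI"][0], "covalent"),
        CovalentLink(instances[3].key, la["ARI"][0], instances[4].key, la["1GL"][0], "covalent"),
        CovalentLink(instances[2].key, la["ERI"][1], instances[5].key, la["CPH"][0], "covalent"),
        CovalentLink(instances[4].key, la["1GL"][1], instances[5].key, la["CPH"][1], "covalent"),
        CovalentLink(mg.key, "MG", instances[5].key, la["CPH"][0], "metal-coordination"),
    ]
    return AssemblyStructure(instances=instances, links=links), comps
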