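"""Deterministic synthetic fixtures: molecules and assemblies with known
ground truth.

The generator exists so that every pipeline stage can be exercised without
downloading archive entries.  Molecules are valence-correct by construction
(a random spanning tree plus optional ring closures and bond-order upgrades,
all drawn within each atom's remaining valence), so sanitization of a
generated molecule is always a no-op.  Assemblies place several component
instances far apart, wire a requested number of covalent and
metal-coordination links between them, surround the first instance with a
toy protein pocket, and return the ground-truth bound-molecule partition
(computed with a union-find over the covalent edges) alongside the
structure.

Identical seed and spec give identical objects.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Optional

from .chem_component import Atom, Bond, Molecule, allowed_valences
from .io_formats import (
    AssemblyStructure,
    AtomSite,
    ComponentAtom,
    ComponentInstance,
    ComponentRecord,
    CovalentLink,
)


@dataclass
class FixtureSpec:
    seed: int = 0
    min_atoms: int = 4
    max_atoms: int = 12
    ring_prob: float = 0.3
    double_bond_prob: float = 0.2
    elements: tuple[tuple[str, float], ...] = (("C", 0.7), ("N", 0.15), ("O", 0.15))
    # assembly-level knobs
    n_instances: int = 4
    n_covalent_links: int = 2
    n_metal_links: int = 0
    pocket_residues: int = 4
    n_waters: int = 1


def _max_valence(element: str) -> int:
    vals = allowed_valences(element, 0)
    if not vals:
        raise ValueError(f"element {element!r} missing from the valence table")
    return max(vals)


def gen_molecule(spec: FixtureSpec, seed: Optional[int] = None) -> Molecule:
    """Generate one valence-correct molecule (heavy atoms only, 3D coords)."""
    rng = random.Random(spec.seed if seed is None else seed)
    if spec.min_atoms < 1 or spec.max_atoms < spec.min_atoms:
        raise ValueError("infeasible size range")
    for element, _ in spec.elements:
        if _max_valence(element) < 2 and spec.max_atoms > 1:
            raise ValueError(f"palette element {element} cannot extend a chain")
    n = rng.randint(spec.min_atoms, spec.max_atoms)
    symbols = [e for e, _ in spec.elements]
    weights = [w for _, w in spec.elements]
    elements = [rng.choices(symbols, weights)[0] for _ in range(n)]
    free = [_max_valence(e) for e in elements]
    atoms = [Atom(element=e) for e in elements]
    bonds: list[Bond] = []
    bonded: set[tuple[int, int]] = set()

    for i in range(1, n):
        parents = [j for j in range(i) if free[j] > 0]
        j = rng.choice(parents)
        bonds.append(Bond(j, i, 1.0))
        bonded.add((j, i))
        free[j] -= 1
        free[i] -= 1

    for _ in range(int(round(n * spec.ring_prob))):
        open_atoms = [i for i in range(n) if free[i] > 0]
        candidates = [
            (i, j)
            for ii, i in enumerate(open_atoms)
            for j in open_atoms[ii + 1:]
            if (min(i, j), max(i, j)) not in bonded
        ]
        if not candidates:
            break
        i, j = rng.choice(candidates)
        bonds.append(Bond(i, j, 1.0))
        bonded.add((min(i, j), max(i, j)))
        free[i] -= 1
        free[j] -= 1

    for bond in bonds:
        if free[bond.a] > 0 and free[bond.b] > 0 and rng.random() < spec.double_bond_prob:
            bond.order = 2.0
            free[bond.a] -= 1
            free[bond.b] -= 1

    # rough 3D embedding: ~1.5 Å steps from the first bonded neighbor,
    # rejecting placements closer than 1.1 Å to any existing atom
    coords: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    for i in range(1, n):
        parent = next(b.other(i) for b in bonds if i in (b.a, b.b) and b.other(i) < i)
        px, py, pz = coords[parent]
        pos = None
        for _ in range(50):
            theta = rng.uniform(0, math.pi)
            phi = rng.uniform(0, 2 * math.pi)
            cand = (
                px + 1.5 * math.sin(theta) * math.cos(phi),
                py + 1.5 * math.sin(theta) * math.sin(phi),
                pz + 1.5 * math.cos(theta),
            )
            if all(math.dist(cand, c) > 1.1 for c in coords):
                pos = cand
                break
        coords.append(pos or (px + 1.5, py, pz))
    counters: dict[str, int] = {}
    for i, atom in enumerate(atoms):
        counters[atom.element] = counters.get(atom.element, 0) + 1
        atom.atom_id = f"{atom.element.upper()}{counters[atom.element]}"
        atom.xyz = coords[i]
    return Molecule(atoms=atoms, bonds=bonds)


def gen_component_record(component_id: str, spec: FixtureSpec, seed: Optional[int] = None) -> ComponentRecord:
    mol = gen_molecule(spec, seed=seed)
    return ComponentRecord.from_molecule(component_id, mol, name=f"fixture {component_id}")


def link_capacity(record: ComponentRecord) -> dict[str, int]:
    """Spare valence per atom id: how many covalent links each atom can accept
    (an implicit hydrogen is displaced by each link bond)."""
    mol = record.to_molecule()
    out = {}
    for i, atom in enumerate(mol.atoms):
        vals = allowed_valences(atom.element, atom.charge)
        spare = int(max(vals) - mol.bond_order_sum(i)) if vals else 0
        if spare > 0:
            out[record.atoms[i].atom_id] = spare
    return out


def linkable_atoms(record: ComponentRecord) -> list[str]:
    """Atom ids with spare valence (chemically plausible link endpoints)."""
    return sorted(link_capacity(record)) or [a.atom_id for a in record.atoms]


class _UnionFind:
    """Ground-truth partition oracle over the generated covalent edges."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self) -> list[frozenset]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return sorted((frozenset(g) for g in out.values()), key=lambda g: sorted(g))


def _translate(mol: Molecule, offset) -> Molecule:
    out = mol.copy()
    for atom in out.atoms:
        atom.xyz = tuple(c + o for c, o in zip(atom.xyz, offset))
    return out


_POCKET_TEMPLATES = {
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    "LYS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("NZ", "N")],
    "ASP": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
            ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
}


def gen_assembly(
    spec: FixtureSpec, seed: Optional[int] = None
) -> tuple[AssemblyStructure, list[frozenset], dict[str, ComponentRecord]]:
    """Generate an assembly plus its expected bound-molecule partition.

    Returns ``(assembly, expected_partition, components)`` where the
    partition is the union-find ground truth over the covalent links placed
    between the non-polymer instances (metal-coordination links never
    merge), including any metal ion as a singleton.
    """
    base_seed = spec.seed if seed is None else seed
    rng = random.Random(base_seed)
    n = spec.n_instances
    n_types = rng.randint(max(1, n // 2), n)
    components = {
        f"LG{t}": gen_component_record(f"LG{t}", spec, seed=base_seed * 1009 + t)
        for t in range(n_types)
    }
    type_ids = sorted(components)

    instances: list[ComponentInstance] = []
    for i in range(n):
        comp_id = type_ids[i % n_types] if i < n_types else rng.choice(type_ids)
        mol = _translate(components[comp_id].to_molecule(), (18.0 * i, 0.0, 0.0))
        sites = [AtomSite(a.atom_id, a.element, a.xyz) for a in mol.atoms]
        instances.append(ComponentInstance(
            component_id=comp_id, chain="A", residue_number=str(101 + i),
            kind="non-polymer", atoms=sites,
        ))

    links: list[CovalentLink] = []
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng.shuffle(pairs)
    uf = _UnionFind([inst.key for inst in instances])
    capacity = {
        i: link_capacity(components[inst.component_id]) for i, inst in enumerate(instances)
    }

    def _take_link_atom(i: int) -> Optional[str]:
        open_atoms = sorted(a for a, c in capacity[i].items() if c > 0)
        if not open_atoms:
            return None
        atom = rng.choice(open_atoms)
        capacity[i][atom] -= 1
        return atom

    placed = 0
    for i, j in pairs:
        if placed >= spec.n_covalent_links:
            break
        a1, a2 = _take_link_atom(i), _take_link_atom(j)
        if a1 is None or a2 is None:
            continue
        links.append(CovalentLink(instances[i].key, a1, instances[j].key, a2, "covalent"))
        uf.union(instances[i].key, instances[j].key)
        placed += 1

    if spec.n_metal_links > 0:
        metal = ComponentInstance(
            component_id="MG", chain="A", residue_number=str(200),
            kind="non-polymer",
            atoms=[AtomSite("MG", "Mg", (-10.0, 0.0, 0.0))],
        )
        instances.append(metal)
        uf.parent[metal.key] = metal.key
        for i in rng.sample(range(n), min(spec.n_metal_links, n)):
            a = rng.choice(instances[i].atoms).atom_id
            links.append(CovalentLink(metal.key, "MG", instances[i].key, a, "metal-coordination"))
        components["MG"] = ComponentRecord(
            component_id="MG", name="magnesium ion",
            atoms=[ComponentAtom("MG", "Mg", 2, (0.0, 0.0, 0.0))],
        )

    # toy pocket around the first instance: Cα plus typed side-chain atoms
    pocket_center = instances[0].atoms[0].xyz
    residue_names = sorted(_POCKET_TEMPLATES)
    for r in range(spec.pocket_residues):
        res = residue_names[r % len(residue_names)]
        theta = rng.uniform(0, math.pi)
        phi = rng.uniform(0, 2 * math.pi)
        radius = rng.uniform(4.5, 6.0)
        base = (
            pocket_center[0] + radius * math.sin(theta) * math.cos(phi),
            pocket_center[1] + radius * math.sin(theta) * math.sin(phi),
            pocket_center[2] + radius * math.cos(theta),
        )
        sites = []
        for k, (atom_id, element) in enumerate(_POCKET_TEMPLATES[res]):
            offset = (0.0, 0.0, 0.0) if k == 0 else (
                rng.uniform(-1.5, 1.5), rng.uniform(-1.5, 1.5), rng.uniform(-1.5, 1.5)
            )
            sites.append(AtomSite(atom_id, element, tuple(b + o for b, o in zip(base, offset))))
        instances.append(ComponentInstance(
            component_id=res, chain="P", residue_number=str(r + 1),
            kind="polymer-residue", atoms=sites,
        ))

    for w in range(spec.n_waters):
        instances.append(ComponentInstance(
            component_id="HOH", chain="W", residue_number=str(w + 1), kind="water",
            atoms=[AtomSite("O", "O", (-20.0 - 5.0 * w, -20.0, 0.0))],
        ))

    assembly = AssemblyStructure(instances=instances, links=links)
    return assembly, uf.groups(), components
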