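"""Inference of complete bound molecules from component connectivity.

Non-polymer, non-water component instances of an assembly are nodes of a
graph whose edges are the declared *covalent* links; metal-coordination
links never merge components (a coordinated Mg stays a separate molecule).
Each connected component becomes one :class:`BoundMolecule` with a bmID
(bm1, bm2, ... ordered by the chain/residue of its first member).  Instances
covalently attached to a polymer chain are flagged as polymer-attached
(modified-residue-like) rather than free ligands.

Multi-component molecules get stable identifiers from a CLC registry keyed
by InChIKey: the first new molecule seen is CLC_000001, the next CLC_000002,
and a given InChIKey always maps back to the same id.  A curated PRD table
(component multiset -> PRD id) takes precedence over CLC assignment.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .chem_component import Atom, Bond, Molecule, compute_descriptors, sanitize
from .errors import UnidentifiedMoleculeError
from .io_formats import AssemblyStructure, ComponentInstance, ComponentRecord


def _residue_sort_key(key: tuple[str, str, str]):
    comp, chain, seq = key
    try:
        seq_key = (0, int(seq))
    except (TypeError, ValueError):
        seq_key = (1, seq)
    return (chain, seq_key, comp)


@dataclass
class BoundMolecule:
    bm_id: str
    instances: list[ComponentInstance]
    component_multiset: Counter
    molecule: Optional[Molecule] = None
    inchikey: Optional[str] = None
    identifier: Optional[str] = None
    polymer_attached: bool = False

    @property
    def instance_keys(self) -> set:
        return {i.key for i in self.instances}


def _fuse_molecule(
    instances: list[ComponentInstance],
    covalent_edges: list,
    components: dict[str, ComponentRecord],
) -> Optional[Molecule]:
    """Fuse per-instance component graphs into one molecule, bonding the link
    atoms with single bonds.  Returns None when a component definition is
    missing."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    offset_of: dict[tuple, dict[str, int]] = {}
    for inst in instances:
        record = components.get(inst.component_id)
        if record is None:
            return None
        base = len(atoms)
        idx = record.atom_index()
        offset_of[inst.key] = {aid: base + i for aid, i in idx.items()}
        mol = record.to_molecule()
        atoms.extend(mol.atoms)
        bonds.extend(Bond(b.a + base, b.b + base, b.order, b.aromatic) for b in mol.bonds)
    seen = {(min(b.a, b.b), max(b.a, b.b)) for b in bonds}
    for key1, atom1, key2, atom2 in covalent_edges:
        try:
            i, j = offset_of[key1][atom1], offset_of[key2][atom2]
        except KeyError:
            return None
        pair = (min(i, j), max(i, j))
        if pair not in seen:
            bonds.append(Bond(pair[0], pair[1], 1.0))
            seen.add(pair)
    fused = Molecule(atoms=atoms, bonds=bonds)
    try:
        fused, _ = sanitize(fused)
    except Exception:
        pass  # keep the raw fusion; InChIKey computation may still fail later
    return fused


def infer_bound_molecules(
    assembly: AssemblyStructure,
    components: Optional[dict[str, ComponentRecord]] = None,
) -> list[BoundMolecule]:
    """Partition the non-polymer, non-water instances into bound molecules.

    Only covalent links merge; when ``components`` provides the per-component
    chemical graphs, each bound molecule also carries the fused molecule and
    its InChIKey.
    """
    nodes = {inst.key: inst for inst in assembly.instances if inst.kind == "non-polymer"}
    polymer_keys = {
        inst.key for inst in assembly.instances if inst.kind == "polymer-residue"
    }
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    covalent_of: dict[frozenset, list] = {}
    attached_to_polymer = set()
    for link in assembly.links:
        if link.kind != "covalent":
            continue
        k1, k2 = tuple(link.instance_1), tuple(link.instance_2)
        if k1 in nodes and k2 in nodes:
            graph.add_edge(k1, k2)
            covalent_of.setdefault(frozenset((k1, k2)), []).append(
                (k1, link.atom_1, k2, link.atom_2)
            )
        elif k1 in nodes and k2 in polymer_keys:
            attached_to_polymer.add(k1)
        elif k2 in nodes and k1 in polymer_keys:
            attached_to_polymer.add(k2)

    groups = sorted(
        (sorted(group, key=_residue_sort_key) for group in nx.connected_components(graph)),
        key=lambda g: _residue_sort_key(g[0]),
    )
    out = []
    for n, group in enumerate(groups, start=1):
        instances = [nodes[k] for k in group]
        edges = [
            e
            for pair, elist in covalent_of.items()
            if pair <= set(group)
            for e in elist
        ]
        molecule = inchikey = None
        if components is not None:
            molecule = _fuse_molecule(instances, edges, components)
            if molecule is not None and molecule.n_atoms:
                try:
                    inchikey = compute_descriptors(molecule).inchikey or None
                except Exception:
                    inchikey = None
        out.append(
            BoundMolecule(
                bm_id=f"bm{n}",
                instances=instances,
                component_multiset=Counter(inst.component_id for inst in instances),
                molecule=molecule,
                inchikey=inchikey,
                polymer_attached=any(k in attached_to_polymer for k in group),
            )
        )
    return out


def free_ligands(bound: list[BoundMolecule]) -> list[BoundMolecule]:
    """Bound molecules that are not covalently attached to a polymer chain."""
    return [bm for bm in bound if not bm.polymer_attached]


# ---------------------------------------------------------------------------
# CLC registry and identifier assignment
# ---------------------------------------------------------------------------

class CLCRegistry:
    """Ordered InChIKey -> CLC id map.  Ids are CLC_ plus a six-digit ordinal,
    assigned sequentially and never reassigned."""

    def __init__(self, assignments: Optional[dict[str, str]] = None):
        self.assignments: dict[str, str] = dict(assignments or {})
        ordinals = [int(v.split("_")[1]) for v in self.assignments.values()]
        self.next_ordinal = max(ordinals, default=0) + 1

    def get_or_assign(self, inchikey: str) -> str:
        existing = self.assignments.get(inchikey)
        if existing is not None:
            return existing
        clc_id = f"CLC_{self.next_ordinal:06d}"
        self.assignments[inchikey] = clc_id
        self.next_ordinal += 1
        return clc_id

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({"assignments": self.assignments}, indent=1))

    @classmethod
    def load(cls, path) -> "CLCRegistry":
        data = json.loads(Path(path).read_text())
        return cls(assignments=data.get("assignments", {}))


def assign_identifier(
    bm: BoundMolecule,
    registry: CLCRegistry,
    prd_table: Optional[dict[frozenset, str]] = None,
) -> str:
    """Identifier for a bound molecule: its component id when it is a single
    instance; a curated PRD id when its component multiset is known; else a
    registry CLC id keyed by InChIKey."""
    if sum(bm.component_multiset.values()) == 1:
        bm.identifier = next(iter(bm.component_multiset))
        return bm.identifier
    if prd_table:
        key = frozenset(bm.component_multiset.items())
        if key in prd_table:
            bm.identifier = prd_table[key]
            return bm.identifier
    if not bm.inchikey:
        raise UnidentifiedMoleculeError(
            f"{bm.bm_id}: no InChIKey available", component_multiset=bm.component_multiset
        )
    bm.identifier = registry.get_or_assign(bm.inchikey)
    return bm.identifier
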