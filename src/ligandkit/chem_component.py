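"""Core molecule model and chemistry operations.

The :class:`Molecule` is a plain attributed graph — atoms carry an element,
a formal charge and optional 2D/3D coordinates; bonds carry an order and an
aromatic flag.  On top of it this module provides:

* valence sanitization — iteratively repairs over-valent atoms by assigning
  formal charges, retyping bonds to metals as coordination bonds, or lowering
  bond orders, with a full action report;
* standard descriptors (Hill formula, canonical SMILES, InChI, InChIKey,
  molecular weight) computed through RDKit;
* Murcko scaffolds (ring systems plus their linkers) and BRICS fragments;
* substructure search against a fragment library;
* a depiction penalty score (DPS) that grades 2D layouts by bond crossings
  and atom overlaps, and a selector that picks the best candidate layout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import BRICS, Descriptors as RDDescriptors
from rdkit import RDLogger

from .errors import (
    EmptyMoleculeError,
    IntegrityError,
    MissingCoordinatesError,
    SanitizationError,
)

RDLogger.DisableLog("rdApp.*")

# Elements treated as metals: bonds from an over-valent atom to these are
# retyped to coordination (order 0) instead of forcing a formal charge.
METALS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA",
    "V", "CR", "MO", "W", "TI", "ZR", "PT", "PD", "AG", "AU", "RU", "RH", "IR", "OS",
}

# (element, charge) -> allowed total bond-order sums.  The remainder up to the
# smallest allowed valence is filled with implicit hydrogens.
DEFAULT_VALENCE_TABLE: dict[str, dict[int, tuple[int, ...]]] = {
    "H": {0: (1,)},
    "B": {0: (3,), -1: (4,)},
    "C": {0: (4,), 1: (3,), -1: (3,)},
    "N": {0: (3,), 1: (4,), -1: (2,)},
    "O": {0: (2,), 1: (3,), -1: (1,)},
    "P": {0: (3, 5), 1: (4,)},
    "S": {0: (2, 4, 6), 1: (3,), -1: (1,)},
    "SE": {0: (2, 4, 6)},
    "F": {0: (1,), -1: (0,)},
    "CL": {0: (1,), -1: (0,)},
    "BR": {0: (1,), -1: (0,)},
    "I": {0: (1,), -1: (0,)},
}

_BOND_ORDER_TO_RDKIT = {
    0.0: Chem.BondType.ZERO,
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def _norm_element(sym: str) -> str:
    return sym.strip().capitalize() if len(sym) <= 2 else sym.strip()


@dataclass
class Atom:
    element: str
    charge: int = 0
    xy: Optional[tuple[float, float]] = None
    xyz: Optional[tuple[float, float, float]] = None
    atom_id: Optional[str] = None

    def __post_init__(self):
        self.element = _norm_element(self.element)


@dataclass
class Bond:
    a: int
    b: int
    order: float = 1.0
    aromatic: bool = False

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a


@dataclass
class Molecule:
    """Simple attributed molecular graph. Atom indices are list positions."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for bond in self.bonds:
            if bond.a == bond.b:
                raise IntegrityError(f"self-loop bond on atom {bond.a}")
            key = (min(bond.a, bond.b), max(bond.a, bond.b))
            if key in seen:
                raise IntegrityError(f"duplicate bond {key}")
            seen.add(key)
            if not (0 <= bond.a < len(self.atoms) and 0 <= bond.b < len(self.atoms)):
                raise IntegrityError(f"bond {key} references a missing atom")

    # -- graph helpers -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element not in ("H", "*")]

    def bonds_of(self, idx: int) -> list[Bond]:
        return [b for b in self.bonds if idx in (b.a, b.b)]

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds_of(idx)]

    def bond_order_sum(self, idx: int) -> float:
        return sum(1.5 if b.aromatic else b.order for b in self.bonds_of(idx))

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, charge=a.charge)
        for b in self.bonds:
            g.add_edge(b.a, b.b, order=b.order, aromatic=b.aromatic)
        return g

    def subset(self, keep: Iterable[int]) -> "Molecule":
        """Molecule induced on the given atom indices (order preserved)."""
        keep = sorted(set(keep))
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [replace(self.atoms[i]) for i in keep]
        bonds = [
            Bond(remap[b.a], remap[b.b], b.order, b.aromatic)
            for b in self.bonds
            if b.a in remap and b.b in remap
        ]
        return Molecule(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# sanitization
# ---------------------------------------------------------------------------

@dataclass
class SanitizationAction:
    atom: int
    action: str  # charge-set | bond-order-lowered | bond-retyped
    before: object
    after: object


@dataclass
class SanitizationReport:
    actions: list[SanitizationAction] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def allowed_valences(element: str, charge: int, table=None) -> tuple[int, ...]:
    table = table or DEFAULT_VALENCE_TABLE
    if element.upper() in METALS:
        return tuple(range(0, 13))  # metals: any coordination number
    entry = table.get(element) or table.get(element.upper()) or {}
    return entry.get(charge, ())


def _is_overvalent(mol: Molecule, idx: int, table) -> bool:
    atom = mol.atoms[idx]
    allowed = allowed_valences(atom.element, atom.charge, table)
    if not allowed:
        # element/charge absent from the table: unknown species, leave alone
        return False
    return mol.bond_order_sum(idx) > max(allowed)


def sanitize(
    mol: Molecule,
    valence_table: Optional[dict] = None,
    max_iter: int = 50,
) -> tuple[Molecule, SanitizationReport]:
    """Iteratively repair over-valent atoms.

    Repair precedence per offending atom: (1) retype a bond to a metal as a
    coordination bond (order 0) — covers haem-like complexes where pyrrole
    nitrogens would otherwise look tetravalent; (2) set a formal charge that
    makes the observed valence legal (e.g. tetravalent N becomes N+); (3)
    lower one bond order, highest-order bond first, lowest neighbor index
    breaking ties.  Sanitizing the output again is a no-op.
    """
    table = valence_table or DEFAULT_VALENCE_TABLE
    out = mol.copy()
    report = SanitizationReport()
    for iteration in range(1, max_iter + 1):
        report.iterations = iteration
        offenders = [i for i in range(out.n_atoms) if _is_overvalent(out, i, table)]
        if not offenders:
            report.converged = True
            return out, report
        idx = offenders[0]
        atom = out.atoms[idx]
        valence = out.bond_order_sum(idx)

        # (1) coordination bond to a metal
        metal_bonds = [
            b for b in out.bonds_of(idx)
            if out.atoms[b.other(idx)].element.upper() in METALS and (b.order > 0 or b.aromatic)
        ]
        if metal_bonds:
            bond = max(metal_bonds, key=lambda b: (1.5 if b.aromatic else b.order, -b.other(idx)))
            report.actions.append(
                SanitizationAction(idx, "bond-retyped", bond.order, 0.0)
            )
            bond.order = 0.0
            bond.aromatic = False
            continue

        # (2) formal charge consistent with the valence table
        candidates = sorted(
            (
                c for c, vals in (table.get(atom.element, {})).items()
                if vals and valence <= max(vals)
            ),
            key=lambda c: (abs(c), -c),  # smallest magnitude, positive first
        )
        if candidates and candidates[0] != atom.charge:
            new_charge = candidates[0]
            report.actions.append(
                SanitizationAction(idx, "charge-set", atom.charge, new_charge)
            )
            atom.charge = new_charge
            continue

        # (3) lower one bond order
        lowerable = [b for b in out.bonds_of(idx) if (1.5 if b.aromatic else b.order) > 1]
        if not lowerable:
            raise SanitizationError(
                f"atom {idx} ({atom.element}) cannot be repaired", report
            )
        bond = max(lowerable, key=lambda b: (1.5 if b.aromatic else b.order, -b.other(idx)))
        before = 1.5 if bond.aromatic else bond.order
        if bond.aromatic:
            bond.aromatic = False
            bond.order = 1.0
        else:
            bond.order -= 1.0
        report.actions.append(
            SanitizationAction(idx, "bond-order-lowered", before, bond.order)
        )
    raise SanitizationError(f"no convergence after {max_iter} iterations", report)


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

def to_rdkit(mol: Molecule, sanitize_rd: bool = True) -> Chem.Mol:
    """Convert to an RDKit Mol. Coordination bonds (order 0) become ZERO bonds."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        if a.element == "*":
            rd_atom = Chem.Atom(0)
        else:
            rd_atom = Chem.Atom(a.element)
        rd_atom.SetFormalCharge(a.charge)
        rw.AddAtom(rd_atom)
    for b in mol.bonds:
        btype = Chem.BondType.AROMATIC if b.aromatic else _BOND_ORDER_TO_RDKIT[float(b.order)]
        rw.AddBond(b.a, b.b, btype)
        if b.aromatic:
            rw.GetAtomWithIdx(b.a).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.b).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.a, b.b).SetIsAromatic(True)
    out = rw.GetMol()
    if sanitize_rd:
        Chem.SanitizeMol(out)
    if any(a.xyz for a in mol.atoms):
        conf = Chem.Conformer(len(mol.atoms))
        for i, a in enumerate(mol.atoms):
            x, y, z = a.xyz if a.xyz else (0.0, 0.0, 0.0)
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        out.AddConformer(conf)
    return out


def from_rdkit(rdmol: Chem.Mol) -> Molecule:
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for rd_atom in rdmol.GetAtoms():
        xyz = None
        if conf is not None:
            p = conf.GetAtomPosition(rd_atom.GetIdx())
            xyz = (p.x, p.y, p.z)
        element = rd_atom.GetSymbol() if rd_atom.GetAtomicNum() else "*"
        atoms.append(Atom(element=element, charge=rd_atom.GetFormalCharge(), xyz=xyz))
    bonds = []
    for rd_bond in rdmol.GetBonds():
        if rd_bond.GetBondType() == Chem.BondType.AROMATIC or rd_bond.GetIsAromatic():
            bonds.append(Bond(rd_bond.GetBeginAtomIdx(), rd_bond.GetEndAtomIdx(), 1.5, True))
        else:
            order = rd_bond.GetBondTypeAsDouble()
            bonds.append(Bond(rd_bond.GetBeginAtomIdx(), rd_bond.GetEndAtomIdx(), order, False))
    return Molecule(atoms=atoms, bonds=bonds)


def from_smiles(smiles: str) -> Molecule:
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return from_rdkit(rdmol)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

@dataclass
class MoleculeDescriptors:
    formula: str
    canonical_smiles: str
    inchi: str
    inchikey: str
    molecular_weight: float


def compute_descriptors(mol: Molecule) -> MoleculeDescriptors:
    """Hill formula, canonical SMILES, InChI/InChIKey and average MW.

    Implicit hydrogens are completed by RDKit's valence model, so a bare
    heavy-atom graph of water gives ``H2O``.
    """
    if mol.n_atoms == 0:
        raise EmptyMoleculeError("cannot compute descriptors of an empty molecule")
    rdmol = to_rdkit(mol)
    from rdkit.Chem import rdMolDescriptors

    inchi = Chem.MolToInchi(rdmol)
    return MoleculeDescriptors(
        formula=rdMolDescriptors.CalcMolFormula(rdmol),
        canonical_smiles=Chem.MolToSmiles(rdmol),
        inchi=inchi,
        inchikey=Chem.InchiToInchiKey(inchi) if inchi else "",
        molecular_weight=RDDescriptors.MolWt(rdmol),
    )


# ---------------------------------------------------------------------------
# scaffolds & fragments
# ---------------------------------------------------------------------------

def murcko_scaffold(mol: Molecule) -> Molecule:
    """Ring systems plus the acyclic linkers connecting them.

    Terminal atoms (degree <= 1 in the heavy-atom graph, hydrogens included
    in the pruning) are peeled off iteratively until a fixed point; acyclic
    molecules therefore reduce to the empty molecule.  Idempotent.
    """
    keep = set(range(mol.n_atoms))
    changed = True
    while changed:
        changed = False
        for i in sorted(keep):
            deg = sum(1 for j in mol.neighbors(i) if j in keep)
            if deg <= 1:
                keep.discard(i)
                changed = True
    return mol.subset(keep)


def brics_fragments(mol: Molecule) -> list[Molecule]:
    """BRICS retrosynthetic fragments (leaf decomposition).

    Attachment points appear as ``*`` marker atoms; the heavy atoms of all
    fragments partition the parent's heavy atoms.  Molecules with no
    cleavable bond come back as a singleton list containing themselves.
    """
    if mol.n_atoms == 0:
        return []
    rdmol = to_rdkit(mol)
    frags = list(BRICS.BRICSDecompose(rdmol, returnMols=True))
    return [from_rdkit(f) for f in frags]


def _edge_match(e1: dict, e2: dict) -> bool:
    if e1["aromatic"] or e2["aromatic"]:
        return e1["aromatic"] == e2["aromatic"]
    return e1["order"] == e2["order"]


def substructure_search(
    mol: Molecule, library: Sequence[Molecule]
) -> list[tuple[int, dict[int, int]]]:
    """Find every library member embedded in ``mol``.

    Matching is a subgraph monomorphism with equal elements and compatible
    bonds (aromatic matches aromatic, otherwise equal order).  Returns one
    witness mapping (library atom index -> mol atom index) per hit.
    """
    g_mol = mol.to_graph()
    hits = []
    for li, lib_mol in enumerate(library):
        if lib_mol.n_atoms == 0:
            continue
        gm = nx.algorithms.isomorphism.GraphMatcher(
            g_mol,
            lib_mol.to_graph(),
            node_match=lambda n1, n2: n1["element"] == n2["element"],
            edge_match=_edge_match,
        )
        for mapping in gm.subgraph_monomorphisms_iter():
            hits.append((li, {v: k for k, v in mapping.items()}))
            break
    return hits


# ---------------------------------------------------------------------------
# depiction scoring
# ---------------------------------------------------------------------------

@dataclass
class DepictionScore:
    penalty: float
    crossings: int
    overlaps: int


def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper crossing of open segments p1p2 and p3p4 (shared endpoints excluded)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def depiction_penalty(
    mol: Molecule,
    w_cross: float = 1.0,
    w_overlap: float = 0.5,
    min_sep: float = 0.5,
) -> DepictionScore:
    """Depiction Penalty Score: bond crossings plus too-close atom pairs.

    ``min_sep`` is relative to the median 2D bond length, so the score is
    invariant under uniform scaling of the layout.
    """
    if any(a.xy is None for a in mol.atoms):
        raise MissingCoordinatesError("depiction penalty needs 2D coordinates on every atom")
    pts = [a.xy for a in mol.atoms]
    crossings = 0
    for b1, b2 in itertools.combinations(mol.bonds, 2):
        if {b1.a, b1.b} & {b2.a, b2.b}:
            continue
        if _segments_cross(pts[b1.a], pts[b1.b], pts[b2.a], pts[b2.b]):
            crossings += 1
    import math

    lengths = sorted(
        math.dist(pts[b.a], pts[b.b]) for b in mol.bonds
    )
    median = lengths[len(lengths) // 2] if lengths else 1.0
    overlaps = sum(
        1
        for i, j in itertools.combinations(range(mol.n_atoms), 2)
        if math.dist(pts[i], pts[j]) < min_sep * median
    )
    return DepictionScore(
        penalty=w_cross * crossings + w_overlap * overlaps,
        crossings=crossings,
        overlaps=overlaps,
    )


def select_depiction(candidates: Sequence[Molecule], **weights) -> Molecule:
    """Pick the candidate 2D layout with the lowest penalty (first on ties)."""
    if not candidates:
        raise ValueError("no depiction candidates given")
    scored = [(depiction_penalty(c, **weights).penalty, i) for i, c in enumerate(candidates)]
    best = min(scored, key=lambda t: t)
    return candidates[best[1]]


# ---------------------------------------------------------------------------
# aromaticity (simple alternation model)
# ---------------------------------------------------------------------------

def perceive_aromaticity(mol: Molecule) -> Molecule:
    """Flag 6-rings with alternating single/double bonds as aromatic.

    This is a deliberately simple alternation test (plus any flags already
    present), not an electron-counting model.
    """
    out = mol.copy()
    g = out.to_graph()
    for cycle in nx.cycle_basis(g):
        if len(cycle) != 6:
            continue
        ring_bonds = []
        ok = True
        for i in range(6):
            a, b = cycle[i], cycle[(i + 1) % 6]
            bond = next(
                (bd for bd in out.bonds if {bd.a, bd.b} == {a, b}), None
            )
            if bond is None:
                ok = False
                break
            ring_bonds.append(bond)
        if not ok:
            continue
        orders = [b.order for b in ring_bonds]
        alternating = all(
            orders[i] != orders[(i + 1) % 6] and orders[i] in (1.0, 2.0)
            for i in range(6)
        )
        if alternating or all(b.aromatic for b in ring_bonds):
            for b in ring_bonds:
                b.aromatic = True
                b.order = 1.5
    return out
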