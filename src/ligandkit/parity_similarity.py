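"""PARITY-style maximum-common-substructure similarity.

The similarity of two molecules is the Jaccard coefficient over heavy atoms
of their maximum common (induced, possibly disconnected) substructure:

    score = matched / (nA + nB - matched)

where ``matched`` is the number of atom pairs in a maximum common subgraph
under element identity and bond-existence match (bond orders are ignored by
default; a strict mode also requires matching orders/aromaticity).  The MCS
is found as a maximum clique of the modular product graph of the two
heavy-atom graphs, searched with a deterministic branch-and-bound with a
greedy coloring bound and a node-expansion budget.

Also here: grouping of related ligands (same scaffold / similar / stereo-
isomers, in that priority) and InChI-layer stereoisomer detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .chem_component import Molecule, compute_descriptors, murcko_scaffold, to_rdkit

#: ligands scoring at least this are "similar" on related-ligand reports
T_RELATED = 0.6


@dataclass
class ParityResult:
    score: float
    matched_atoms: int
    mapping: dict[int, int]  # query heavy-atom index -> target heavy-atom index
    timed_out: bool = False


def _bond_map(mol: Molecule, heavy: list[int]) -> dict[tuple[int, int], tuple[float, bool]]:
    pos = {a: i for i, a in enumerate(heavy)}
    out = {}
    for b in mol.bonds:
        if b.a in pos and b.b in pos:
            i, j = pos[b.a], pos[b.b]
            out[(min(i, j), max(i, j))] = (b.order, b.aromatic)
    return out


class _CliqueSearch:
    """Deterministic max-clique branch-and-bound with an expansion budget."""

    def __init__(self, adj: list[int], budget: int):
        self.adj = adj
        self.n = len(adj)
        self.budget = budget
        self.expansions = 0
        self.best: list[int] = []
        self.timed_out = False

    def run(self) -> list[int]:
        self._greedy_seed()
        self._expand([], list(range(self.n)))
        return self.best

    def _greedy_seed(self) -> None:
        # maximal clique by repeatedly taking the highest-degree candidate;
        # provides a strong lower bound before branch-and-bound starts
        cand = (1 << self.n) - 1
        clique: list[int] = []
        while cand:
            best_v, best_deg = -1, -1
            m = cand
            while m:
                v = (m & -m).bit_length() - 1
                m &= m - 1
                deg = (self.adj[v] & cand).bit_count()
                if deg > best_deg:
                    best_v, best_deg = v, deg
            clique.append(best_v)
            cand &= self.adj[best_v]
        self.best = clique

    def _color_bound(self, cand: list[int]) -> list[tuple[int, int]]:
        # greedy coloring; returns (vertex, color#) with colors counted from 1
        colors: list[int] = []
        classes: list[int] = []  # bitmask of vertices per color class
        out = []
        for v in cand:
            placed = False
            for ci, mask in enumerate(classes):
                if not (self.adj[v] & mask):
                    classes[ci] = mask | (1 << v)
                    out.append((v, ci + 1))
                    placed = True
                    break
            if not placed:
                classes.append(1 << v)
                out.append((v, len(classes)))
        # candidates must be processed in ascending color order for the
        # len(clique)+color bound to be admissible
        out.sort(key=lambda vc: vc[1])
        return out

    def _expand(self, clique: list[int], cand: list[int]) -> None:
        if self.timed_out:
            return
        if not cand:
            if len(clique) > len(self.best):
                self.best = list(clique)
            return
        colored = self._color_bound(cand)
        for i in range(len(colored) - 1, -1, -1):
            v, color = colored[i]
            if len(clique) + color <= len(self.best):
                return
            self.expansions += 1
            if self.expansions > self.budget:
                self.timed_out = True
                return
            mask = self.adj[v]
            new_cand = [u for u, _ in colored[:i] if (mask >> u) & 1]
            clique.append(v)
            self._expand(clique, new_cand)
            clique.pop()
            if self.timed_out:
                return


def parity_upper_bound(a: Molecule, b: Molecule) -> float:
    """Exact upper bound on the PARITY score from element multisets alone:
    no common subgraph can match more atoms per element than both have."""
    from collections import Counter

    ca = Counter(a.atoms[i].element for i in a.heavy_indices())
    cb = Counter(b.atoms[i].element for i in b.heavy_indices())
    m = sum(min(ca[e], cb[e]) for e in ca)
    na, nb = sum(ca.values()), sum(cb.values())
    return m / (na + nb - m) if m else 0.0


def parity_score(
    a: Molecule,
    b: Molecule,
    strict_bonds: bool = False,
    node_budget: int = 50_000,
) -> ParityResult:
    """PARITY similarity of two molecules over their heavy atoms.

    Symmetric in its arguments; an empty molecule scores 0 with an empty
    mapping.  If the clique search exhausts ``node_budget`` expansions the
    best mapping found so far is returned with ``timed_out=True``.
    """
    heavy_a = a.heavy_indices()
    heavy_b = b.heavy_indices()
    na, nb = len(heavy_a), len(heavy_b)
    if na == 0 or nb == 0:
        return ParityResult(score=0.0, matched_atoms=0, mapping={}, timed_out=False)

    elems_a = [a.atoms[i].element for i in heavy_a]
    elems_b = [b.atoms[i].element for i in heavy_b]
    bonds_a = _bond_map(a, heavy_a)
    bonds_b = _bond_map(b, heavy_b)

    # modular product graph: vertices are element-compatible atom pairs
    pairs = [(i, j) for i in range(na) for j in range(nb) if elems_a[i] == elems_b[j]]
    if not pairs:
        return ParityResult(score=0.0, matched_atoms=0, mapping={}, timed_out=False)

    def bond_compat(ea: Optional[tuple], eb: Optional[tuple]) -> bool:
        if (ea is None) != (eb is None):
            return False
        if ea is None:
            return True
        if not strict_bonds:
            return True
        (oa, ara), (ob, arb) = ea, eb
        return (ara and arb) or (not ara and not arb and oa == ob)

    n = len(pairs)
    adj = [0] * n
    for p in range(n):
        i, j = pairs[p]
        for q in range(p + 1, n):
            k, l = pairs[q]
            if i == k or j == l:
                continue
            ea = bonds_a.get((min(i, k), max(i, k)))
            eb = bonds_b.get((min(j, l), max(j, l)))
            if bond_compat(ea, eb):
                adj[p] |= 1 << q
                adj[q] |= 1 << p

    search = _CliqueSearch(adj, node_budget)
    clique = search.run()
    matched = len(clique)
    mapping = {heavy_a[pairs[v][0]]: heavy_b[pairs[v][1]] for v in sorted(clique)}
    score = matched / (na + nb - matched) if matched else 0.0
    return ParityResult(
        score=score, matched_atoms=matched, mapping=mapping, timed_out=search.timed_out
    )


# ---------------------------------------------------------------------------
# stereoisomers
# ---------------------------------------------------------------------------

_SKELETON_LAYERS = ("c", "h", "q", "p")
_STEREO_LAYERS = ("b", "t", "m", "s")


def _inchi_layers(inchi: str) -> tuple[str, dict[str, str]]:
    body = inchi.split("=", 1)[-1]
    parts = body.split("/")
    formula = parts[1] if len(parts) > 1 else ""
    layers = {}
    for part in parts[2:]:
        if part:
            layers[part[0]] = part[1:]
    return formula, layers


def molecule_inchi(mol: Molecule) -> str:
    """InChI of a molecule; stereocenters are perceived from 3D coordinates
    when present (the graph itself carries no chirality)."""
    rdmol = to_rdkit(mol)
    if rdmol.GetNumConformers():
        Chem.AssignStereochemistryFrom3D(rdmol)
    return Chem.MolToInchi(rdmol)


def stereoisomer_check(a: Molecule, b: Molecule, inchi_a: str = None, inchi_b: str = None) -> bool:
    """True iff the two molecules share formula+connectivity InChI layers but
    differ in their stereo layers (double-bond or tetrahedral)."""
    inchi_a = inchi_a or molecule_inchi(a)
    inchi_b = inchi_b or molecule_inchi(b)
    if not inchi_a or not inchi_b or inchi_a == inchi_b:
        return False
    fa, la = _inchi_layers(inchi_a)
    fb, lb = _inchi_layers(inchi_b)
    if fa != fb:
        return False
    if any(la.get(k) != lb.get(k) for k in _SKELETON_LAYERS):
        return False
    return any(la.get(k) != lb.get(k) for k in _STEREO_LAYERS)


# ---------------------------------------------------------------------------
# related-ligand grouping
# ---------------------------------------------------------------------------

@dataclass
class ReferenceLigand:
    ligand_id: str
    molecule: Molecule
    scaffold_smiles: Optional[str] = None
    inchi: Optional[str] = None


@dataclass
class RelatedLigandReport:
    same_scaffold: list[str] = field(default_factory=list)
    similar: list[tuple[str, float]] = field(default_factory=list)
    stereoisomers: list[str] = field(default_factory=list)
    t_related: float = T_RELATED


def scaffold_descriptor(mol: Molecule) -> str:
    """Canonical SMILES of the Murcko scaffold ('' for ring-less molecules)."""
    scaffold = murcko_scaffold(mol)
    if scaffold.n_atoms == 0:
        return ""
    return compute_descriptors(scaffold).canonical_smiles


def related_ligands(
    query: Molecule,
    reference_set: Sequence[ReferenceLigand],
    t_related: float = T_RELATED,
    query_scaffold: Optional[str] = None,
    query_inchi: Optional[str] = None,
) -> RelatedLigandReport:
    """Partition a reference set into stereoisomers, same-scaffold and similar
    ligands (priority: stereoisomer > same scaffold > similar; similarity is
    PARITY score >= ``t_related``, inclusive).  Ring-less scaffolds never count
    as shared."""
    q_scaffold = query_scaffold if query_scaffold is not None else scaffold_descriptor(query)
    q_inchi = query_inchi or molecule_inchi(query)
    report = RelatedLigandReport(t_related=t_related)
    for ref in reference_set:
        ref_scaffold = (
            ref.scaffold_smiles
            if ref.scaffold_smiles is not None
            else scaffold_descriptor(ref.molecule)
        )
        if stereoisomer_check(query, ref.molecule, inchi_a=q_inchi, inchi_b=ref.inchi):
            report.stereoisomers.append(ref.ligand_id)
        elif q_scaffold and ref_scaffold == q_scaffold:
            report.same_scaffold.append(ref.ligand_id)
        else:
            result = parity_score(query, ref.molecule)
            if result.score >= t_related:
                report.similar.append((ref.ligand_id, result.score))
    return report
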