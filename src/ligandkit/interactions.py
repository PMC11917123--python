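"""Geometric protein–ligand contact typing in four categories.

Contacts between a bound molecule and its environment are classified with
CREDO-style geometric rules into atom–atom (hbond, weak-hbond, ionic, metal,
hydrophobic, halogen, vdw, proximal, clash), atom–plane (cation-pi,
donor-pi), plane–plane (pi-pi face-to-face / offset / edge-to-edge) and
plane–group (aromatic ring vs amide, guanidinium or carboxylate group)
subtypes.  All thresholds live in an editable :class:`InteractionRuleSet`.

Because experimental structures rarely resolve hydrogens, hydrogen bonds are
evaluated in a distance-only mode by default; when hydrogens are present
(e.g. after :func:`add_polar_hydrogens`) the donor–H···acceptor angle is
also required.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .bound_molecules import BoundMolecule
from .errors import ProtonationModeError
from .io_formats import AssemblyStructure, AtomSite, ComponentInstance, ComponentRecord
from .chem_component import METALS

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
}
_METAL_VDW = 2.00
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "B": 0.84,
}
_METAL_COV = 1.40
HALOGENS = {"F", "CL", "BR", "I"}


def vdw_radius(element: str) -> float:
    e = element.upper()
    if e in METALS:
        return _METAL_VDW
    return VDW_RADII.get(e, 1.80)


def covalent_radius(element: str) -> float:
    e = element.upper()
    if e in METALS:
        return _METAL_COV
    return COVALENT_RADII.get(e, 0.77)


@dataclass
class InteractionRuleSet:
    """Geometric thresholds (Å, degrees). Defaults follow CREDO conventions."""

    vdw_tolerance: float = 0.1
    clash_tolerance: float = 0.6
    hbond_dist_max: float = 3.5
    hbond_angle_min: float = 120.0
    weak_hbond_dist_max: float = 3.8
    ionic_dist_max: float = 4.0
    metal_dist_max: float = 3.0
    hydrophobic_dist_max: float = 4.5
    halogen_dist_max: float = 4.0
    proximal_dist_max: float = 5.0
    aromatic_centroid_max: float = 6.0
    cationpi_dist_max: float = 4.5
    donorpi_dist_max: float = 4.0
    plane_angle_ff_max: float = 30.0
    plane_angle_ee_min: float = 60.0
    ring_planarity_rmsd_max: float = 0.1

    def global_cutoff(self) -> float:
        return max(
            self.hbond_dist_max, self.weak_hbond_dist_max, self.ionic_dist_max,
            self.metal_dist_max, self.hydrophobic_dist_max, self.halogen_dist_max,
            self.proximal_dist_max, self.aromatic_centroid_max,
            2 * _METAL_VDW + self.vdw_tolerance,
        )


@dataclass
class RingPlane:
    members: list[int]            # prepared-atom indices
    centroid: np.ndarray
    normal: np.ndarray
    rmsd: float
    instance_key: tuple = None


@dataclass
class FunctionalGroup:
    kind: str                     # amide | guanidinium | carboxylate
    members: list[int]
    centroid: np.ndarray
    instance_key: tuple = None


@dataclass
class Contact:
    category: str                 # atom-atom | atom-plane | plane-plane | plane-group
    subtype: str
    ligand: dict
    partner: dict
    distance: float
    angle: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# structure preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedAtom:
    index: int
    instance_key: tuple
    kind: str
    atom_id: str
    element: str
    xyz: np.ndarray
    charge: int = 0


class PreparedStructure:
    """Flattened assembly with perceived bonds, atom types and ring planes."""

    def __init__(self, assembly: AssemblyStructure,
                 components: Optional[dict[str, ComponentRecord]] = None,
                 rules: Optional[InteractionRuleSet] = None):
        self.assembly = assembly
        self.rules = rules or InteractionRuleSet()
        self.atoms: list[PreparedAtom] = []
        charges: dict[tuple, dict[str, int]] = {}
        for inst in assembly.instances:
            record = (components or {}).get(inst.component_id)
            if record is not None:
                charges[inst.key] = {a.atom_id: a.charge for a in record.atoms}
            for site in inst.atoms:
                self.atoms.append(PreparedAtom(
                    index=len(self.atoms), instance_key=inst.key, kind=inst.kind,
                    atom_id=site.atom_id, element=site.element.capitalize(),
                    xyz=np.asarray(site.xyz, dtype=float),
                    charge=charges.get(inst.key, {}).get(site.atom_id, 0),
                ))
        self.coords = (
            np.vstack([a.xyz for a in self.atoms]) if self.atoms else np.zeros((0, 3))
        )
        self._index_of = {
            (a.instance_key, a.atom_id): a.index for a in self.atoms
        }
        self.bonds: set[tuple[int, int]] = set()
        self.bond_orders: dict[tuple[int, int], Optional[float]] = {}
        self._perceive_bonds(components or {})
        self.neighbors: dict[int, set[int]] = defaultdict(set)
        for i, j in self.bonds:
            self.neighbors[i].add(j)
            self.neighbors[j].add(i)
        self.types: list[set[str]] = [self._classify(a) for a in self.atoms]
        self.rings: list[RingPlane] = self._detect_all_rings()
        self.groups: list[FunctionalGroup] = self._detect_groups()
        self.has_hydrogens = any(a.element == "H" for a in self.atoms)

    # -- bonds ---------------------------------------------------------
    def _perceive_bonds(self, components: dict[str, ComponentRecord]) -> None:
        for inst in self.assembly.instances:
            record = components.get(inst.component_id)
            present = {
                a.atom_id: self._index_of[(inst.key, a.atom_id)] for a in inst.atoms
            }
            if record is not None:
                for b in record.bonds:
                    if b.atom_id_1 in present and b.atom_id_2 in present:
                        i, j = present[b.atom_id_1], present[b.atom_id_2]
                        self.bonds.add((min(i, j), max(i, j)))
                        self.bond_orders[(min(i, j), max(i, j))] = b.order
                # atoms absent from the record (e.g. placed hydrogens) bond
                # to their nearest in-range partner by distance
                known = {a.atom_id for a in record.atoms}
                for atom_id, i in present.items():
                    if atom_id in known:
                        continue
                    for atom_id2, j in present.items():
                        if i == j:
                            continue
                        a, b = self.atoms[i], self.atoms[j]
                        dmax = covalent_radius(a.element) + covalent_radius(b.element) + 0.45
                        if np.linalg.norm(a.xyz - b.xyz) <= dmax:
                            self.bonds.add((min(i, j), max(i, j)))
                            self.bond_orders.setdefault((min(i, j), max(i, j)), 1.0)
            else:
                idxs = sorted(present.values())
                for i, j in itertools.combinations(idxs, 2):
                    a, b = self.atoms[i], self.atoms[j]
                    dmax = covalent_radius(a.element) + covalent_radius(b.element) + 0.45
                    if np.linalg.norm(a.xyz - b.xyz) <= dmax:
                        self.bonds.add((i, j))
                        self.bond_orders[(i, j)] = None  # order unknown
        for link in self.assembly.links:
            i = self._index_of.get((tuple(link.instance_1), link.atom_1))
            j = self._index_of.get((tuple(link.instance_2), link.atom_2))
            if i is not None and j is not None:
                self.bonds.add((min(i, j), max(i, j)))

    # -- typing ----------------------------------------------------------
    def heavy_neighbors(self, i: int) -> list[int]:
        return [j for j in self.neighbors[i] if self.atoms[j].element != "H"]

    def h_neighbors(self, i: int) -> list[int]:
        return [j for j in self.neighbors[i] if self.atoms[j].element == "H"]

    def _detect_all_rings(self) -> list[RingPlane]:
        planes: list[RingPlane] = []
        by_instance: dict[tuple, list[int]] = defaultdict(list)
        for a in self.atoms:
            by_instance[a.instance_key].append(a.index)
        for key, idxs in by_instance.items():
            sub = nx.Graph()
            sub.add_nodes_from(idxs)
            idx_set = set(idxs)
            for i, j in self.bonds:
                if i in idx_set and j in idx_set:
                    sub.add_edge(i, j)
            for cycle in nx.minimum_cycle_basis(sub):
                if not 5 <= len(cycle) <= 7:
                    continue
                pts = self.coords[sorted(cycle)]
                centroid = pts.mean(axis=0)
                centered = pts - centroid
                _, s, vt = np.linalg.svd(centered, full_matrices=False)
                normal = vt[-1]
                rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
                if rmsd <= self.rules.ring_planarity_rmsd_max:
                    planes.append(RingPlane(
                        members=sorted(cycle), centroid=centroid,
                        normal=normal / np.linalg.norm(normal),
                        rmsd=rmsd, instance_key=key,
                    ))
        return planes

    def _classify(self, atom: PreparedAtom) -> set[str]:
        types: set[str] = set()
        el = atom.element.upper()
        if el == "H":
            return types
        heavy = self.heavy_neighbors(atom.index)
        heavy_elems = [self.atoms[j].element.upper() for j in heavy]
        if el in METALS:
            types.update({"metal", "cation"})
            return types
        if el in HALOGENS and "C" in heavy_elems:
            types.add("halogen")
        if el == "O":
            types.add("acceptor")
            if atom.charge >= 0 and len(heavy) <= 1 and not self._is_carbonyl_like(atom.index, heavy):
                types.add("donor")
        if el == "N":
            if len(heavy) <= 2:
                types.add("acceptor")
            if self._n_is_donor(atom.index, heavy):
                types.add("donor")
        if el == "S":
            if len(heavy) <= 2:
                types.add("acceptor")
            if len(heavy) <= 1:
                types.add("donor")
        if atom.charge > 0:
            types.add("cation")
        if atom.charge < 0:
            types.add("anion")
            types.discard("donor")
        if el == "N" and len(heavy) + len(self.h_neighbors(atom.index)) >= 4:
            types.add("cation")
        # guanidinium N: bonded to a C that carries three N
        if el == "N":
            for j in heavy:
                if self.atoms[j].element.upper() == "C":
                    nn = [self.atoms[k].element.upper() for k in self.heavy_neighbors(j)]
                    if nn.count("N") >= 3:
                        types.add("cation")
        # carboxylate / phosphate terminal O
        if el == "O" and len(heavy) == 1:
            j = heavy[0]
            if self.atoms[j].element.upper() in ("C", "P", "S"):
                terminal_o = sum(
                    1 for k in self.heavy_neighbors(j)
                    if self.atoms[k].element.upper() == "O" and len(self.heavy_neighbors(k)) == 1
                )
                if terminal_o >= 2:
                    types.add("anion")
                    types.discard("donor")
        if el in ("C", "S") and not any(e in ("N", "O", "F") for e in heavy_elems):
            types.add("hydrophobe")
        # weak (C-H) donor: carbon activated by an adjacent polar atom
        if el == "C" and any(e in ("N", "O") for e in heavy_elems):
            types.add("weak-donor")
        return types

    def _order_sum(self, i: int) -> Optional[float]:
        """Sum of bond orders at i, or None if any incident order is unknown."""
        total = 0.0
        for j in self.neighbors[i]:
            order = self.bond_orders.get((min(i, j), max(i, j)))
            if order is None:
                return None
            total += order
        return total

    def _is_carbonyl_like(self, i: int, heavy: list[int]) -> bool:
        """Terminal O double-bonded to its neighbor (no H to donate).

        With known bond orders: order sum >= 2.  Without them, a C–O distance
        under 1.30 Å is read as a double bond."""
        total = self._order_sum(i)
        if total is not None:
            return total >= 2.0
        if len(heavy) == 1:
            d = float(np.linalg.norm(self.atoms[i].xyz - self.atoms[heavy[0]].xyz))
            return d < 1.30
        return False

    def _n_is_donor(self, i: int, heavy: list[int]) -> bool:
        total = self._order_sum(i)
        if total is not None:
            max_val = 4 if self.atoms[i].charge > 0 else 3
            return total < max_val
        return len(heavy) <= 2

    def _detect_groups(self) -> list[FunctionalGroup]:
        groups = []
        for a in self.atoms:
            if a.element.upper() != "C":
                continue
            heavy = self.heavy_neighbors(a.index)
            elems = [self.atoms[j].element.upper() for j in heavy]
            n_n = elems.count("N")
            terminal_o = [
                j for j in heavy
                if self.atoms[j].element.upper() == "O" and len(self.heavy_neighbors(j)) == 1
            ]
            members = sorted([a.index] + heavy)
            centroid = self.coords[members].mean(axis=0)
            if n_n >= 3:
                groups.append(FunctionalGroup("guanidinium", members, centroid, a.instance_key))
            elif len(terminal_o) >= 2:
                groups.append(FunctionalGroup("carboxylate", members, centroid, a.instance_key))
            elif len(terminal_o) == 1 and n_n >= 1:
                groups.append(FunctionalGroup("amide", members, centroid, a.instance_key))
        return groups


# ---------------------------------------------------------------------------
# polar hydrogen placement
# ---------------------------------------------------------------------------

_XH_LENGTH = {"O": 0.96, "N": 1.01, "S": 1.34}


def add_polar_hydrogens(
    assembly: AssemblyStructure,
    components: Optional[dict[str, ComponentRecord]] = None,
    enabled: bool = True,
) -> AssemblyStructure:
    """Place one hydrogen on each typed donor (N/O/S with free valence) that
    lacks an explicit one, at the ideal bond length along the bisector
    opposite the existing bonds.  Already-protonated donors are untouched;
    ``enabled=False`` returns the input unchanged (externally protonated)."""
    if not enabled:
        return assembly
    prepared = PreparedStructure(assembly, components)
    new_sites: dict[tuple, list[AtomSite]] = defaultdict(list)
    for atom in prepared.atoms:
        if "donor" not in prepared.types[atom.index]:
            continue
        if prepared.h_neighbors(atom.index):
            continue
        heavy = prepared.heavy_neighbors(atom.index)
        if heavy:
            direction = -sum(
                (prepared.coords[j] - atom.xyz)
                / np.linalg.norm(prepared.coords[j] - atom.xyz)
                for j in heavy
            )
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        else:
            direction = np.array([1.0, 0.0, 0.0])
        length = _XH_LENGTH.get(atom.element.upper(), 1.0)
        pos = atom.xyz + length * direction
        new_sites[atom.instance_key].append(
            AtomSite(atom_id=f"H{atom.atom_id}", element="H", xyz=tuple(pos))
        )
    out_instances = []
    for inst in assembly.instances:
        atoms = list(inst.atoms) + new_sites.get(inst.key, [])
        out_instances.append(ComponentInstance(
            component_id=inst.component_id, chain=inst.chain,
            residue_number=inst.residue_number, kind=inst.kind, atoms=atoms,
        ))
    return AssemblyStructure(instances=out_instances, links=list(assembly.links))


def detect_ring_planes(prepared: PreparedStructure) -> list[RingPlane]:
    """Planar (RMSD <= 0.1 Å) rings of size 5–7, with centroid and unit normal."""
    return prepared.rings


# ---------------------------------------------------------------------------
# contact computation
# ---------------------------------------------------------------------------

def _grid(coords: np.ndarray, indices: Iterable[int], cell: float):
    grid: dict[tuple, list[int]] = defaultdict(list)
    for i in indices:
        key = tuple((coords[i] // cell).astype(int))
        grid[key].append(i)
    return grid


def _grid_neighbors(grid, coords, point, cell):
    cx, cy, cz = (np.asarray(point) // cell).astype(int)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                yield from grid.get((cx + dx, cy + dy, cz + dz), ())


def _atom_ref(prepared: PreparedStructure, i: int) -> dict:
    a = prepared.atoms[i]
    return {
        "component_id": a.instance_key[0], "chain": a.instance_key[1],
        "residue_number": a.instance_key[2], "atom_id": a.atom_id, "element": a.element,
    }


def _ring_ref(prepared: PreparedStructure, ring: RingPlane) -> dict:
    key = ring.instance_key
    return {
        "component_id": key[0], "chain": key[1], "residue_number": key[2],
        "atom_ids": [prepared.atoms[i].atom_id for i in ring.members],
    }


def _angle_deg(v1, v2) -> float:
    cosang = np.clip(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
    )
    return math.degrees(math.acos(cosang))


def _hbond_geometry_ok(prepared, donor, acceptor, rules, use_angles) -> bool:
    if not use_angles:
        return True
    hs = prepared.h_neighbors(donor)
    if not hs:
        return False
    dpos, apos = prepared.coords[donor], prepared.coords[acceptor]
    for h in hs:
        hpos = prepared.coords[h]
        if _angle_deg(dpos - hpos, apos - hpos) >= rules.hbond_angle_min:
            return True
    return False


def _pair_subtypes(prepared, i, j, rules, use_angles) -> list[tuple[str, Optional[float]]]:
    """Evaluate every atom–atom rule for the unordered pair (i, j)."""
    a, b = prepared.atoms[i], prepared.atoms[j]
    d = float(np.linalg.norm(a.xyz - b.xyz))
    ta, tb = prepared.types[i], prepared.types[j]
    vdw_sum = vdw_radius(a.element) + vdw_radius(b.element)
    out: list[tuple[str, Optional[float]]] = []
    # metal coordination geometry sits well inside the vdW clash range, so it
    # is typed first and never reported as a clash
    is_metal_pair = (
        ("metal" in ta and b.element.upper() in ("N", "O", "S"))
        or ("metal" in tb and a.element.upper() in ("N", "O", "S"))
    )
    if is_metal_pair and d <= rules.metal_dist_max:
        return [("metal", None)]
    if d < vdw_sum - rules.clash_tolerance:
        return [("clash", None)]
    if d <= vdw_sum + rules.vdw_tolerance:
        out.append(("vdw", None))
    elif d <= rules.proximal_dist_max:
        out.append(("proximal", None))
    if a.element != "H" and b.element != "H":
        if d <= rules.hbond_dist_max and (
            ("donor" in ta and "acceptor" in tb and _hbond_geometry_ok(prepared, i, j, rules, use_angles))
            or ("donor" in tb and "acceptor" in ta and _hbond_geometry_ok(prepared, j, i, rules, use_angles))
        ):
            out.append(("hbond", None))
        if d <= rules.weak_hbond_dist_max and (
            ("weak-donor" in ta and "acceptor" in tb)
            or ("weak-donor" in tb and "acceptor" in ta)
        ):
            out.append(("weak-hbond", None))
        if d <= rules.ionic_dist_max and (
            ("cation" in ta and "anion" in tb) or ("cation" in tb and "anion" in ta)
        ):
            out.append(("ionic", None))
        if d <= rules.hydrophobic_dist_max and "hydrophobe" in ta and "hydrophobe" in tb:
            out.append(("hydrophobic", None))
        if d <= rules.halogen_dist_max and (
            ("halogen" in ta and "acceptor" in tb) or ("halogen" in tb and "acceptor" in ta)
        ):
            out.append(("halogen", None))
    return out


def compute_contacts(
    prepared: PreparedStructure,
    bm: BoundMolecule,
    rules: Optional[InteractionRuleSet] = None,
    hbond_angles: str = "auto",
) -> list[Contact]:
    """Type every ligand–environment contact of one bound molecule.

    ``hbond_angles``: "auto" uses D–H···A angles when hydrogens are present,
    "require" errors on unprotonated input, "never" is distance-only.
    Covalently bonded pairs are skipped; a clashing pair carries only the
    clash subtype.
    """
    rules = rules or prepared.rules
    if hbond_angles == "require" and not prepared.has_hydrogens:
        raise ProtonationModeError(
            "angle-dependent H-bond mode needs a protonated structure"
        )
    use_angles = prepared.has_hydrogens if hbond_angles == "auto" else hbond_angles == "require"

    # atom-atom typing runs over heavy atoms; hydrogens only enter through
    # the donor-H-acceptor angle test
    ligand_keys = bm.instance_keys
    ligand_idx = [
        a.index for a in prepared.atoms
        if a.instance_key in ligand_keys and a.element != "H"
    ]
    env_idx = [
        a.index for a in prepared.atoms
        if a.instance_key not in ligand_keys and a.element != "H"
    ]
    cutoff = rules.global_cutoff()
    grid = _grid(prepared.coords, env_idx, cutoff)

    contacts: list[Contact] = []
    for i in ligand_idx:
        for j in _grid_neighbors(grid, prepared.coords, prepared.coords[i], cutoff):
            d = float(np.linalg.norm(prepared.coords[i] - prepared.coords[j]))
            if d > cutoff:
                continue
            if (min(i, j), max(i, j)) in prepared.bonds:
                continue
            for subtype, angle in _pair_subtypes(prepared, i, j, rules, use_angles):
                contacts.append(Contact(
                    category="atom-atom", subtype=subtype,
                    ligand=_atom_ref(prepared, i), partner=_atom_ref(prepared, j),
                    distance=round(d, 4), angle=angle,
                ))

    ligand_rings = [r for r in prepared.rings if r.instance_key in ligand_keys]
    env_rings = [r for r in prepared.rings if r.instance_key not in ligand_keys]

    # atom-plane: environment atoms vs ligand rings, ligand atoms vs env rings
    for rings, atoms, lig_is_ring in ((ligand_rings, env_idx, True), (env_rings, ligand_idx, False)):
        for ring in rings:
            for j in atoms:
                d = float(np.linalg.norm(prepared.coords[j] - ring.centroid))
                types = prepared.types[j]
                hits = []
                if "cation" in types and d <= rules.cationpi_dist_max:
                    hits.append("cation-pi")
                if "donor" in types and d <= rules.donorpi_dist_max:
                    hits.append("donor-pi")
                for subtype in hits:
                    lig_ref = _ring_ref(prepared, ring) if lig_is_ring else _atom_ref(prepared, j)
                    par_ref = _atom_ref(prepared, j) if lig_is_ring else _ring_ref(prepared, ring)
                    contacts.append(Contact(
                        category="atom-plane", subtype=subtype,
                        ligand=lig_ref, partner=par_ref, distance=round(d, 4),
                    ))

    # plane-plane
    for r1 in ligand_rings:
        for r2 in env_rings:
            d = float(np.linalg.norm(r1.centroid - r2.centroid))
            if d > rules.aromatic_centroid_max:
                continue
            theta = _angle_deg(r1.normal, r2.normal)
            theta = min(theta, 180.0 - theta)
            if theta <= rules.plane_angle_ff_max:
                subtype = "pi-pi-FF"
            elif theta >= rules.plane_angle_ee_min:
                subtype = "pi-pi-EE"
            else:
                subtype = "pi-pi-OF"
            contacts.append(Contact(
                category="plane-plane", subtype=subtype,
                ligand=_ring_ref(prepared, r1), partner=_ring_ref(prepared, r2),
                distance=round(d, 4), angle=round(theta, 2),
            ))

    # plane-group: ligand rings vs typed environment groups and vice versa
    lig_groups = [g for g in prepared.groups if g.instance_key in ligand_keys]
    env_groups = [g for g in prepared.groups if g.instance_key not in ligand_keys]
    for rings, groups, lig_is_ring in ((ligand_rings, env_groups, True), (env_rings, lig_groups, False)):
        for ring in rings:
            for grp in groups:
                d = float(np.linalg.norm(ring.centroid - grp.centroid))
                if d > rules.aromatic_centroid_max:
                    continue
                grp_ref = {
                    "component_id": grp.instance_key[0], "chain": grp.instance_key[1],
                    "residue_number": grp.instance_key[2], "group": grp.kind,
                    "atom_ids": [prepared.atoms[i].atom_id for i in grp.members],
                }
                lig_ref = _ring_ref(prepared, ring) if lig_is_ring else grp_ref
                par_ref = grp_ref if lig_is_ring else _ring_ref(prepared, ring)
                contacts.append(Contact(
                    category="plane-group", subtype=f"{grp.kind}-ring",
                    ligand=lig_ref, partner=par_ref, distance=round(d, 4),
                ))

    contacts.sort(key=lambda c: (
        c.category, str(sorted(c.ligand.items())), str(sorted(c.partner.items())), c.subtype
    ))
    return contacts


def interactions_report(
    prepared: PreparedStructure,
    bound_molecules: list[BoundMolecule],
    rules: Optional[InteractionRuleSet] = None,
) -> dict:
    """Per-bmID, per-ligand-atom contact report (stable JSON schema v1)."""
    report = {"schema_version": "1", "bound_molecules": []}
    for bm in bound_molecules:
        contacts = compute_contacts(prepared, bm, rules)
        per_atom: dict[str, list] = defaultdict(list)
        for c in contacts:
            key = c.ligand.get("atom_id") or "|".join(c.ligand.get("atom_ids", []))
            per_atom[key].append(c.to_dict())
        report["bound_molecules"].append({
            "bm_id": bm.bm_id,
            "identifier": bm.identifier,
            "components": dict(bm.component_multiset),
            "n_contacts": len(contacts),
            "contacts_by_atom": dict(sorted(per_atom.items())),
        })
    return report
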