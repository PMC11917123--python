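"""Reading and writing the mmCIF dialects and chemical export formats.

Two inputs are understood:

* **component blocks** — the ``_chem_comp_atom`` / ``_chem_comp_bond`` tables
  of a chemical component definition (ideal Cartesian coordinates in Å);
* **assembly structures** — the ``_atom_site`` table plus optional
  ``_struct_conn`` covalent/metal links of a macromolecular assembly.

All other mmCIF categories are ignored.  Exports: SDF V2000, XYZ, JSON
(loss-less) and component mmCIF.  Coordinates are Cartesian Å throughout;
residue numbers are opaque keys.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi.cif as cif

from .chem_component import Atom, Bond, Molecule
from .errors import EmptyStructureError, IntegrityError, MissingCoordinatesError, ParseError

BOND_ORDER_NAMES = {"SING": 1.0, "DOUB": 2.0, "TRIP": 3.0, "AROM": 1.5}
BOND_ORDER_TOKENS = {1.0: "SING", 2.0: "DOUB", 3.0: "TRIP", 1.5: "AROM", 0.0: "SING"}

#: Components treated as polymer residues when partitioning an assembly.
STANDARD_POLYMER_COMPONENTS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU",
}
WATER_COMPONENTS = {"HOH", "WAT", "DOD"}

LINK_KINDS = {"covale": "covalent", "metalc": "metal-coordination"}


def _missing(tok: Optional[str]) -> bool:
    return tok is None or tok in ("?", ".")


# ---------------------------------------------------------------------------
# component records
# ---------------------------------------------------------------------------

@dataclass
class ComponentAtom:
    atom_id: str
    element: str
    charge: int = 0
    xyz: Optional[tuple[float, float, float]] = None
    xy: Optional[tuple[float, float]] = None


@dataclass
class ComponentBond:
    atom_id_1: str
    atom_id_2: str
    order: float = 1.0  # 1, 2, 3 or 1.5 (aromatic)


@dataclass
class ComponentRecord:
    component_id: str
    name: str = ""
    atoms: list[ComponentAtom] = field(default_factory=list)
    bonds: list[ComponentBond] = field(default_factory=list)
    descriptors: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise IntegrityError(f"{self.component_id}: duplicate atom_ids")
        known = set(ids)
        for b in self.bonds:
            for aid in (b.atom_id_1, b.atom_id_2):
                if aid not in known:
                    raise IntegrityError(
                        f"{self.component_id}: bond references unknown atom {aid!r}"
                    )

    def atom_index(self) -> dict[str, int]:
        return {a.atom_id: i for i, a in enumerate(self.atoms)}

    def to_molecule(self) -> Molecule:
        idx = self.atom_index()
        atoms = [
            Atom(element=a.element, charge=a.charge, xyz=a.xyz, xy=a.xy, atom_id=a.atom_id)
            for a in self.atoms
        ]
        bonds = [
            Bond(idx[b.atom_id_1], idx[b.atom_id_2], b.order, b.order == 1.5)
            for b in self.bonds
        ]
        return Molecule(atoms=atoms, bonds=bonds)

    @classmethod
    def from_molecule(cls, component_id: str, mol: Molecule, name: str = "") -> "ComponentRecord":
        counters: dict[str, int] = {}
        ids = []
        for a in mol.atoms:
            if a.atom_id:
                ids.append(a.atom_id)
            else:
                counters[a.element] = counters.get(a.element, 0) + 1
                ids.append(f"{a.element.upper()}{counters[a.element]}")
        atoms = [
            ComponentAtom(ids[i], a.element, a.charge, a.xyz, a.xy)
            for i, a in enumerate(mol.atoms)
        ]
        bonds = [
            ComponentBond(ids[b.a], ids[b.b], 1.5 if b.aromatic else b.order)
            for b in mol.bonds
        ]
        return cls(component_id=component_id, name=name, atoms=atoms, bonds=bonds)


def read_component(text: str) -> ComponentRecord:
    """Parse one component definition block (``_chem_comp_atom``/``_chem_comp_bond``)."""
    try:
        doc = cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed mmCIF: {exc}") from exc
    if len(doc) == 0:
        raise ParseError("no data block found")
    block = doc[0]
    comp_id = block.find_value("_chem_comp.id") or block.name
    name = block.find_value("_chem_comp.name") or ""
    if name:
        name = cif.as_string(name)

    atoms = []
    table = block.find(
        "_chem_comp_atom.",
        ["atom_id", "type_symbol", "?charge",
         "?pdbx_model_Cartn_x_ideal", "?pdbx_model_Cartn_y_ideal", "?pdbx_model_Cartn_z_ideal"],
    )
    for row in table:
        atom_id = cif.as_string(row[0])
        element = cif.as_string(row[1])
        try:
            charge = 0 if (not row.has(2) or _missing(row[2])) else int(cif.as_int(row[2]))
            xyz = None
            if row.has(3) and not _missing(row[3]):
                xyz = (cif.as_number(row[3]), cif.as_number(row[4]), cif.as_number(row[5]))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"bad _chem_comp_atom row for atom {atom_id!r}: {exc}") from exc
        atoms.append(ComponentAtom(atom_id=atom_id, element=element, charge=charge, xyz=xyz))

    bonds = []
    btable = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"])
    for row in btable:
        order_tok = cif.as_string(row[2]).upper()
        if order_tok not in BOND_ORDER_NAMES:
            raise ParseError(
                f"bad _chem_comp_bond row {cif.as_string(row[0])}-{cif.as_string(row[1])}: "
                f"unknown order {order_tok!r}"
            )
        bonds.append(
            ComponentBond(cif.as_string(row[0]), cif.as_string(row[1]), BOND_ORDER_NAMES[order_tok])
        )

    descriptors = {}
    dtable = block.find("_pdbx_chem_comp_descriptor.", ["type", "descriptor"])
    for row in dtable:
        descriptors[cif.as_string(row[0])] = cif.as_string(row[1])

    return ComponentRecord(
        component_id=comp_id, name=name, atoms=atoms, bonds=bonds, descriptors=descriptors
    )


def _component_to_mmcif(record: ComponentRecord) -> str:
    doc = cif.Document()
    block = doc.add_new_block(record.component_id)
    block.set_pair("_chem_comp.id", cif.quote(record.component_id))
    block.set_pair("_chem_comp.name", cif.quote(record.name or "?"))
    loop = block.init_loop(
        "_chem_comp_atom.",
        ["comp_id", "atom_id", "type_symbol", "charge",
         "pdbx_model_Cartn_x_ideal", "pdbx_model_Cartn_y_ideal", "pdbx_model_Cartn_z_ideal"],
    )
    for a in record.atoms:
        xyz = ["?"] * 3 if a.xyz is None else [f"{v:.3f}" for v in a.xyz]
        loop.add_row([record.component_id, cif.quote(a.atom_id), a.element.upper(),
                      str(a.charge), *xyz])
    if record.bonds:
        loop = block.init_loop(
            "_chem_comp_bond.", ["comp_id", "atom_id_1", "atom_id_2", "value_order"]
        )
        for b in record.bonds:
            loop.add_row([record.component_id, cif.quote(b.atom_id_1), cif.quote(b.atom_id_2),
                          BOND_ORDER_TOKENS[b.order]])
    if record.descriptors:
        loop = block.init_loop("_pdbx_chem_comp_descriptor.", ["type", "descriptor"])
        for k, v in record.descriptors.items():
            loop.add_row([cif.quote(k), cif.quote(v)])
    return doc.as_string()


def _component_to_sdf(record: ComponentRecord) -> str:
    if any(a.xyz is None for a in record.atoms):
        raise MissingCoordinatesError(f"{record.component_id}: SDF export needs 3D coordinates")
    lines = [record.component_id, "  ligandkit", ""]
    lines.append(
        f"{len(record.atoms):3d}{len(record.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in record.atoms:
        x, y, z = a.xyz
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    idx = {a.atom_id: i + 1 for i, a in enumerate(record.atoms)}
    sdf_order = {1.0: 1, 2.0: 2, 3.0: 3, 1.5: 4}
    for b in record.bonds:
        lines.append(f"{idx[b.atom_id_1]:3d}{idx[b.atom_id_2]:3d}{sdf_order[b.order]:3d}  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(record.atoms) if a.charge]
    for chunk_start in range(0, len(charged), 8):
        chunk = charged[chunk_start:chunk_start + 8]
        lines.append("M  CHG" + f"{len(chunk):3d}" + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def _component_to_xyz(record: ComponentRecord) -> str:
    if any(a.xyz is None for a in record.atoms):
        raise MissingCoordinatesError(f"{record.component_id}: XYZ export needs 3D coordinates")
    lines = [str(len(record.atoms)), record.component_id]
    for a in record.atoms:
        x, y, z = a.xyz
        lines.append(f"{a.element} {x:.4f} {y:.4f} {z:.4f}")
    return "\n".join(lines) + "\n"


def component_to_json_dict(record: ComponentRecord) -> dict:
    return {
        "component_id": record.component_id,
        "name": record.name,
        "atoms": [
            {"atom_id": a.atom_id, "element": a.element, "charge": a.charge,
             "xyz": list(a.xyz) if a.xyz else None, "xy": list(a.xy) if a.xy else None}
            for a in record.atoms
        ],
        "bonds": [
            {"atom_id_1": b.atom_id_1, "atom_id_2": b.atom_id_2, "order": b.order}
            for b in record.bonds
        ],
        "descriptors": record.descriptors,
    }


def component_from_json_dict(d: dict) -> ComponentRecord:
    return ComponentRecord(
        component_id=d["component_id"],
        name=d.get("name", ""),
        atoms=[
            ComponentAtom(
                a["atom_id"], a["element"], a.get("charge", 0),
                tuple(a["xyz"]) if a.get("xyz") else None,
                tuple(a["xy"]) if a.get("xy") else None,
            )
            for a in d["atoms"]
        ],
        bonds=[ComponentBond(b["atom_id_1"], b["atom_id_2"], b["order"]) for b in d["bonds"]],
        descriptors=d.get("descriptors", {}),
    )


def write_component(record: ComponentRecord, fmt: str = "component-mmCIF") -> str:
    """Serialize a component record as SDF, XYZ, JSON or component mmCIF."""
    fmt = fmt.lower()
    if fmt == "sdf":
        return _component_to_sdf(record)
    if fmt == "xyz":
        return _component_to_xyz(record)
    if fmt == "json":
        return json.dumps(component_to_json_dict(record), indent=1)
    if fmt in ("component-mmcif", "mmcif", "cif"):
        return _component_to_mmcif(record)
    raise ValueError(f"unknown export format {fmt!r}")


# ---------------------------------------------------------------------------
# assembly structures
# ---------------------------------------------------------------------------

@dataclass
class AtomSite:
    atom_id: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class ComponentInstance:
    component_id: str
    chain: str
    residue_number: str
    kind: str  # polymer-residue | non-polymer | water
    atoms: list[AtomSite] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.component_id, self.chain, self.residue_number)


@dataclass
class CovalentLink:
    instance_1: tuple[str, str, str]
    atom_1: str
    instance_2: tuple[str, str, str]
    atom_2: str
    kind: str = "covalent"  # covalent | metal-coordination | other


@dataclass
class AssemblyStructure:
    instances: list[ComponentInstance] = field(default_factory=list)
    links: list[CovalentLink] = field(default_factory=list)

    def __post_init__(self):
        keys = [i.key for i in self.instances]
        if len(keys) != len(set(keys)):
            raise IntegrityError("duplicate instance keys in assembly")
        by_key = {k: inst for k, inst in zip(keys, self.instances)}
        for link in self.links:
            for key, atom in ((link.instance_1, link.atom_1), (link.instance_2, link.atom_2)):
                inst = by_key.get(tuple(key))
                if inst is None:
                    raise IntegrityError(f"link references unknown instance {key}")
                if atom not in {a.atom_id for a in inst.atoms}:
                    raise IntegrityError(f"link references unknown atom {atom!r} of {key}")

    def instance(self, key) -> ComponentInstance:
        key = tuple(key)
        for inst in self.instances:
            if inst.key == key:
                return inst
        raise KeyError(key)

    def non_polymer_instances(self) -> list[ComponentInstance]:
        return [i for i in self.instances if i.kind == "non-polymer"]


def _classify_kind(comp_id: str, polymer_components, waters) -> str:
    if comp_id in waters:
        return "water"
    if comp_id in polymer_components:
        return "polymer-residue"
    return "non-polymer"


def read_assembly(
    text: str,
    polymer_components=STANDARD_POLYMER_COMPONENTS,
    waters=WATER_COMPONENTS,
) -> AssemblyStructure:
    """Parse an assembly: ``_atom_site`` plus optional ``_struct_conn`` links.

    Instances are partitioned into polymer-residue / non-polymer / water by
    component identity against ``polymer_components``; unknown link kinds are
    kept with kind ``other`` and a warning.
    """
    try:
        doc = cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed mmCIF: {exc}") from exc
    if len(doc) == 0:
        raise ParseError("no data block found")
    block = doc[0]

    table = block.find(
        "_atom_site.",
        ["label_comp_id", "auth_asym_id", "auth_seq_id", "label_atom_id",
         "type_symbol", "Cartn_x", "Cartn_y", "Cartn_z"],
    )
    instances: dict[tuple, ComponentInstance] = {}
    for row in table:
        comp = cif.as_string(row[0])
        chain = cif.as_string(row[1])
        seq = cif.as_string(row[2])
        key = (comp, chain, seq)
        if key not in instances:
            instances[key] = ComponentInstance(
                component_id=comp, chain=chain, residue_number=seq,
                kind=_classify_kind(comp, polymer_components, waters),
            )
        try:
            xyz = (cif.as_number(row[5]), cif.as_number(row[6]), cif.as_number(row[7]))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"bad _atom_site row for {key}: {exc}") from exc
        instances[key].atoms.append(
            AtomSite(atom_id=cif.as_string(row[3]), element=cif.as_string(row[4]), xyz=xyz)
        )
    if not instances:
        raise EmptyStructureError("assembly has no atom sites")

    links = []
    ltable = block.find(
        "_struct_conn.",
        ["conn_type_id",
         "ptnr1_label_comp_id", "ptnr1_auth_asym_id", "ptnr1_auth_seq_id", "ptnr1_label_atom_id",
         "ptnr2_label_comp_id", "ptnr2_auth_asym_id", "ptnr2_auth_seq_id", "ptnr2_label_atom_id"],
    )
    for row in ltable:
        raw_kind = cif.as_string(row[0]).lower()
        kind = LINK_KINDS.get(raw_kind)
        if kind is None:
            warnings.warn(f"unknown link kind {raw_kind!r}; recorded as 'other'")
            kind = "other"
        links.append(
            CovalentLink(
                instance_1=(cif.as_string(row[1]), cif.as_string(row[2]), cif.as_string(row[3])),
                atom_1=cif.as_string(row[4]),
                instance_2=(cif.as_string(row[5]), cif.as_string(row[6]), cif.as_string(row[7])),
                atom_2=cif.as_string(row[8]),
                kind=kind,
            )
        )
    return AssemblyStructure(instances=list(instances.values()), links=links)


def write_assembly(assembly: AssemblyStructure) -> str:
    """Serialize an assembly back to the same mmCIF subset ``read_assembly`` reads."""
    doc = cif.Document()
    block = doc.add_new_block("assembly")
    loop = block.init_loop(
        "_atom_site.",
        ["group_PDB", "id", "label_atom_id", "type_symbol", "label_comp_id",
         "auth_asym_id", "auth_seq_id", "Cartn_x", "Cartn_y", "Cartn_z"],
    )
    serial = 0
    for inst in assembly.instances:
        group = "ATOM" if inst.kind == "polymer-residue" else "HETATM"
        for a in inst.atoms:
            serial += 1
            loop.add_row([
                group, str(serial), cif.quote(a.atom_id), a.element.upper(),
                inst.component_id, inst.chain, inst.residue_number,
                f"{a.xyz[0]:.3f}", f"{a.xyz[1]:.3f}", f"{a.xyz[2]:.3f}",
            ])
    if assembly.links:
        inverse = {v: k for k, v in LINK_KINDS.items()}
        loop = block.init_loop(
            "_struct_conn.",
            ["id", "conn_type_id",
             "ptnr1_label_comp_id", "ptnr1_auth_asym_id", "ptnr1_auth_seq_id", "ptnr1_label_atom_id",
             "ptnr2_label_comp_id", "ptnr2_auth_asym_id", "ptnr2_auth_seq_id", "ptnr2_label_atom_id"],
        )
        for i, link in enumerate(assembly.links, start=1):
            loop.add_row([
                f"link{i}", inverse.get(link.kind, "?"),
                link.instance_1[0], link.instance_1[1], link.instance_1[2], cif.quote(link.atom_1),
                link.instance_2[0], link.instance_2[1], link.instance_2[2], cif.quote(link.atom_2),
            ])
    return doc.as_string()
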