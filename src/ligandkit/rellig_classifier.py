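"""Functional-role classification of bound ligands.

Each ligand, in the context of the protein it is bound to, may be annotated
with any subset of three non-exclusive roles:

* **cofactor-like** — a two-stage similarity screen against curated cofactor
  classes: the ligand must reach the class's own threshold against the class
  *template* molecule, then again against the class *representative*, and the
  entry must carry an EC number belonging to the class (prefix matching, so a
  class list entry ``1.1.1`` covers ``1.1.1.1``).  A ligand that passes both
  similarity stages but lacks a matching EC number is flagged for manual
  review instead.
* **reactant-like** — PARITY similarity ≥ 0.7 (inclusive) to any participant
  of a reaction catalyzed by the bound protein.
* **drug-like** — the ligand (matched by InChIKey, falling back to its id)
  is a drug whose pharmacologically active targets include the protein.

Curated reference tables (cofactor classes with template/representative
SMILES, reactions with participant SMILES, drug-target pairs) are plain JSON
files; a small illustrative set ships with the package for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .chem_component import Molecule, compute_descriptors, from_smiles
from .parity_similarity import parity_score, parity_upper_bound

T_REACTANT = 0.7


@dataclass
class CofactorClass:
    name: str
    template: Molecule
    representative: Molecule
    threshold: float
    ec_set: tuple[str, ...]


@dataclass
class ReactionRecord:
    reaction_id: str
    participants: list[tuple[str, Molecule]]  # (participant name, structure)
    protein_accessions: frozenset[str]


@dataclass
class DrugTargetTable:
    #: drug key (InChIKey or ligand id) -> set of active-target accessions
    targets: dict[str, frozenset[str]] = field(default_factory=dict)
    #: optional friendly names per drug key
    names: dict[str, str] = field(default_factory=dict)


@dataclass
class Evidence:
    role: str
    matched: str
    score: Optional[float] = None
    ec: Optional[str] = None


@dataclass
class FunctionalAnnotation:
    ligand_id: str
    protein_accession: Optional[str]
    roles: set[str] = field(default_factory=set)
    manual_review: bool = False
    evidence: list[Evidence] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference-table loading
# ---------------------------------------------------------------------------

def _read_reference(path_or_name) -> dict:
    p = Path(path_or_name)
    if p.exists():
        return json.loads(p.read_text())
    return json.loads(
        resources.files("ligandkit.data").joinpath(str(path_or_name)).read_text()
    )


def load_cofactor_classes(source="cofactor_classes.json") -> list[CofactorClass]:
    data = _read_reference(source)
    return [
        CofactorClass(
            name=c["name"],
            template=from_smiles(c["template_smiles"]),
            representative=from_smiles(c["representative_smiles"]),
            threshold=float(c["threshold"]),
            ec_set=tuple(c["ec"]),
        )
        for c in data["classes"]
    ]


def load_reactions(source="reactions.json") -> list[ReactionRecord]:
    data = _read_reference(source)
    return [
        ReactionRecord(
            reaction_id=r["reaction_id"],
            participants=[(p["name"], from_smiles(p["smiles"])) for p in r["participants"]],
            protein_accessions=frozenset(r["protein_accessions"]),
        )
        for r in data["reactions"]
    ]


def load_drug_targets(source="drug_targets.json") -> DrugTargetTable:
    data = _read_reference(source)
    table = DrugTargetTable()
    for d in data["drugs"]:
        for key in filter(None, (d.get("inchikey"), d.get("ligand_id"))):
            table.targets[key] = frozenset(d["targets"])
            if d.get("name"):
                table.names[key] = d["name"]
    return table


# ---------------------------------------------------------------------------
# EC matching
# ---------------------------------------------------------------------------

def ec_fields(ec: str) -> list[str]:
    """Split an EC number, dropping trailing wildcard fields ('-' or '')."""
    fields = ec.strip().split(".")
    while fields and fields[-1] in ("-", "", "*"):
        fields.pop()
    return fields


def ec_matches(class_ec: str, entry_ec: str) -> bool:
    """Prefix semantics: class entry '1.1.1' (or '1.1.1.-') covers '1.1.1.x'."""
    cls = ec_fields(class_ec)
    ent = ec_fields(entry_ec)
    return bool(cls) and len(cls) <= len(ent) and ent[: len(cls)] == cls


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def classify_cofactor(
    ligand: Molecule,
    entry_ecs: set[str],
    classes: Sequence[CofactorClass],
) -> tuple[bool, bool, list[Evidence]]:
    """Two-stage cofactor screen.

    Returns (is_cofactor_like, manual_review, evidence).  Manual review is
    raised when both similarity stages pass for some class but the entry has
    no EC number of that class.
    """
    evidence: list[Evidence] = []
    manual = False
    for cls in classes:
        # element-multiset bound lets hopeless comparisons be skipped exactly
        if parity_upper_bound(ligand, cls.template) < cls.threshold:
            continue
        s1 = parity_score(ligand, cls.template).score
        if s1 < cls.threshold:
            continue
        if parity_upper_bound(ligand, cls.representative) < cls.threshold:
            continue
        s2 = parity_score(ligand, cls.representative).score
        if s2 < cls.threshold:
            continue
        matched_ec = next(
            (e for e in sorted(entry_ecs) for c in cls.ec_set if ec_matches(c, e)), None
        )
        if matched_ec is not None:
            evidence.append(Evidence("cofactor-like", cls.name, max(s1, s2), matched_ec))
        else:
            manual = True
            evidence.append(Evidence("cofactor-candidate", cls.name, max(s1, s2), None))
    is_cofactor = any(e.role == "cofactor-like" for e in evidence)
    return is_cofactor, (manual and not is_cofactor), evidence


def classify_reactant(
    ligand: Molecule,
    protein_accession: Optional[str],
    reactions: Sequence[ReactionRecord],
    t_reactant: float = T_REACTANT,
) -> tuple[bool, list[Evidence]]:
    """Reactant-like iff best PARITY score against a participant of a reaction
    mapped to this protein is >= ``t_reactant`` (inclusive)."""
    best: Optional[Evidence] = None
    for reaction in reactions:
        if protein_accession not in reaction.protein_accessions:
            continue
        for name, participant in reaction.participants:
            if (
                best is not None
                and parity_upper_bound(ligand, participant) <= best.score
            ):
                continue
            score = parity_score(ligand, participant).score
            if best is None or score > best.score:
                best = Evidence("reactant-like", f"{reaction.reaction_id}:{name}", score)
    if best is not None and best.score >= t_reactant:
        return True, [best]
    return False, []


def classify_drug(
    ligand: Molecule,
    protein_accession: Optional[str],
    table: DrugTargetTable,
    ligand_id: Optional[str] = None,
    inchikey: Optional[str] = None,
) -> tuple[bool, list[Evidence]]:
    """Drug-like iff the ligand is a tabulated drug and the protein is one of
    its pharmacologically active targets."""
    if inchikey is None and ligand.n_atoms:
        inchikey = compute_descriptors(ligand).inchikey
    for key in filter(None, (inchikey, ligand_id)):
        targets = table.targets.get(key)
        if targets and protein_accession in targets:
            return True, [Evidence("drug-like", table.names.get(key, key))]
    return False, []


@dataclass
class EntryReferences:
    cofactor_classes: Sequence[CofactorClass] = ()
    reactions: Sequence[ReactionRecord] = ()
    drug_targets: DrugTargetTable = field(default_factory=DrugTargetTable)


def annotate_entry(
    ligands: Sequence[tuple[str, Molecule]],
    protein_accessions: Sequence[str],
    entry_ecs: set[str],
    references: EntryReferences,
) -> list[FunctionalAnnotation]:
    """Run all three classifiers for every (ligand, protein accession) pair;
    roles are unioned and the result is deterministic and idempotent."""
    annotations = []
    accessions = list(protein_accessions) or [None]
    for ligand_id, mol in ligands:
        inchikey = compute_descriptors(mol).inchikey if mol.n_atoms else None
        for accession in accessions:
            ann = FunctionalAnnotation(ligand_id=ligand_id, protein_accession=accession)
            is_cof, manual, ev = classify_cofactor(mol, entry_ecs, references.cofactor_classes)
            if is_cof:
                ann.roles.add("cofactor-like")
            ann.manual_review = manual
            ann.evidence.extend(ev)
            is_rx, ev = classify_reactant(mol, accession, references.reactions)
            if is_rx:
                ann.roles.add("reactant-like")
            ann.evidence.extend(ev)
            is_drug, ev = classify_drug(
                mol, accession, references.drug_targets, ligand_id=ligand_id, inchikey=inchikey
            )
            if is_drug:
                ann.roles.add("drug-like")
            ann.evidence.extend(ev)
            annotations.append(ann)
    return annotations
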