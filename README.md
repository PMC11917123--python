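# ligandkit

A small-molecule analysis toolkit for macromolecular structures, aimed at
structural bioinformaticians and cheminformaticians who work with ligands in
protein/nucleic-acid assemblies. It covers the desk-scale version of an
archive ligand pipeline:

* **Chemical components** — parse component definitions (atom/bond tables of
  the component mmCIF dialect), sanitize unusual valences, compute descriptors
  (Hill formula, canonical SMILES, InChI/InChIKey, molecular weight), Murcko
  scaffolds, BRICS fragments, substructure search, and score 2D depictions.
* **PARITY similarity** — atom-level maximum-common-substructure similarity:
  `score = |MCS| / (n_A + n_B − |MCS|)` over heavy atoms, where the MCS is the
  maximum common (induced, possibly disconnected) subgraph under element
  matching. Found as a maximum clique of the modular product graph with a
  deterministic branch-and-bound and a node-expansion budget.
* **Bound molecules (CLC)** — infer complete bound molecules from the covalent
  connectivity of non-polymer component instances in an assembly, assign
  per-entry `bm1, bm2, …` identifiers, and register multi-component molecules
  under stable `CLC_NNNNNN` identifiers keyed by InChIKey (covalently linked
  components). Metal coordination never merges components.
* **Contacts** — geometric typing of ligand–environment interactions in four
  categories (atom–atom, atom–plane, plane–plane, plane–group) with
  CREDO-style distance/angle rules: hydrogen bonds, weak hydrogen bonds,
  ionic, metal, hydrophobic, halogen, van der Waals, proximal, clash,
  cation-π, donor-π, π-stacking (face/offset/edge) and ring–group contacts,
  plus naive polar-hydrogen placement for structures without hydrogens.
* **Functional roles** — classify each bound ligand in its protein context as
  cofactor-like (two-stage similarity screen against curated cofactor classes
  gated by the entry's EC numbers), reactant-like (similarity ≥ 0.7 to a
  participant of a reaction catalyzed by the bound protein), and/or drug-like
  (InChIKey match to a drug whose pharmacologically active targets include
  the protein).
* **Aggregation & validation** — per-atom relative interaction frequencies
  (the ligand-page heatmap numbers, both normalizations) and standard
  ligand-quality flags: |Z| > 2.0 geometric outliers and RMSZ, torsion local
  density < 5%, ring torsion RMSD > 60°, RSCC < 0.8, RSR > 0.4.
* **Fixtures** — a deterministic generator of valence-correct molecules and
  assemblies with known ground-truth partitions, so every stage is testable
  without downloading archive entries.

## Worked example

Generate a synthetic assembly (three ligand instances, one covalent link, a
coordinated metal, and a toy binding pocket), then infer its bound molecules:

```bash
$ ligandkit fixtures --seed 3 --out-dir fx
$ ligandkit component fx/LG0.cif --describe
{
 "component_id": "LG0",
 "formula": "C5H9N",
 "smiles": "CC12CC1CN2",
 "inchikey": "JGUZCJUICVFLCZ-BRJRFNKRSA-N",
 "molecular_weight": 83.134,
 "sanitization_actions": 0
}
$ ligandkit infer-clc fx/assembly_3.cif --components fx --registry reg.json
{
 "bound_molecules": [
  {"bm_id": "bm1", "components": {"LG0": 2, "LG1": 1},
   "identifier": "CLC_000001", "polymer_attached": false},
  {"bm_id": "bm2", "components": {"LG1": 1},
   "identifier": "LG1", "polymer_attached": false}
 ]
}
```

Two `LG0` instances and one `LG1` are covalently linked, so they form a
single bound molecule: a multi-component ligand that gets the first free CLC
identifier (`CLC_000001`) in the registry, while the unlinked `LG1` instance
keeps its own component identifier. `sanitization_actions: 0` says the
component's valences needed no repair. Pairwise similarity and quality flags
work the same way:

```bash
$ ligandkit parity fx/LG0.cif fx/LG1.cif
fx/LG0.cif  fx/LG1.cif  0.4444  4  False     # score, matched atoms, timed_out
$ ligandkit validate --rscc 0.79 --rsr 0.2
{"density": {"rscc_flag": true, "rsr_flag": false, "flagged": true}}
```

The `0.4444` is 4 matched atoms out of 5+8−4 pooled heavy atoms; the RSCC of
0.79 falls below the 0.8 cutoff, so the ligand is highlighted for scrutiny.

The same stages are available as a library (`ligandkit.parity_score`,
`ligandkit.infer_bound_molecules`, `ligandkit.compute_contacts`, …) and as a
single entry pipeline, `ligandkit pipeline`.

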