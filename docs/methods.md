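# Methods

This note documents the models, rules and numerical choices behind
ligandkit, and what its synthetic fixtures do and do not emulate.

## Molecule model and sanitization

A molecule is a simple attributed graph: atoms carry element, formal charge
and optional 2D/3D Cartesian coordinates (Å); bonds carry an order (1, 2, 3;
1.5 with an aromatic flag; 0 for metal-coordination/dative bonds). Implicit
hydrogens are completed against a valence table mapping (element, charge) to
allowed total bond-order sums; the shipped defaults cover H, B, C, N, O, P,
S, Se and the halogens, with metals accepting any coordination number. The
table is data, not code, and callers may substitute their own.

Sanitization iteratively repairs atoms whose bond-order sum exceeds every
allowed valence for their (element, charge). Repairs are attempted in a fixed
precedence per offending atom (lowest atom index first):

1. **retype a bond to a metal** as a coordination bond (order 0) — this is
   what resolves haem-like complexes, where a pyrrole nitrogen σ-bonded to
   Fe would otherwise appear tetravalent;
2. **set a formal charge** that legalizes the observed valence (smallest
   magnitude first, positive before negative — a tetravalent neutral N
   becomes N⁺);
3. **lower one bond order**, highest-order bond first, lowest neighbor index
   breaking ties.

Metal retyping is tried before charge assignment: when a metal is involved
the coordination interpretation is chemically preferable to inventing formal
charges on the organic framework. One action is applied per iteration; the
procedure either converges (no offenders remain, making it idempotent by
construction) or raises after `max_iter` (default 50) with the partial action
report attached.

Descriptors (Hill formula, canonical SMILES, InChI, InChIKey, average
molecular weight) are computed through RDKit after a lossless graph
conversion. The graph model itself carries no stereochemistry; where stereo
matters (InChI stereo layers, stereoisomer detection) it is perceived from
3D coordinates when present, or supplied as precomputed InChI strings.

Murcko scaffolds are computed by iteratively peeling terminal atoms
(degree ≤ 1) until a fixed point: ring systems plus their connecting linkers
remain, and acyclic molecules reduce to the empty molecule. Exocyclic
substituents — including double-bonded terminal atoms — are removed. BRICS
fragmentation delegates to RDKit's rule set; attachment points appear as
`*` marker atoms and the fragments' heavy atoms partition the parent's.
Substructure search is a subgraph monomorphism (VF2) with element equality
and bond compatibility: aromatic matches aromatic, otherwise equal order.

## Depiction penalty score

A 2D layout is graded as `w_cross · crossings + w_overlap · overlaps` with
defaults `w_cross = 1.0`, `w_overlap = 0.5`. Crossings are proper interior
intersections of bond segments that share no atom; overlaps are atom pairs
closer than `min_sep = 0.5` times the **median bond length**, which makes the
score invariant under uniform scaling. The overlap criterion is this
package's concrete reading of "suboptimal atom positioning"; the weights are
conventions, not measured constants. The layout selector returns the
lowest-penalty candidate, first on ties.

## PARITY similarity

Two molecules are compared over heavy atoms only. The similarity is the
Jaccard coefficient over atoms of a maximum common induced subgraph:

    score = m / (nA + nB − m),  m = |MCS|

Atom matching is by element (charge-insensitive); bond matching is existence
only by default — both pairs bonded or both unbonded — which makes the score
robust to tautomer and bond-order drawing differences; a strict mode also
requires order/aromaticity agreement. The subgraph may be disconnected.

The MCS is a maximum clique of the modular product graph, searched by a
Tomita-style branch-and-bound with a greedy-coloring upper bound, seeded
with a greedy maximal clique for a strong initial lower bound. The search is
deterministic (fixed vertex order) and carries a node-expansion budget
(default 50 000): when exhausted, the best clique found so far is returned
with `timed_out=True`. For molecules up to ~10 heavy atoms the search always
completes and is exact (verified against an independent exhaustive oracle);
for cofactor-sized pairs the budget bounds runtime at a few seconds with
near-optimal mappings in practice. An exact element-multiset upper bound
(`parity_upper_bound`) lets callers skip comparisons that cannot reach a
threshold; the classifiers use it.

A caveat of the disconnected-MCS definition: large molecules with similar
elemental composition can score high even when chemically distinct, because
scattered atom mappings with matching non-adjacency are legal. The
functional-role classifier compensates with its EC gate (below). Stereoisomer
detection compares InChI layers: same formula and connectivity/proton layers
(`c`, `h`, `q`, `p`), different stereo layers (`b`, `t`, `m`, `s`).

Related-ligand grouping partitions a reference set with priority
stereoisomer > same scaffold > similar, where "same scaffold" compares
canonical Murcko-scaffold SMILES (empty, ring-less scaffolds never count as
shared) and "similar" means score ≥ 0.6, inclusive.

## Bound-molecule inference and CLC identifiers

Non-polymer, non-water component instances are nodes; declared covalent
links are edges; connected components are bound molecules. Metal-coordination
links never merge (a coordinated Mg²⁺ remains its own molecule) —
configurable by editing the link kinds considered. Waters are excluded
outright as solvent. Components covalently linked to a polymer residue are
flagged `polymer_attached` (modified-residue-like) and excluded from the free
ligand list while remaining in the report. bmIDs are assigned in order of
each component's first member under (chain, residue-number) sorting, with
numeric residue numbers compared numerically.

The assembled molecule is built by concatenating the per-component graphs
and adding a single bond at each link's atom pair; no leaving groups are
removed (the archive's remediation chemistry is out of scope), and the fusion
is re-sanitized. Identifiers: a single-instance molecule keeps its component
id; a multiset found in a curated PRD table gets that PRD id (curated
reference molecules take precedence over automatic ids); anything else gets a
registry CLC id — `CLC_` plus a six-digit ordinal assigned sequentially per
registry and keyed by InChIKey, never reassigned. Registry ordinals are
local to the registry instance; they are not intended to reproduce any
archive's numbering. Each assembly is processed independently; merging
across symmetry copies is not attempted.

## Contact typing

Structures are prepared by flattening instances into typed atoms. Bonds come
from the component definitions when available, otherwise from covalent-radius
distance perception (cutoff = r₁ + r₂ + 0.45 Å); inter-instance links are
added on top. Atom types (donor, acceptor, cation, anion, hydrophobe,
halogen, metal, weak C–H donor) derive from element, formal charge, bond
orders where known, and simple motifs (guanidinium, carboxylate/phosphate
terminal oxygens); with unknown bond orders a terminal C–O under 1.30 Å is
read as a carbonyl (acceptor only).

Polar-hydrogen placement puts one H on each donor lacking one, at the ideal
X–H length (O 0.96 Å, N 1.01 Å, S 1.34 Å) anti to the mean of its bond
vectors. It is a deliberately naive stand-in for a real protonation engine:
no tautomer or pKa logic, one H per donor. It is idempotent and can be
disabled for externally protonated input.

Rules and defaults (Å, degrees), all editable in `InteractionRuleSet`:
vdw tolerance 0.1; clash tolerance 0.6; H-bond donor–acceptor ≤ 3.5 with
D–H···A ≥ 120° when hydrogens exist (distance-only otherwise — most
experimental structures lack hydrogens); weak H-bond ≤ 3.8 from an activated
carbon; ionic ≤ 4.0; metal–N/O/S ≤ 3.0; hydrophobic C/S pairs ≤ 4.5;
halogen ≤ 4.0; proximal ≤ 5.0; ring centroids ≤ 6.0 for stacking with
face-to-face ≤ 30° and edge-to-edge ≥ 60° normal angles (offset between);
cation-π ≤ 4.5; donor-π ≤ 4.0. These mirror CREDO-style conventions; tests
pin this configuration, not universal constants. Atom–atom typing runs over
heavy atoms only (hydrogens enter only through the angle test); covalently
bonded pairs are skipped; a pair may carry several compatible subtypes, but a
clash suppresses all bonding subtypes, and metal coordination — whose
geometry sits inside the vdW clash range — is typed before the clash check.
Ring planes are 5–7-membered cycles with planarity RMSD ≤ 0.1 Å (centroid =
mean, normal = smallest principal axis); typed groups for plane–group
contacts are amide, guanidinium and carboxylate, an explicit and extensible
set. Neighbor search uses a uniform grid with cell size equal to the global
cutoff, chosen for exactness over speed.

## Functional roles

Cofactor-like: per class, PARITY against the class template must meet the
class threshold, then PARITY against the class representative must meet it
again, and the entry must carry an EC number matching the class's EC set
with prefix semantics (a class entry `1.1.1` or `1.1.1.-` covers `1.1.1.x`;
any syntactically valid EC present in the entry metadata is accepted). Both
similarity stages passing without an EC match flags the ligand for manual
review instead of annotating it. Reactant-like: best PARITY score ≥ 0.7
(inclusive) against any participant of a reaction mapped to the bound
protein's accession. Drug-like: the ligand's InChIKey (fallback: exact
ligand id) maps to a drug whose pharmacologically active targets include the
protein. Roles are non-exclusive and unioned per (ligand, accession) pair;
the shipped reference tables (four cofactor classes, two reactions, two
drugs) are small illustrative curations for testing — production tables are
user-supplied files of the same JSON schema.

## Aggregation and validation

Contacts aggregate by ligand `atom_id` into two normalizations: percent of
the ligand's total interactions per atom, and, per amino-acid type, percent
of that amino acid's interactions per atom (each column sums to 100). An
optional subtype filter restricts counting; zero matching contacts yield an
empty table rather than a division by zero. Aggregation is associative, so
per-entry tables can be merged by summing counts. Tables export as full
precision; no display rounding is applied.

Quality flags use strict inequalities at every boundary, following the
"above"/"below" wording of the conventions they implement: |Z| > 2.0 is an
outlier (two-sided — deviations in either direction matter even though the
convention is phrased unsigned), RMSZ = √mean(Z²) with [0, 1] as the ideal
band and absent for empty categories, torsion local density < 5% and ring
torsion RMSD > 60° are flagged, RSCC < 0.8 or RSR > 0.4 highlights the
ligand. Z-scores, densities and density-fit metrics are inputs: computing
them against a small-molecule crystallographic library or electron-density
maps is out of scope.

## Synthetic fixtures

`gen_molecule` builds a random spanning tree over palette-drawn elements
(default C/N/O at 0.7/0.15/0.15), closes rings and upgrades bond orders only
within each atom's remaining valence, so every generated molecule sanitizes
with zero actions by construction. Coordinates come from a
self-avoiding random embedding with 1.5 Å steps — finite and collision-free,
but not physically minimized geometry. `gen_assembly` places instances
~18 Å apart, wires a requested number of covalent and metal-coordination
links through atoms with spare valence (tracking per-atom link capacity),
surrounds the first instance with a toy pocket of Gly/Ser/Lys/Asp-like
residues at 4.5–6 Å and adds waters; it returns the ground-truth partition
computed by union-find over exactly the covalent edges it placed. Identical
seeds give identical objects.

What the fixtures do not emulate: real bond geometry and torsions,
crystallographic disorder and altlocs, realistic binding-site packing,
aromatic ring placement in pockets, or archive-scale component diversity.
Green tests therefore demonstrate the correctness of the graph, geometric
and bookkeeping logic under controlled conditions, not end-to-end accuracy
on experimental structures.

## Problem sizes

The default verification runs use 100 seeded assemblies for partition
checks, 25 molecule pairs (≤ 10 heavy atoms) for exhaustive MCS agreement,
500 pairs for symmetry, 5 random 200-atom scenes for contact agreement and
1000 random contact multisets for normalization — sizes at which the
independent oracles (union-find, networkx max-clique, brute-force all-pairs)
remain exact and fast.

## Known limitations

* No stereochemistry in the graph model (see above); no tautomer or pKa
  handling; aromaticity perception is a 6-ring alternation test plus
  explicit flags, not an electron-counting model.
* The disconnected-MCS similarity inflates scores between large,
  compositionally similar molecules; strict-bond mode and the EC gate
  mitigate this where it matters.
* Polar-hydrogen placement is geometric only; angle-dependent H-bond typing
  on naively protonated input inherits its biases.
* CLC fusion does not remove leaving atoms, so the InChIKey of a fused
  molecule may differ from the curated reference molecule's InChIKey for the
  same chemistry.
* Conformer generation, depiction layout generation, and archive-scale
  fingerprint prescreening are out of scope.
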