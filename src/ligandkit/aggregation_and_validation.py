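"""Interaction-frequency aggregation and ligand-quality flagging.

Aggregation turns contact lists from many entries into the two heatmap
normalizations shown on ligand pages: the share of the ligand's total
interactions carried by each ligand atom, and, per amino-acid type, the
share of that amino acid's interactions carried by each ligand atom.  Both
are percentages and each normalization sums to 100.

Quality flagging applies the standard validation cutoffs: geometric
Z-scores above 2.0 (two-sided, strict) are outliers and are summarized by
their RMSZ; torsion angles with a local density measure below 5% and rings
with a torsion-angle RMSD above 60° are flagged; ligands with RSCC below
0.8 or RSR above 0.4 are highlighted for scrutiny.  Z-scores and density
metrics are consumed as input — computing them against a crystallographic
reference library is out of scope.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .interactions import Contact


@dataclass
class InteractionFrequencyTable:
    atom_counts: Counter = field(default_factory=Counter)
    pair_counts: Counter = field(default_factory=Counter)  # (atom_id, amino acid)
    total: int = 0
    filter_applied: Optional[frozenset] = None

    @property
    def atom_percentages(self) -> dict[str, float]:
        """Per-atom share of all the ligand's interactions, in percent."""
        if not self.total:
            return {}
        return {a: 100.0 * c / self.total for a, c in sorted(self.atom_counts.items())}

    @property
    def atom_aa_percentages(self) -> dict[tuple[str, str], float]:
        """Per (ligand atom, amino acid): share of that amino acid's
        interactions, in percent (each amino-acid column sums to 100)."""
        aa_totals = Counter()
        for (atom, aa), c in self.pair_counts.items():
            aa_totals[aa] += c
        return {
            (atom, aa): 100.0 * c / aa_totals[aa]
            for (atom, aa), c in sorted(self.pair_counts.items())
        }

    def to_frame(self) -> pd.DataFrame:
        """Heatmap table: rows = ligand atoms, columns = amino acids."""
        pct = self.atom_aa_percentages
        if not pct:
            return pd.DataFrame()
        frame = pd.Series(pct).unstack(fill_value=0.0)
        frame.index.name = "atom_id"
        return frame

    def to_records(self) -> list[dict]:
        return [
            {"atom_id": a, "count": self.atom_counts[a], "percent": p}
            for a, p in self.atom_percentages.items()
        ]


def aggregate_atom_frequencies(
    contacts: Iterable[Contact],
    subtype_filter: Optional[Iterable[str]] = None,
) -> InteractionFrequencyTable:
    """Aggregate contacts (possibly concatenated across entries) into
    relative interaction frequencies keyed by ligand atom_id.

    ``subtype_filter`` restricts to the named subtypes (e.g. {"hbond"})
    before counting; with zero matching interactions the table is empty.
    Aggregation is associative: concatenating contact lists and aggregating
    equals merging per-entry aggregates.
    """
    keep = frozenset(subtype_filter) if subtype_filter is not None else None
    table = InteractionFrequencyTable(filter_applied=keep)
    for contact in contacts:
        if keep is not None and contact.subtype not in keep:
            continue
        atom = contact.ligand.get("atom_id")
        if atom is None:  # ring/group participants carry no single atom_id
            continue
        table.atom_counts[atom] += 1
        table.total += 1
        partner_comp = contact.partner.get("component_id")
        if partner_comp:
            table.pair_counts[(atom, partner_comp)] += 1
    return table


# ---------------------------------------------------------------------------
# validation flags
# ---------------------------------------------------------------------------

@dataclass
class ValidationThresholds:
    z_outlier: float = 2.0
    torsion_density_min: float = 5.0   # percent
    ring_rmsd_max: float = 60.0        # degrees
    rscc_min: float = 0.8
    rsr_max: float = 0.4
    rmsz_ideal: tuple[float, float] = (0.0, 1.0)


@dataclass
class GeometryReport:
    zscores: dict[str, list[float]]
    rmsz: dict[str, Optional[float]]
    outliers: dict[str, list[int]]     # indices of |Z| > z_outlier per category
    torsion_flags: list[int]
    ring_flags: list[int]
    rmsz_in_ideal_range: dict[str, Optional[bool]]


def geometry_flags(
    zscores: dict[str, Sequence[float]],
    torsion_densities: Sequence[float] = (),
    ring_rmsds: Sequence[float] = (),
    thresholds: Optional[ValidationThresholds] = None,
) -> GeometryReport:
    """Flag geometric outliers.

    ``zscores`` maps a category (e.g. "bonds", "angles") to its Z values;
    an entry is an outlier iff |Z| > 2.0 (strictly).  RMSZ = sqrt(mean(Z²)),
    absent for empty categories.  Torsions are flagged when their local
    density is below 5% and rings when their torsion RMSD exceeds 60°, both
    strict.
    """
    t = thresholds or ValidationThresholds()
    rmsz: dict[str, Optional[float]] = {}
    outliers: dict[str, list[int]] = {}
    ideal: dict[str, Optional[bool]] = {}
    lo, hi = t.rmsz_ideal
    for category, values in zscores.items():
        values = list(values)
        if values:
            rmsz[category] = math.sqrt(sum(z * z for z in values) / len(values))
            ideal[category] = lo <= rmsz[category] <= hi
        else:
            rmsz[category] = None
            ideal[category] = None
        outliers[category] = [i for i, z in enumerate(values) if abs(z) > t.z_outlier]
    return GeometryReport(
        zscores={k: list(v) for k, v in zscores.items()},
        rmsz=rmsz,
        outliers=outliers,
        torsion_flags=[i for i, d in enumerate(torsion_densities) if d < t.torsion_density_min],
        ring_flags=[i for i, r in enumerate(ring_rmsds) if r > t.ring_rmsd_max],
        rmsz_in_ideal_range=ideal,
    )


@dataclass
class DensityFlags:
    rscc_flag: bool
    rsr_flag: bool

    @property
    def flagged(self) -> bool:
        return self.rscc_flag or self.rsr_flag


def density_flags(
    rscc: float,
    rsr: float,
    thresholds: Optional[ValidationThresholds] = None,
) -> DensityFlags:
    """Highlight poor density fit: RSCC strictly below 0.8 or RSR strictly
    above 0.4.  RSCC outside [0, 1] is an input error."""
    t = thresholds or ValidationThresholds()
    if not 0.0 <= rscc <= 1.0:
        raise ValueError(f"RSCC must lie in [0, 1], got {rscc}")
    return DensityFlags(rscc_flag=rscc < t.rscc_min, rsr_flag=rsr > t.rsr_max)
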