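"""Lowest-common-ancestor baseline: per-peptide taxon assignment, normalized
taxon abundances (NTA), biological-function abundances (BA), and the
0.5%-of-taxon-specific-peptides filter.

Each peptide is assigned the LCA of its compatible species set.  TA(t) counts
redundant peptides (spectral counts) whose assignment is exactly t; NTA
normalizes TA over all assigned taxa.  BA(g) sums redundant peptide counts
over every peptide mapped to GO term g, a peptide contributing its full
count to each of its terms.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .em_core import CompatibilityMap
from .io_model import PeptideEvidence
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class LcaAssignment:
    per_peptide: dict[str, str]  # peptide -> assigned taxon
    ta: dict[str, float] = field(default_factory=dict)
    nta: dict[str, float] = field(default_factory=dict)
    ba: dict[str, float] = field(default_factory=dict)


def assign_lca(
    peptides: Sequence[PeptideEvidence], compat: CompatibilityMap, tree: TaxonomyTree
) -> LcaAssignment:
    per_peptide: dict[str, str] = {}
    for ev in peptides:
        if ev.peptide in per_peptide:
            continue
        taxa = compat.taxon_sets.get(ev.peptide)
        if not taxa:
            continue
        per_peptide[ev.peptide] = tree.lca(taxa)
    return LcaAssignment(per_peptide=per_peptide)


def compute_ta(assignment: LcaAssignment, peptides: Sequence[PeptideEvidence]) -> dict[str, float]:
    """Redundant peptide count per exactly-assigned taxon."""
    ta: dict[str, float] = {}
    for ev in peptides:
        taxon = assignment.per_peptide.get(ev.peptide)
        if taxon is None:
            continue
        ta[taxon] = ta.get(taxon, 0.0) + ev.spectral_count
    return ta


def compute_nta(assignment: LcaAssignment, peptides: Sequence[PeptideEvidence]) -> dict[str, float]:
    ta = compute_ta(assignment, peptides)
    total = sum(ta.values())
    if total <= 0:
        warnings.warn("no assigned peptides: NTA is empty")
        return {}
    return {taxon: count / total for taxon, count in ta.items()}


def compute_ba(
    peptides: Sequence[PeptideEvidence], peptide_to_terms: Mapping[str, set[str]]
) -> dict[str, float]:
    """BA(g): redundant peptide count summed over peptides mapped to g."""
    ba: dict[str, float] = {}
    for ev in peptides:
        for go_id in peptide_to_terms.get(ev.peptide, ()):
            ba[go_id] = ba.get(go_id, 0.0) + ev.spectral_count
    return ba


def unipept_filter(species_level_ta: Mapping[str, float], min_fraction: float = 0.005) -> set[str]:
    """Drop species contributing less than ``min_fraction`` of the
    species-level taxon-specific peptide total (the boundary is retained)."""
    total = sum(species_level_ta.values())
    if total <= 0:
        return set()
    return {t for t, count in species_level_ta.items() if count / total >= min_fraction}


# ---------------------------------------------------------------------------
# writers


def write_lca(assignment: LcaAssignment, tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide", "assigned_taxon_id", "rank"])
        for pep, taxon in sorted(assignment.per_peptide.items()):
            writer.writerow([pep, taxon, tree.rank(taxon)])


def write_map(values: Mapping[str, float], columns: tuple[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for key, value in sorted(values.items()):
            writer.writerow([key, repr(value)])
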