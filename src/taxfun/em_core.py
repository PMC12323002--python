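"""Two-stage expectation-maximization for taxon biomass and biological-function
abundance, with lineage aggregation.

Stage 1 estimates a probability p(t) per identified taxon from the MS1
extracted-ion-chromatogram areas of confidently identified peptides; the
probabilities sum to one over all identified taxa.  Stage 2, run per GO
aspect, estimates the joint probability p(k|t)p(t) of observing function k
from taxon t while holding p(t) fixed, so that the per-taxon sum over
functions equals the taxon's biomass exactly.  Species-level tables are
aggregated upward by summing over each ancestor's descendant species, which
keeps the set of unique GO ids identical at every level.

Peptide evidence weight is ms1_area x spectral_count throughout; a reserved
``UNANNOTATED`` sink term per taxon absorbs evidence from proteins without
annotations so that mass is conserved.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_model import ASPECTS, FunctionAnnotation, PeptideEvidence, ProteinRecord, annotation_index
from .taxonomy import CANONICAL_RANKS, TaxonomyTree

#: reserved sink "term" for peptide evidence from unannotated proteins
UNANNOTATED = "UNANNOTATED"

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 2000


@dataclass(frozen=True)
class CompatibilityMap:
    """Peptide -> taxa and peptide -> (taxon, term) compatibility sets.

    ``taxon_sets[pep]`` is the set of identified species whose retained
    proteins contain the peptide; ``pair_sets[(pep, aspect)]`` the set of
    (taxon, go_id) pairs the peptide supports for that aspect.
    """

    taxon_sets: dict[str, frozenset[str]]
    pair_sets: dict[tuple[str, str], frozenset[tuple[str, str]]]

    def taxa(self) -> set[str]:
        out: set[str] = set()
        for s in self.taxon_sets.values():
            out.update(s)
        return out


@dataclass(frozen=True)
class BiomassEstimate:
    probabilities: dict[str, float]  # taxon -> p(t)
    iterations: int
    converged: bool
    log_likelihood: float = math.nan


@dataclass(frozen=True)
class FunctionAbundanceTable:
    aspect: str
    joint: dict[tuple[str, str], float]  # (taxon, go_id) -> p(k|t)p(t)
    level: str = "species"

    def per_taxon_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for (taxon, _), value in self.joint.items():
            totals[taxon] = totals.get(taxon, 0.0) + value
        return totals

    def unique_terms(self) -> set[str]:
        return {go_id for (_, go_id) in self.joint}


# ---------------------------------------------------------------------------
# compatibility construction


def build_compatibility(
    peptides: Sequence[PeptideEvidence],
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[FunctionAnnotation] | Mapping[str, frozenset[tuple[str, str]]],
    identified_taxa: Iterable[str],
) -> CompatibilityMap:
    """Map each confidently identified peptide to its compatible taxa and
    (taxon, GO-term) pairs through the retained proteins of identified taxa.

    A peptide-taxon pair backed only by unannotated proteins maps to the
    reserved ``(taxon, UNANNOTATED)`` pair; peptides compatible with no
    identified taxon are dropped with a warning.
    """
    identified_taxa = set(identified_taxa)
    if isinstance(annotations, Mapping):
        ann = annotations
    else:
        ann = annotation_index(annotations)
    proteins = [p for p in proteins if p.taxon in identified_taxa]
    by_peptide: dict[str, list[ProteinRecord]] = {}
    for record in proteins:
        for pep in record.peptides:
            by_peptide.setdefault(pep, []).append(record)

    taxon_sets: dict[str, frozenset[str]] = {}
    pair_sets: dict[tuple[str, str], frozenset[tuple[str, str]]] = {}
    dropped = 0
    for evidence in peptides:
        pep = evidence.peptide
        if pep in taxon_sets:
            continue
        carriers = by_peptide.get(pep, ())
        taxa = frozenset(r.taxon for r in carriers)
        if not taxa:
            dropped += 1
            continue
        taxon_sets[pep] = taxa
        for aspect in ASPECTS:
            pairs: set[tuple[str, str]] = set()
            for taxon in taxa:
                terms = {
                    go_id
                    for r in carriers
                    if r.taxon == taxon
                    for go_id, a in ann.get(r.accession, frozenset())
                    if a == aspect
                }
                if terms:
                    pairs.update((taxon, go_id) for go_id in terms)
                else:
                    pairs.add((taxon, UNANNOTATED))
            pair_sets[(pep, aspect)] = frozenset(pairs)
    if dropped:
        warnings.warn(f"dropped {dropped} peptide(s) compatible with no identified taxon")
    return CompatibilityMap(taxon_sets=taxon_sets, pair_sets=pair_sets)


# ---------------------------------------------------------------------------
# evidence grouping helpers


def _evidence_weights(
    peptides: Sequence[PeptideEvidence], use_spectral_counts_only: bool
) -> dict[str, float]:
    """Total evidence weight per peptide sequence (area x count, summed
    over redundant evidence rows)."""
    weights: dict[str, float] = {}
    for ev in peptides:
        w = float(ev.spectral_count) if use_spectral_counts_only else ev.ms1_area * ev.spectral_count
        weights[ev.peptide] = weights.get(ev.peptide, 0.0) + w
    return weights


# ---------------------------------------------------------------------------
# stage 1: taxon biomass


def estimate_biomass(
    peptides: Sequence[PeptideEvidence],
    compat: CompatibilityMap,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: str = "uniform",
    use_spectral_counts_only: bool = False,
) -> BiomassEstimate:
    """EM over mixture weights w_t.

    E-step: r_{i,t} = w_t / sum_{t' in T_i} w_{t'};
    M-step: w_t <- sum_i x_i c_i r_{i,t} / sum_i x_i c_i.
    The weighted log-likelihood sum_i x_i c_i log(sum_{t in T_i} w_t) is
    non-decreasing across iterations.
    """
    weights = _evidence_weights(peptides, use_spectral_counts_only)
    # group evidence by compatibility set: EM only sees (T_i, weight) pairs
    groups: dict[frozenset[str], float] = {}
    for pep, w in weights.items():
        taxa = compat.taxon_sets.get(pep)
        if taxa is None:
            continue
        groups[taxa] = groups.get(taxa, 0.0) + w
    if not groups:
        raise ValueError("no peptide evidence is compatible with any identified taxon")
    total_weight = sum(groups.values())
    if total_weight <= 0:
        raise ValueError(
            "all MS1 areas are zero; rerun with use_spectral_counts_only=True "
            "to weight evidence by spectral counts"
        )

    taxa = sorted({t for s in groups for t in s})
    if init == "uniform":
        w = {t: 1.0 / len(taxa) for t in taxa}
    elif init == "area-weighted":
        raw = {t: 0.0 for t in taxa}
        for taxon_set, gw in groups.items():
            share = gw / len(taxon_set)
            for t in taxon_set:
                raw[t] += share
        w = {t: raw[t] / total_weight for t in taxa}
    else:
        raise ValueError(f"unknown init {init!r}")

    # fixed iteration order makes results invariant to peptide input order
    ordered_groups = sorted(groups.items(), key=lambda kv: tuple(sorted(kv[0])))
    converged = False
    iteration = 0
    log_likelihood = -math.inf
    for iteration in range(1, max_iter + 1):
        new_w = {t: 0.0 for t in taxa}
        log_likelihood = 0.0
        for taxon_set, gw in ordered_groups:
            members = sorted(taxon_set)
            denom = sum(w[t] for t in members)
            if denom <= 0.0:
                continue  # degenerate: every compatible taxon at zero mass
            log_likelihood += gw * math.log(denom)
            for t in members:
                new_w[t] += gw * w[t] / denom
        new_w = {t: v / total_weight for t, v in new_w.items()}
        delta = max(abs(new_w[t] - w[t]) for t in taxa)
        w = new_w
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"biomass EM did not converge in {max_iter} iterations")
    return BiomassEstimate(
        probabilities=w, iterations=iteration, converged=converged, log_likelihood=log_likelihood
    )


# ---------------------------------------------------------------------------
# stage 2: function abundance with fixed biomass


def estimate_function_abundance(
    peptides: Sequence[PeptideEvidence],
    compat: CompatibilityMap,
    biomass: BiomassEstimate,
    aspect: str,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    use_spectral_counts_only: bool = False,
) -> FunctionAbundanceTable:
    """EM over the conditionals phi_{k|t} with p(t) held fixed.

    theta_{t,k} = p(t) phi_{k|t};
    E-step: z_{i,(t,k)} = theta_{t,k} / sum_{(t',k') in A_i} theta_{t',k'};
    M-step: phi_{k|t} <- sum_i x_i c_i z_{i,(t,k)} / sum_{k'} sum_i x_i c_i z_{i,(t,k')}.
    The returned joint p(t) phi_{k|t} sums to p(t) per taxon by construction.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"unknown GO aspect {aspect!r}")
    p = biomass.probabilities
    missing = compat.taxa() - set(p)
    if missing:
        raise ValueError(f"biomass estimate lacks taxa {sorted(missing)}")

    weights = _evidence_weights(peptides, use_spectral_counts_only)
    groups: dict[frozenset[tuple[str, str]], float] = {}
    for pep, wt in weights.items():
        pairs = compat.pair_sets.get((pep, aspect))
        if pairs is None:
            continue
        groups[pairs] = groups.get(pairs, 0.0) + wt

    # supported terms per taxon for this aspect
    support: dict[str, set[str]] = {}
    for pairs in groups:
        for taxon, go_id in pairs:
            support.setdefault(taxon, set()).add(go_id)

    joint: dict[tuple[str, str], float] = {}
    # taxa with biomass but no compatible evidence for this aspect: all of
    # their mass goes to the unannotated sink
    for taxon in sorted(set(p) - set(support)):
        joint[(taxon, UNANNOTATED)] = p[taxon]

    if support:
        phi = {
            taxon: {k: 1.0 / len(terms) for k in sorted(terms)}
            for taxon in sorted(support)
            for terms in [support[taxon]]
        }
        ordered_groups = sorted(groups.items(), key=lambda kv: tuple(sorted(kv[0])))
        converged = False
        dropped_zero_mass = 0
        for _ in range(1, max_iter + 1):
            acc = {taxon: {k: 0.0 for k in phi[taxon]} for taxon in phi}
            for pairs, gw in ordered_groups:
                members = sorted(pairs)
                denom = sum(p[t] * phi[t][k] for t, k in members)
                if denom <= 0.0:
                    dropped_zero_mass += 1
                    continue
                for t, k in members:
                    acc[t][k] += gw * p[t] * phi[t][k] / denom
            delta = 0.0
            new_phi = {}
            for taxon, term_acc in acc.items():
                taxon_total = sum(term_acc.values())
                if taxon_total <= 0.0:
                    # no responsibility reached this taxon (p(t)=0 or starved)
                    new_phi[taxon] = dict(phi[taxon])
                    continue
                new_phi[taxon] = {k: v / taxon_total for k, v in term_acc.items()}
                delta = max(
                    delta, max(abs(new_phi[taxon][k] - phi[taxon][k]) for k in phi[taxon])
                )
            phi = new_phi
            if delta < tol:
                converged = True
                break
        if dropped_zero_mass:
            warnings.warn(
                f"{dropped_zero_mass} evidence group(s) had zero total responsibility "
                "(all compatible taxa at zero biomass) and were ignored"
            )
        if not converged:
            warnings.warn(f"function-abundance EM did not converge in {max_iter} iterations")
        for taxon, terms in phi.items():
            for k, v in terms.items():
                joint[(taxon, k)] = p[taxon] * v

    return FunctionAbundanceTable(aspect=aspect, joint=joint, level="species")


# ---------------------------------------------------------------------------
# lineage aggregation


def aggregate_to_level(
    table: FunctionAbundanceTable, tree: TaxonomyTree, level: str
) -> FunctionAbundanceTable:
    """Sum species-level joints over each ancestor at the requested rank.

    Species lacking an ancestor at the level contribute to the root node, so
    no mass is lost and the set of unique GO ids is level-invariant.
    """
    if table.level != "species":
        raise ValueError("aggregation starts from a species-level table")
    if level not in CANONICAL_RANKS:
        raise ValueError(f"non-canonical rank {level!r}")
    joint: dict[tuple[str, str], float] = {}
    for (taxon, go_id), value in table.joint.items():
        ancestor = tree.lineage_at(taxon, level) or tree.root
        key = (ancestor, go_id)
        joint[key] = joint.get(key, 0.0) + value
    return FunctionAbundanceTable(aspect=table.aspect, joint=joint, level=level)


def aggregate_biomass(
    probabilities: Mapping[str, float], tree: TaxonomyTree, level: str
) -> dict[str, float]:
    """Project species-level biomass to a canonical rank by summation."""
    if level not in CANONICAL_RANKS:
        raise ValueError(f"non-canonical rank {level!r}")
    out: dict[str, float] = {}
    for taxon, value in probabilities.items():
        ancestor = tree.lineage_at(taxon, level) or tree.root
        out[ancestor] = out.get(ancestor, 0.0) + value
    return out


# ---------------------------------------------------------------------------
# writers


def write_abundance(
    tables: Sequence[FunctionAbundanceTable],
    tree: TaxonomyTree,
    path: str | Path,
    sample_id: str = "",
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "level", "taxon_id", "taxon_name", "aspect", "go_id", "abundance"])
        for table in tables:
            for (taxon, go_id), value in sorted(table.joint.items()):
                name = tree.name(taxon) if taxon in tree else taxon
                writer.writerow([sample_id, table.level, taxon, name, table.aspect, go_id, repr(value)])


def write_biomass(
    levels: Mapping[str, Mapping[str, float]], path: str | Path, sample_id: str = ""
) -> None:
    """``levels`` maps rank -> (taxon -> biomass)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "level", "taxon_id", "biomass"])
        for level in CANONICAL_RANKS:
            if level not in levels:
                continue
            for taxon, value in sorted(levels[level].items()):
                writer.writerow([sample_id, level, taxon, repr(value)])
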