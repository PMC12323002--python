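"""Synthetic benchmark communities with known ground truth.

Generates a taxonomy, protein records with tryptic-like peptide tokens,
per-protein GO annotations, and peptide-evidence samples whose MS1 areas
follow a lognormal noise model around each peptide's true biomass share.
Peptides can be shared among species at a chosen rank (genus, family, ...)
at configurable fractions; everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import (
    ASPECTS,
    FunctionAnnotation,
    PeptideEvidence,
    ProteinRecord,
    write_annotations,
    write_peptides,
    write_proteins,
)
from .taxonomy import CANONICAL_RANKS, TaxNode, TaxonomyTree

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for termini
_AREA_SCALE = 1e6


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community.

    ``species`` lists (taxon_id, lineage) pairs, the lineage mapping canonical
    ranks (phylum..genus) to ancestor ids.  ``sharing`` maps a rank to the
    fraction of all peptides shared among species with a common ancestor at
    that rank; fractions must sum to <= 1, the remainder being species-unique.
    """

    species: tuple[tuple[str, Mapping[str, str]], ...]
    biomass_ratios: tuple[float, ...]
    proteins_per_species: int = 4
    terms_per_protein: tuple[int, int] = (1, 3)
    peptides_per_protein: tuple[int, int] = (4, 8)
    sharing: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.biomass_ratios):
            raise ValueError("species and biomass_ratios lengths differ")
        if any(r <= 0 for r in self.biomass_ratios):
            raise ValueError("biomass ratios must be positive")
        if sum(self.sharing.values()) > 1:
            raise ValueError("sharing fractions must sum to <= 1")
        for rank in self.sharing:
            if rank not in CANONICAL_RANKS or rank in ("root", "species"):
                raise ValueError(f"sharing rank {rank!r} must be an internal canonical rank")

    @property
    def biomass_truth(self) -> dict[str, float]:
        total = sum(self.biomass_ratios)
        return {tid: r / total for (tid, _), r in zip(self.species, self.biomass_ratios)}


@dataclass(frozen=True)
class Community:
    spec: CommunitySpec
    tree: TaxonomyTree
    proteins: tuple[ProteinRecord, ...]
    annotations: tuple[FunctionAnnotation, ...]
    peptide_sources: dict[str, frozenset[str]]  # peptide -> species carrying it
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.tree.to_lineage_tsv(out_dir / "taxonomy.tsv")
        write_proteins(self.proteins, out_dir / "proteins.tsv")
        write_annotations(self.annotations, out_dir / "annotations.tsv")
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def default_lineages(
    n_species: int, species_per_genus: int = 2
) -> tuple[tuple[str, dict[str, str]], ...]:
    """Convenience lineage builder: species s1..sN grouped into genera of
    ``species_per_genus``, one genus per family/order/class, two phyla."""
    species = []
    for i in range(n_species):
        genus = i // species_per_genus
        lineage = {
            "phylum": f"p{genus % 2}",
            "class": f"c{genus}",
            "order": f"o{genus}",
            "family": f"f{genus}",
            "genus": f"g{genus}",
        }
        species.append((f"s{i}", lineage))
    return tuple(species)


def _build_tree(species: Sequence[tuple[str, Mapping[str, str]]]) -> TaxonomyTree:
    nodes: dict[str, TaxNode] = {"root": TaxNode("root", "root", "root", None)}
    order = [r for r in CANONICAL_RANKS if r not in ("root", "species")]
    for tid, lineage in species:
        parent = "root"
        for rank in order:
            anc = lineage.get(rank)
            if anc is None:
                continue
            if anc not in nodes:
                nodes[anc] = TaxNode(anc, anc, rank, parent)
            elif nodes[anc].parent != parent:
                raise ValueError(f"inconsistent lineage at {anc!r}")
            parent = anc
        nodes[tid] = TaxNode(tid, tid, "species", parent)
    return TaxonomyTree(nodes)


def _peptide_token(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        token = body + ("K" if rng.integers(2) else "R")
        if token not in existing:
            existing.add(token)
            return token


def _go_pool(rng: np.random.Generator, size: int = 120) -> dict[str, list[str]]:
    ids = rng.choice(np.arange(1, 10_000_000), size=size, replace=False)
    per_aspect = size // len(ASPECTS)
    pool: dict[str, list[str]] = {}
    for i, aspect in enumerate(ASPECTS):
        chunk = ids[i * per_aspect : (i + 1) * per_aspect]
        pool[aspect] = [f"GO:{v:07d}" for v in sorted(chunk)]
    return pool


def generate_community(spec: CommunitySpec) -> Community:
    """Deterministically build taxonomy, proteins, annotations and ground truth."""
    rng = np.random.default_rng(spec.seed)
    tree = _build_tree(spec.species)
    go_pool = _go_pool(rng)
    existing_tokens: set[str] = set()

    # per-protein peptide token lists, species-unique at first
    lo, hi = spec.peptides_per_protein
    protein_peptides: dict[str, list[str]] = {}
    protein_meta: dict[str, tuple[str, float]] = {}  # accession -> (species, evalue)
    peptide_sources: dict[str, set[str]] = {}
    species_ids = [tid for tid, _ in spec.species]
    for tid in species_ids:
        for j in range(spec.proteins_per_species):
            acc = f"{tid}_P{j}"
            n_pep = int(rng.integers(lo, hi + 1))
            peps = [_peptide_token(rng, existing_tokens) for _ in range(n_pep)]
            protein_peptides[acc] = peps
            protein_meta[acc] = (tid, float(10.0 ** rng.uniform(-8, -4)))
            for pep in peps:
                peptide_sources[pep] = {tid}

    # add rank-shared peptides on top of the species-unique pool so that
    # each rank's fraction is taken of the final emitted total
    n_unique = len(peptide_sources)
    remainder = 1.0 - sum(spec.sharing.values())
    if remainder <= 0:
        raise ValueError("sharing fractions leave no room for species-unique peptides")
    n_final = round(n_unique / remainder)
    sharing_counts: dict[str, int] = {}
    for rank in sorted(spec.sharing):
        frac = spec.sharing[rank]
        groups: dict[str, list[str]] = {}
        for tid in species_ids:
            anc = tree.lineage_at(tid, rank)
            if anc is not None:
                groups.setdefault(anc, []).append(tid)
        groups = {a: members for a, members in groups.items() if len(members) >= 2}
        if not groups:
            raise ValueError(f"no group of >=2 species shares an ancestor at rank {rank!r}")
        n_shared = round(frac * n_final)
        sharing_counts[rank] = n_shared
        group_keys = sorted(groups)
        for _ in range(n_shared):
            anc = group_keys[int(rng.integers(len(group_keys)))]
            pep = _peptide_token(rng, existing_tokens)
            peptide_sources[pep] = set()
            for tid in groups[anc]:
                j = int(rng.integers(spec.proteins_per_species))
                protein_peptides[f"{tid}_P{j}"].append(pep)
                peptide_sources[pep].add(tid)
    n_total = len(peptide_sources)

    proteins = tuple(
        ProteinRecord(
            accession=acc,
            taxon=protein_meta[acc][0],
            evalue=protein_meta[acc][1],
            peptides=frozenset(protein_peptides[acc]),
        )
        for acc in sorted(protein_peptides)
    )

    # per-protein GO terms drawn from the aspect pools
    tlo, thi = spec.terms_per_protein
    annotations = []
    true_terms: dict[str, set[tuple[str, str]]] = {tid: set() for tid in species_ids}
    for acc in sorted(protein_peptides):
        terms: set[tuple[str, str]] = set()
        for aspect in ASPECTS:
            n_terms = int(rng.integers(tlo, thi + 1))
            chosen = rng.choice(len(go_pool[aspect]), size=n_terms, replace=False)
            terms.update((go_pool[aspect][c], aspect) for c in sorted(chosen))
        annotations.append(FunctionAnnotation(accession=acc, terms=frozenset(terms)))
        true_terms[protein_meta[acc][0]].update(terms)

    ground_truth = {
        "biomass": spec.biomass_truth,
        "term_sets": {
            tid: sorted(f"{go}|{aspect}" for go, aspect in terms)
            for tid, terms in true_terms.items()
        },
        "sharing_counts": sharing_counts,
        "n_peptides": n_total,
    }
    return Community(
        spec=spec,
        tree=tree,
        proteins=proteins,
        annotations=tuple(annotations),
        peptide_sources={p: frozenset(s) for p, s in peptide_sources.items()},
        ground_truth=ground_truth,
    )


def generate_sample(
    community: Community, sample_id: str = "sample", seed: int | None = None
) -> list[PeptideEvidence]:
    """Draw one peptide-evidence sample from the community.

    Each peptide's MS1 area is the sum over its source species of
    ``share_s * exp(N(0, sigma)) * scale``.  With sigma = 0 the sample is
    noise-free: spectral counts are pinned to 1 and, with unique peptides
    only and equal per-species peptide counts, per-species area totals are
    exactly proportional to the biomass ratios.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shares = spec.biomass_truth
    records = []
    for pep in sorted(community.peptide_sources):
        area = 0.0
        for tid in sorted(community.peptide_sources[pep]):
            noise = float(np.exp(rng.normal(0.0, spec.noise_sigma))) if spec.noise_sigma > 0 else 1.0
            area += shares[tid] * noise * _AREA_SCALE
        records.append(
            PeptideEvidence(
                peptide=pep,
                evalue=float(10.0 ** rng.uniform(-8, -4)),
                ms1_area=area,
                spectral_count=1 if spec.noise_sigma == 0 else int(rng.integers(1, 4)),
                sample_id=sample_id,
            )
        )
    return records


def write_sample(records: Sequence[PeptideEvidence], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "peptides.tsv"
    write_peptides(records, path)
    return path
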