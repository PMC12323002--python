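"""Protein clustering by shared identified peptides, E-value-ranked cluster
heads, and per-taxon unclustering.

Two proteins are joined when the overlap coefficient of their identified
peptide sets, |Pa ∩ Pb| / min(|Pa|, |Pb|), reaches the threshold; clusters
are the connected components of that graph.  Within a cluster the head is
the smallest-E-value member, and unclustering retains one best protein per
identified taxon.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_model import FunctionAnnotation, ProteinRecord, annotation_index


@dataclass(frozen=True)
class ProteinCluster:
    members: tuple[ProteinRecord, ...]
    head: str
    retained: dict[str, str] = field(default_factory=dict)  # taxon -> accession

    def member(self, accession: str) -> ProteinRecord:
        for m in self.members:
            if m.accession == accession:
                return m
        raise KeyError(accession)


def _rank_key(record: ProteinRecord) -> tuple[float, str]:
    # smallest E-value wins; accession breaks ties deterministically
    return (record.evalue, record.accession)


def cluster_proteins(
    records: Sequence[ProteinRecord], overlap_threshold: float = 0.8
) -> list[ProteinCluster]:
    if not 0 < overlap_threshold <= 1:
        raise ValueError(f"overlap_threshold must be in (0,1], got {overlap_threshold}")
    for r in records:
        if not r.peptides:
            raise ValueError(f"protein {r.accession!r} has no identified peptides")
    graph = nx.Graph()
    graph.add_nodes_from(r.accession for r in records)
    by_acc = {r.accession: r for r in records}
    if len(by_acc) != len(records):
        raise ValueError("duplicate protein accessions")
    # index peptides -> proteins so only candidate pairs are scored
    by_peptide: dict[str, list[str]] = {}
    for r in records:
        for pep in r.peptides:
            by_peptide.setdefault(pep, []).append(r.accession)
    seen_pairs: set[tuple[str, str]] = set()
    for accs in by_peptide.values():
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                pair = (a, b) if a < b else (b, a)
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                pa, pb = by_acc[pair[0]].peptides, by_acc[pair[1]].peptides
                overlap = len(pa & pb) / min(len(pa), len(pb))
                if overlap >= overlap_threshold:
                    graph.add_edge(*pair)
    clusters = []
    for component in nx.connected_components(graph):
        members = tuple(sorted((by_acc[a] for a in component), key=_rank_key))
        clusters.append(ProteinCluster(members=members, head=members[0].accession))
    clusters.sort(key=lambda c: c.members[0].accession)
    return clusters


def uncluster_by_taxon(cluster: ProteinCluster, identified_taxa: Iterable[str]) -> ProteinCluster:
    """Retain the best-ranking member per identified taxon; other taxa drop out."""
    identified_taxa = set(identified_taxa)
    if not identified_taxa:
        raise ValueError("identified_taxa must be nonempty")
    retained: dict[str, str] = {}
    for member in cluster.members:  # members already sorted best-first
        if member.taxon in identified_taxa and member.taxon not in retained:
            retained[member.taxon] = member.accession
    return replace(cluster, retained=retained)


def collect_go_terms(
    clusters: Sequence[ProteinCluster],
    annotations: Iterable[FunctionAnnotation] | Mapping[str, frozenset[tuple[str, str]]],
) -> dict[str, set[tuple[str, str]]]:
    """Union of annotation terms of each cluster's retained proteins, per taxon."""
    if isinstance(annotations, Mapping):
        index = annotations
    else:
        index = annotation_index(annotations)
    out: dict[str, set[tuple[str, str]]] = {}
    for cluster in clusters:
        for taxon, accession in cluster.retained.items():
            terms = index.get(accession)
            if terms is None:
                warnings.warn(f"retained protein {accession!r} has no annotation record")
                terms = frozenset()
            out.setdefault(taxon, set()).update(terms)
    return out


def write_clusters(clusters: Sequence[ProteinCluster], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster_id", "accession", "taxon_id", "is_head", "is_retained"])
        for cid, cluster in enumerate(clusters):
            retained_accs = set(cluster.retained.values())
            for m in cluster.members:
                writer.writerow(
                    [
                        cid,
                        m.accession,
                        m.taxon,
                        int(m.accession == cluster.head),
                        int(m.accession in retained_accs),
                    ]
                )
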