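"""Taxonomic tree with canonical-rank projection and lowest-common-ancestor queries.

The tree is rooted and every node carries one of the seven canonical ranks
(root, phylum, class, order, family, genus, species) or ``no-rank`` for
strains/clades.  No-rank nodes are transparent for rank projection: walking
up a lineage skips them, so a strain projects to its species ancestor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

CANONICAL_RANKS: tuple[str, ...] = (
    "root",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
NO_RANK = "no-rank"
_RANK_INDEX = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}

LINEAGE_COLUMNS = ("taxon_id", "name", "rank", "parent_id")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy inputs or invalid queries."""


def _normalize_rank(rank: str) -> str:
    rank = rank.strip().lower().replace("_", " ")
    if rank in ("no rank", "no-rank", "clade", "strain", "subspecies"):
        return NO_RANK
    rank = rank.replace(" ", "-")
    if rank not in _RANK_INDEX and rank != NO_RANK:
        # non-canonical taxdump ranks (superkingdom, tribe, ...) are
        # treated as transparent, same as NCBI's explicit "no rank"
        return NO_RANK
    return rank


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTree:
    """Validated rooted tree of taxa.

    Parameters
    ----------
    nodes
        Mapping taxon-id -> :class:`TaxNode`.  Exactly one node must have
        ``parent is None``; every parent reference must resolve.
    """

    def __init__(self, nodes: Mapping[str, TaxNode]):
        roots = [n.taxon_id for n in nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root: str = roots[0]
        self.nodes: dict[str, TaxNode] = dict(nodes)
        self._depth: dict[str, int] = {}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_lineage_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Read the flat lineage format (taxon_id, name, rank, parent_id).

        ``parent_id`` is empty for the root row.
        """
        nodes: dict[str, TaxNode] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(LINEAGE_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise TaxonomyError(f"{path}: missing columns {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                tid = row["taxon_id"].strip()
                if tid in nodes:
                    raise TaxonomyError(f"{path}:{lineno}: duplicate taxon id {tid!r}")
                parent = row["parent_id"].strip() or None
                nodes[tid] = TaxNode(tid, row["name"].strip(), _normalize_rank(row["rank"]), parent)
        return cls(nodes)

    @classmethod
    def from_taxdump(cls, nodes_dmp: str | Path, names_dmp: str | Path) -> "TaxonomyTree":
        """Read the NCBI taxdump dialect (pipe-delimited nodes.dmp/names.dmp)."""
        names: dict[str, str] = {}
        with open(names_dmp, encoding="utf-8") as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                names[fields[0]] = fields[1]
        nodes: dict[str, TaxNode] = {}
        with open(nodes_dmp, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) < 3:
                    raise TaxonomyError(f"{nodes_dmp}:{lineno}: expected >=3 fields")
                tid, parent, rank = fields[0], fields[1], _normalize_rank(fields[2])
                if tid in nodes:
                    raise TaxonomyError(f"{nodes_dmp}:{lineno}: duplicate taxon id {tid!r}")
                if parent == tid:  # taxdump encodes the root as its own parent
                    nodes[tid] = TaxNode(tid, names.get(tid, tid), "root", None)
                else:
                    nodes[tid] = TaxNode(tid, names.get(tid, tid), rank, parent)
        return cls(nodes)

    def to_lineage_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(LINEAGE_COLUMNS)
            for tid in sorted(self.nodes):
                node = self.nodes[tid]
                writer.writerow([node.taxon_id, node.name, node.rank, node.parent or ""])

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise TaxonomyError(
                    f"node {node.taxon_id!r} references absent parent {node.parent!r}"
                )
        # depth computation doubles as cycle/reachability check
        for tid in self.nodes:
            self._depth_of(tid)
        for node in self.nodes.values():
            if node.rank != "species":
                continue
            ranks = [
                _RANK_INDEX[self.nodes[a].rank]
                for a in self.path_from_root(node.taxon_id)
                if self.nodes[a].rank != NO_RANK
            ]
            if any(b <= a for a, b in zip(ranks, ranks[1:])):
                raise TaxonomyError(
                    f"lineage of {node.taxon_id!r} has non-descending canonical ranks"
                )

    def _depth_of(self, taxon_id: str) -> int:
        if taxon_id in self._depth:
            return self._depth[taxon_id]
        chain = []
        cur: str | None = taxon_id
        seen = set()
        while cur is not None and cur not in self._depth:
            if cur in seen:
                raise TaxonomyError(f"cycle detected at taxon {cur!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.nodes[cur].parent
        base = -1 if cur is None else self._depth[cur]
        for tid in reversed(chain):
            base += 1
            self._depth[tid] = base
        return self._depth[taxon_id]

    # -- queries ----------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def depth(self, taxon_id: str) -> int:
        return self._depth_of(taxon_id)

    def path_from_root(self, taxon_id: str) -> list[str]:
        """Taxon ids from the root down to (and including) ``taxon_id``."""
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        path = []
        cur: str | None = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        path.reverse()
        return path

    def lineage_at(self, taxon_id: str, level: str) -> str | None:
        """Project a taxon to its ancestor (or self) at a canonical rank.

        Returns ``None`` when the lineage has no node of the requested rank.
        """
        if level not in _RANK_INDEX:
            raise TaxonomyError(f"non-canonical rank {level!r}")
        for ancestor in self.path_from_root(taxon_id):
            if self.nodes[ancestor].rank == level:
                return ancestor
        return None

    def lca(self, taxa: Iterable[str]) -> str:
        """Deepest node ancestral to (or equal to) every input taxon."""
        taxa = set(taxa)
        if not taxa:
            raise TaxonomyError("lca of an empty taxon set is undefined")
        paths = [self.path_from_root(t) for t in taxa]
        ancestor = self.root
        for level_nodes in zip(*paths):
            if len(set(level_nodes)) != 1:
                break
            ancestor = level_nodes[0]
        return ancestor

    def rank(self, taxon_id: str) -> str:
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        return self.nodes[taxon_id].rank

    def name(self, taxon_id: str) -> str:
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        return self.nodes[taxon_id].name
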