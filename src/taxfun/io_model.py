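"""Data model and tab-separated readers/writers for peptide evidence,
protein records and GO annotations, plus confidence filtering.

All files are UTF-8, tab-separated, single header row.  Schemas:

* peptides.tsv:    peptide, evalue, ms1_area, spectral_count, sample_id
* proteins.tsv:    accession, taxon_id, evalue, peptides (semicolon-joined)
* annotations.tsv: accession, go_id, aspect
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ASPECTS = ("biological_process", "molecular_function", "cellular_component")
GAF_ASPECT_CODES = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}
_GO_PATTERN = re.compile(r"^GO:\d{7}$")

PEPTIDE_COLUMNS = ("peptide", "evalue", "ms1_area", "spectral_count", "sample_id")
PROTEIN_COLUMNS = ("accession", "taxon_id", "evalue", "peptides")
ANNOTATION_COLUMNS = ("accession", "go_id", "aspect")


class SchemaError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class PeptideEvidence:
    """One confidently identified peptide occurrence.

    ``spectral_count`` carries the redundant occurrence count of the peptide
    (repeated identifications are one row, not repeated rows).
    """

    peptide: str
    evalue: float
    ms1_area: float
    spectral_count: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        if self.ms1_area < 0:
            raise ValueError(f"ms1_area must be >= 0, got {self.ms1_area}")
        if self.spectral_count < 1:
            raise ValueError(f"spectral_count must be >= 1, got {self.spectral_count}")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    taxon: str
    evalue: float
    peptides: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        object.__setattr__(self, "peptides", frozenset(self.peptides))


@dataclass(frozen=True)
class FunctionAnnotation:
    accession: str
    terms: frozenset[tuple[str, str]] = field(default_factory=frozenset)  # (go_id, aspect)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        for go_id, aspect in self.terms:
            if not _GO_PATTERN.match(go_id):
                raise ValueError(f"malformed GO id {go_id!r}")
            if aspect not in ASPECTS:
                raise ValueError(f"unknown GO aspect {aspect!r}")


# ---------------------------------------------------------------------------
# readers / writers


def _open_reader(path: str | Path, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh, delimiter="\t")
    missing = set(required) - set(reader.fieldnames or ())
    if missing:
        fh.close()
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return reader, fh


def read_peptides(path: str | Path) -> list[PeptideEvidence]:
    reader, fh = _open_reader(path, PEPTIDE_COLUMNS)
    records = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    PeptideEvidence(
                        peptide=row["peptide"].strip(),
                        evalue=float(row["evalue"]),
                        ms1_area=float(row["ms1_area"]),
                        spectral_count=int(row["spectral_count"]),
                        sample_id=row["sample_id"].strip(),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_peptides(records: Iterable[PeptideEvidence], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEPTIDE_COLUMNS)
        for r in records:
            writer.writerow([r.peptide, repr(r.evalue), repr(r.ms1_area), r.spectral_count, r.sample_id])


def read_proteins(path: str | Path) -> list[ProteinRecord]:
    reader, fh = _open_reader(path, PROTEIN_COLUMNS)
    records = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                peptides = frozenset(p for p in row["peptides"].split(";") if p)
                records.append(
                    ProteinRecord(
                        accession=row["accession"].strip(),
                        taxon=row["taxon_id"].strip(),
                        evalue=float(row["evalue"]),
                        peptides=peptides,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_proteins(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROTEIN_COLUMNS)
        for r in records:
            writer.writerow([r.accession, r.taxon, repr(r.evalue), ";".join(sorted(r.peptides))])


def read_annotations(path: str | Path, dialect: str = "flat") -> list[FunctionAnnotation]:
    """Read protein -> GO-term annotations.

    ``dialect="flat"`` expects the annotations.tsv schema; ``dialect="gaf"``
    reads the GAF 2.2 subset (column 2 = accession, column 5 = GO id,
    column 9 = aspect code P/F/C; ``!`` comment lines skipped).
    """
    if dialect == "flat":
        terms_by_acc = _read_flat_annotations(path)
    elif dialect == "gaf":
        terms_by_acc = _read_gaf(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return [
        FunctionAnnotation(accession=acc, terms=frozenset(terms))
        for acc, terms in sorted(terms_by_acc.items())
    ]


def _read_flat_annotations(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    reader, fh = _open_reader(path, ANNOTATION_COLUMNS)
    out: dict[str, set[tuple[str, str]]] = {}
    with fh:
        for lineno, row in enumerate(reader, start=2):
            go_id, aspect = row["go_id"].strip(), row["aspect"].strip()
            if not _GO_PATTERN.match(go_id):
                raise SchemaError(f"{path}:{lineno}: malformed GO id {go_id!r}")
            if aspect not in ASPECTS:
                raise SchemaError(f"{path}:{lineno}: unknown aspect {aspect!r}")
            out.setdefault(row["accession"].strip(), set()).add((go_id, aspect))
    return out


def _read_gaf(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    out: dict[str, set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise SchemaError(f"{path}:{lineno}: GAF line has {len(fields)} columns, need >= 9")
            acc, go_id, code = fields[1].strip(), fields[4].strip(), fields[8].strip()
            if not _GO_PATTERN.match(go_id):
                raise SchemaError(f"{path}:{lineno}: malformed GO id {go_id!r}")
            if code not in GAF_ASPECT_CODES:
                raise SchemaError(f"{path}:{lineno}: unknown GAF aspect code {code!r}")
            out.setdefault(acc, set()).add((go_id, GAF_ASPECT_CODES[code]))
    return out


def write_annotations(records: Iterable[FunctionAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for r in records:
            for go_id, aspect in sorted(r.terms):
                writer.writerow([r.accession, go_id, aspect])


def annotation_index(records: Iterable[FunctionAnnotation]) -> dict[str, frozenset[tuple[str, str]]]:
    """Accession -> term-set lookup; duplicate accessions are unioned."""
    out: dict[str, set[tuple[str, str]]] = {}
    for r in records:
        out.setdefault(r.accession, set()).update(r.terms)
    return {acc: frozenset(terms) for acc, terms in out.items()}


# ---------------------------------------------------------------------------
# confidence filtering


def filter_by_pfd(items: Sequence, pfd_target: float) -> tuple[list, float | None]:
    """Retain the largest E-value-sorted prefix whose estimated PFD stays
    at or below ``pfd_target``.

    The E-value of an item is read as the expected number of false positives
    at its score, so the estimated proportion of false discoveries among the
    ``r`` best items is ``E_r / r``.  Returns the retained items (ascending
    E-value) and the E-value cutoff (``None`` when nothing is retained).
    """
    if not 0 < pfd_target < 1:
        raise ValueError(f"pfd_target must be in (0,1), got {pfd_target}")
    ranked = sorted(items, key=lambda it: it.evalue)
    best_r = 0
    for r, item in enumerate(ranked, start=1):
        if item.evalue / r <= pfd_target:
            best_r = r
    retained = ranked[:best_r]
    cutoff = retained[-1].evalue if retained else None
    return retained, cutoff


def apply_evalue_cutoff(items: Sequence, cutoff: float) -> list:
    """Items with evalue <= cutoff (inclusive), input order preserved."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    return [it for it in items if it.evalue <= cutoff]
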