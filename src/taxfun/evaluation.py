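"""Evaluation statistics: sensitivity and proportion of false discoveries,
overlap-coefficient matrices, pairwise log2 fold changes, aggregate
fold-change error metrics, and quasi-gold-standard construction."""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import FunctionAnnotation, ProteinRecord, annotation_index


def percent(fraction: float, decimals: int = 1, mode: str = "half-up") -> float:
    """Render a fraction as a percentage at the requested precision.

    ``mode`` is "half-up" (default, matches printed report precision) or
    "truncate".
    """
    value = Decimal(repr(fraction * 100.0))
    quantum = Decimal(1).scaleb(-decimals)
    if mode == "half-up":
        return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        return float(value.quantize(quantum, rounding="ROUND_DOWN"))
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass(frozen=True)
class SensitivityPfd:
    tp: int
    fp: int
    fn: int
    sensitivity: float  # raw fraction
    pfd: float | None  # raw fraction; None when nothing was reported


@dataclass(frozen=True)
class FoldChangeSet:
    """Log2 fold changes for one pairwise comparison.

    ``pairs`` holds (identifier, computed, true) triples; identifiers missing
    or non-positive in either compared table are excluded and tallied in
    ``n_missing``.
    """

    pairs: tuple[tuple[str, float, float], ...]
    n_missing: int = 0

    @property
    def m(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ErrorMetrics:
    e_error: float
    e_malfce: float
    pct_ev: float  # fraction of pairs with |error| <= threshold
    n_comparisons: int


def sensitivity_pfd(reported: set, gold: set) -> SensitivityPfd:
    """TP/FP/FN counts plus sensitivity TP/(TP+FN) and PFD FP/(TP+FP)."""
    if not gold:
        raise ValueError("gold standard must be nonempty")
    tp = len(reported & gold)
    fp = len(reported - gold)
    fn = len(gold - reported)
    sensitivity = tp / (tp + fn)
    pfd = fp / (tp + fp) if reported else None
    return SensitivityPfd(tp=tp, fp=fp, fn=fn, sensitivity=sensitivity, pfd=pfd)


def overlap_matrix(labeled_sets: Sequence[tuple[str, set]]) -> tuple[list[str], np.ndarray]:
    """O[r, c] = |S_r ∩ S_c| / |S_r|; rows for empty S_r are NaN."""
    if len(labeled_sets) < 2:
        raise ValueError("need at least two sets")
    labels = [label for label, _ in labeled_sets]
    n = len(labeled_sets)
    matrix = np.full((n, n), np.nan)
    for r, (_, sr) in enumerate(labeled_sets):
        if not sr:
            continue
        for c, (_, sc) in enumerate(labeled_sets):
            matrix[r, c] = len(sr & sc) / len(sr)
    return labels, matrix


def log2_fold_changes(
    table_a: Mapping[str, float],
    table_b: Mapping[str, float],
    truth: Mapping[str, float] | float = 0.0,
) -> FoldChangeSet:
    """Per shared identifier, log2(a/b) against the true fold change.

    ``truth`` is either a constant expected log2 fold change or a
    per-identifier map.
    """
    shared = sorted(
        ident
        for ident in set(table_a) & set(table_b)
        if table_a[ident] > 0 and table_b[ident] > 0
    )
    n_missing = len(set(table_a) | set(table_b)) - len(shared)
    if not shared:
        warnings.warn("no shared identifiers with positive abundance")
        return FoldChangeSet(pairs=(), n_missing=n_missing)
    pairs = []
    for ident in shared:
        computed = float(np.log2(table_a[ident] / table_b[ident]))
        true = truth[ident] if isinstance(truth, Mapping) else float(truth)
        pairs.append((ident, computed, true))
    return FoldChangeSet(pairs=tuple(pairs), n_missing=n_missing)


def error_metrics(fc_sets: Sequence[FoldChangeSet], ev_threshold: float = 2.0) -> ErrorMetrics:
    """Aggregate fold-change error over N pairwise comparisons.

    E[Error]  = (1/N) sum_i sum_j (computed_ij - true_ij) / M_i
    E[MALFCE] = (1/N) sum_i sum_j |computed_ij - true_ij| / M_i
    %EV       = fraction of all pairs with |computed - true| <= ev_threshold
    """
    usable = []
    for fc in fc_sets:
        if fc.m == 0:
            warnings.warn("excluding empty fold-change comparison")
            continue
        usable.append(fc)
    if not usable:
        raise ValueError("no nonempty fold-change comparisons")
    n = len(usable)
    e_error = 0.0
    e_malfce = 0.0
    within = 0
    total_pairs = 0
    for fc in usable:
        errors = np.array([computed - true for _, computed, true in fc.pairs])
        e_error += float(errors.mean())
        e_malfce += float(np.abs(errors).mean())
        within += int(np.sum(np.abs(errors) <= ev_threshold))
        total_pairs += fc.m
    return ErrorMetrics(
        e_error=e_error / n,
        e_malfce=e_malfce / n,
        pct_ev=within / total_pairs,
        n_comparisons=n,
    )


def build_quasi_gold(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[FunctionAnnotation] | Mapping[str, frozenset[tuple[str, str]]],
    expected_fp: float = 1.0,
) -> set[tuple[str, str]]:
    """Union of GO terms of all proteins passing the expected-false-positive
    E-value cutoff, without clustering.

    A protein's E-value is the expected false-positive count at its score, so
    the cutoff is simply ``evalue <= expected_fp``.
    """
    if expected_fp <= 0:
        raise ValueError(f"expected_fp must be > 0, got {expected_fp}")
    if isinstance(annotations, Mapping):
        index = annotations
    else:
        index = annotation_index(annotations)
    retained = [p for p in proteins if p.evalue <= expected_fp]
    if not retained:
        warnings.warn("no protein passes the expected-false-positive cutoff")
        return set()
    terms: set[tuple[str, str]] = set()
    for p in retained:
        terms.update(index.get(p.accession, frozenset()))
    return terms


# ---------------------------------------------------------------------------
# writers


def write_metrics_json(metrics: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_matrix_tsv(labels: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + list(labels))
        for label, row in zip(labels, matrix):
            writer.writerow([label] + ["" if np.isnan(v) else repr(float(v)) for v in row])
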