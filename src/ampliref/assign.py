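"""Best-hit species-level classification and database benchmarking.

Implements the threshold rule used to curate body-site 16S databases:
a query is assigned to a species when its best reference hit reaches
98.5% identity over 98% query coverage.  Queries whose best hit falls in
the ambiguous [98, 98.5)% identity band (with coverage met) are set
aside — they are neither confidently assigned nor evidence of a novel
taxon.  Everything else is unassigned and becomes input for the
reference-expansion workflow.

For large reference sets a fast edit-distance prescreen (edlib,
semi-global) ranks references before the exact scored alignment is run
on the small candidate subset; references whose edit distance exceeds
the best by more than ``prescreen_margin`` cannot win the score ranking
for any near-threshold hit and are skipped.  Sets with at most
``prescreen_min_refs`` references are always searched exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .alignment import DEFAULT_SCORING, AlignmentStats, Scoring, align
from .refdb import ReferenceSet

__all__ = [
    "ClassifyConfig",
    "Assignment",
    "BandPartition",
    "SweepGrid",
    "BenchmarkRow",
    "DatabaseComparison",
    "best_hit",
    "classify_set",
    "sweep_thresholds",
    "partition_bands",
    "compare_databases",
]

BAND_ASSIGNED = "assigned"
BAND_AMBIGUOUS = "ambiguous_band"
BAND_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for species-level assignment (percent, inclusive)."""

    id_thresh: float = 98.5
    cov_thresh: float = 98.0
    band_floor: float = 98.0

    def __post_init__(self):
        if self.band_floor > self.id_thresh:
            raise ValueError("band_floor must not exceed id_thresh")

    def band(self, identity: float, coverage: float) -> str:
        if coverage >= self.cov_thresh:
            if identity >= self.id_thresh:
                return BAND_ASSIGNED
            if identity >= self.band_floor:
                return BAND_AMBIGUOUS
        return BAND_UNASSIGNED


@dataclass
class Assignment:
    query_id: str
    best_ref: Optional[str]
    best_hmt: Optional[int]
    stats: Optional[AlignmentStats]
    band: str


@dataclass
class BandPartition:
    assigned: set
    ambiguous_band: set
    unassigned: set


@dataclass
class SweepGrid:
    id_thresholds: list
    cov_thresholds: list
    fraction_identified: np.ndarray  # shape (len(id), len(cov))


@dataclass
class BenchmarkRow:
    database_label: str
    n_reads: int
    n_identified: int

    @property
    def pct_identified(self) -> float:
        if self.n_reads == 0:
            return 0.0
        return 100.0 * self.n_identified / self.n_reads


@dataclass
class DatabaseComparison:
    """Per-query agreement between two databases' species assignments."""

    categories: dict  # query_id -> category string
    counts: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)  # (name_a, name_b) -> n


class _RefIndex:
    """Flat, deterministically ordered view of a ReferenceSet's sequences."""

    def __init__(self, refset: ReferenceSet):
        rows = []
        for taxon, ref in refset.iter_refs():
            rows.append((ref.ref_id, taxon.hmt, ref.sequence))
        rows.sort(key=lambda r: r[0])
        self.rows = rows

    def __len__(self):
        return len(self.rows)


def _candidates(query: str, index: _RefIndex, margin: int, min_refs: int):
    if len(index) <= min_refs:
        return index.rows
    dists = []
    for ref_id, hmt, seq in index.rows:
        d = edlib.align(query, seq, mode="HW", task="distance")["editDistance"]
        if d < 0:  # no alignment under edlib's default cap; treat as far
            d = len(query)
        dists.append(d)
    best = min(dists)
    return [row for row, d in zip(index.rows, dists) if d <= best + margin]


def best_hit(
    query: str,
    refset: ReferenceSet,
    cfg: ClassifyConfig = ClassifyConfig(),
    query_id: str = "",
    scoring: Scoring = DEFAULT_SCORING,
    prescreen_margin: int = 16,
    prescreen_min_refs: int = 8,
    _index: Optional[_RefIndex] = None,
) -> Assignment:
    """Best-scoring reference hit for one query, banded per ``cfg``.

    Ties on score are broken by higher identity, then longer alignment,
    then lexicographically smaller ref_id.
    """
    index = _index if _index is not None else _RefIndex(refset)
    if len(index) == 0:
        raise ValueError("reference set is empty")
    best = None  # (key tuple, ref_id, hmt, stats)
    for ref_id, hmt, seq in _candidates(query, index, prescreen_margin, prescreen_min_refs):
        stats = align(query, seq, scoring)
        key = (stats.score, stats.identity, stats.alignment_length)
        if best is None or key > best[0] or (key == best[0] and ref_id < best[1]):
            best = (key, ref_id, hmt, stats)
    _, ref_id, hmt, stats = best
    band = cfg.band(stats.identity, stats.coverage)
    if band == BAND_UNASSIGNED and stats.score <= 0:
        return Assignment(query_id, None, None, None, BAND_UNASSIGNED)
    return Assignment(query_id, ref_id, hmt, stats, band)


def classify_set(
    queries: Iterable[tuple],
    refset: ReferenceSet,
    cfg: ClassifyConfig = ClassifyConfig(),
    database_label: str = "",
    scoring: Scoring = DEFAULT_SCORING,
    prescreen_margin: int = 16,
    prescreen_min_refs: int = 8,
):
    """Classify ``(query_id, sequence)`` pairs against a reference set.

    Returns ``(assignments, BenchmarkRow)``.  Only band=assigned queries
    count as identified, matching the single >=98.5%/98% criterion of the
    benchmark tables.  Empty/malformed sequences are skipped; their count
    is recorded on the returned row as ``n_skipped``.
    """
    index = _RefIndex(refset)
    assignments = []
    n_skipped = 0
    for query_id, seq in queries:
        if not seq:
            n_skipped += 1
            continue
        assignments.append(
            best_hit(
                seq,
                refset,
                cfg,
                query_id=query_id,
                scoring=scoring,
                prescreen_margin=prescreen_margin,
                prescreen_min_refs=prescreen_min_refs,
                _index=index,
            )
        )
    n_assigned = sum(1 for a in assignments if a.band == BAND_ASSIGNED)
    row = BenchmarkRow(database_label, len(assignments), n_assigned)
    row.n_skipped = n_skipped
    return assignments, row


def partition_bands(assignments: Sequence[Assignment]) -> BandPartition:
    """Disjoint, exhaustive partition of query ids by assignment band."""
    part = BandPartition(set(), set(), set())
    for a in assignments:
        getattr(part, a.band).add(a.query_id)
    return part


def sweep_thresholds(
    queries: Iterable[tuple],
    refset: ReferenceSet,
    id_grid: Sequence[float],
    cov_grid: Sequence[float],
    scoring: Scoring = DEFAULT_SCORING,
    assignments: Optional[list] = None,
) -> SweepGrid:
    """Fraction of queries identified over an identity x coverage grid.

    The best hit is fixed per query (score ranking); each grid cell then
    applies its thresholds to that hit, so the grid is exactly monotone
    non-increasing along both axes.  Precomputed ``assignments`` from a
    :func:`classify_set` run over the same queries/refset may be passed
    to avoid re-aligning (band labels are ignored, only the best-hit
    stats are used).
    """
    id_grid = list(id_grid)
    cov_grid = list(cov_grid)
    if not id_grid or not cov_grid:
        raise ValueError("threshold grids must be non-empty")
    if sorted(id_grid) != id_grid or sorted(cov_grid) != cov_grid:
        raise ValueError("threshold grids must be sorted ascending")
    if assignments is None:
        assignments, _ = classify_set(
            queries, refset, ClassifyConfig(0.0, 0.0, 0.0), scoring=scoring
        )
    n = len(assignments)
    grid = np.zeros((len(id_grid), len(cov_grid)))
    for a in assignments:
        if a.stats is None:
            continue
        for i, idt in enumerate(id_grid):
            if a.stats.identity < idt:
                break
            for c, covt in enumerate(cov_grid):
                if a.stats.coverage < covt:
                    break
                grid[i, c] += 1
    return SweepGrid(id_grid, cov_grid, grid / max(n, 1))


def compare_databases(
    queries: Iterable[tuple],
    refset_a: ReferenceSet,
    refset_b: ReferenceSet,
    cfg: ClassifyConfig = ClassifyConfig(),
    labels: tuple = ("A", "B"),
) -> DatabaseComparison:
    """Per-query species-level agreement between two reference sets.

    Categories: both-same-name, both-different-name, only-A, only-B,
    neither, where "name" is the species-level display name of the
    assigned taxon.
    """
    queries = list(queries)
    assign_a, _ = classify_set(queries, refset_a, cfg, database_label=labels[0])
    assign_b, _ = classify_set(queries, refset_b, cfg, database_label=labels[1])
    name_a = {t.hmt: t.display_name for t in refset_a.taxa.values()}
    name_b = {t.hmt: t.display_name for t in refset_b.taxa.values()}
    categories = {}
    differential = {}
    for a, b in zip(assign_a, assign_b):
        ok_a = a.band == BAND_ASSIGNED
        ok_b = b.band == BAND_ASSIGNED
        if ok_a and ok_b:
            na, nb = name_a[a.best_hmt], name_b[b.best_hmt]
            if na == nb:
                cat = "both-same-name"
            else:
                cat = "both-different-name"
                differential[(na, nb)] = differential.get((na, nb), 0) + 1
        elif ok_a:
            cat = f"only-{labels[0]}"
        elif ok_b:
            cat = f"only-{labels[1]}"
        else:
            cat = "neither"
        categories[a.query_id] = cat
    counts = {}
    for cat in categories.values():
        counts[cat] = counts.get(cat, 0) + 1
    return DatabaseComparison(categories, counts, differential)
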