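"""Collapse BLAST results into unique gene models.

Several assembled sequences frequently share a top database hit.  Two cases
must be told apart: sequences aligning to *non-overlapping* segments of the
shared subject are conservatively treated as unassembled fragments of a single
transcript (counted once), while sequences aligning to *overlapping* segments
are potential paralogs (each counted).  Interval systems that are neither
all-disjoint nor all-overlapping are resolved by the minimal partition of the
intervals into mutually non-overlapping chains, which for intervals equals the
maximum point-depth of overlap; this generalizes both binary cases exactly.

"Overlap" means sharing at least one subject position (closed 1-based
intervals).  An optional tolerance ignores micro-overlaps of up to that many
positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import BlastHit

__all__ = [
    "Classification",
    "TopHitTable",
    "SubjectTally",
    "GeneTally",
    "filter_by_evalue",
    "select_top_hits",
    "classify_shared_subject",
    "unique_gene_tally",
    "mixed_unique_gene_count",
    "species_breakdown",
]


class Classification(str, Enum):
    """How the queries sharing one subject relate to each other."""

    SINGLE = "single"                      # one query
    MERGED_FRAGMENTS = "merged_fragments"  # >= 2 queries, all pairwise disjoint
    PARALOGS = "paralogs"                  # all pairwise overlapping
    MIXED = "mixed"                        # anything else


@dataclass
class TopHitTable:
    """Per-query best hit after e-value filtering, with filter provenance."""

    hits: dict[str, BlastHit]
    evalue_cutoff: float | None = None

    def __len__(self) -> int:
        return len(self.hits)

    def subjects(self) -> dict[str, list[BlastHit]]:
        """Subject id -> the top hits pointing at it (query input order)."""
        by_subject: dict[str, list[BlastHit]] = {}
        for hit in self.hits.values():
            by_subject.setdefault(hit.subject_id, []).append(hit)
        return by_subject


@dataclass
class SubjectTally:
    query_ids: list[str]
    intervals: list[tuple[int, int]]
    classification: Classification
    gene_count: int


@dataclass
class GeneTally:
    """Per-subject classification and the resulting unique-gene count."""

    per_subject: dict[str, SubjectTally]
    mode: str
    total_unique_genes: int = field(init=False)
    n_merged_away: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_unique_genes = sum(t.gene_count for t in self.per_subject.values())
        n_queries = sum(len(t.query_ids) for t in self.per_subject.values())
        self.n_merged_away = n_queries - self.total_unique_genes


def filter_by_evalue(hits: Iterable[BlastHit], cutoff: float) -> list[BlastHit]:
    """Keep hits with evalue <= cutoff, preserving order."""
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be > 0")
    return [h for h in hits if h.evalue <= cutoff]


def select_top_hits(hits: Sequence[BlastHit], evalue_cutoff: float | None = None) -> TopHitTable:
    """Pick each query's best hit: minimal e-value, then maximal bitscore,
    then first occurrence in input order (so BLAST's own output order makes
    the choice reproducible)."""
    best: dict[str, BlastHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (hit.evalue, -hit.bitscore) < (cur.evalue, -cur.bitscore):
            best[hit.query_id] = hit
    return TopHitTable(hits=best, evalue_cutoff=evalue_cutoff)


def _trimmed(intervals: Sequence[tuple[int, int]], tolerance: int) -> list[tuple[int, int]]:
    """Shrink interval ends by `tolerance` so micro-overlaps do not count,
    keeping at least a single-point interval."""
    return [(s, max(s, e - tolerance)) for s, e in intervals]


def _max_depth(intervals: Sequence[tuple[int, int]]) -> int:
    """Maximum number of intervals covering any single point (sweep line)."""
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e + 1, -1))
    depth = best = 0
    for _, delta in sorted(events):
        depth += delta
        best = max(best, depth)
    return best


def classify_shared_subject(
    intervals: Sequence[tuple[int, int]], tolerance: int = 0
) -> tuple[Classification, int]:
    """Classify the subject-axis intervals of queries sharing one top hit.

    The gene count is the minimum number of mutually non-overlapping chains
    needed to cover all intervals; for intervals this equals the maximum
    point-depth of overlap (max clique = chromatic number in interval graphs).
    """
    if not intervals:
        raise ValueError("at least one interval is required")
    for s, e in intervals:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e}): start > end")
    work = _trimmed(intervals, tolerance)
    depth = _max_depth(work)
    n = len(work)
    if n == 1:
        return Classification.SINGLE, 1
    if depth == 1:
        return Classification.MERGED_FRAGMENTS, 1
    if depth == n:
        # pairwise-overlapping intervals share a common point (Helly property),
        # so all-pairwise-overlap is exactly depth == n
        return Classification.PARALOGS, n
    return Classification.MIXED, depth


def unique_gene_tally(
    top: TopHitTable, mode: str = "interval_aware", tolerance: int = 0
) -> GeneTally:
    """Tally unique genes from a top-hit table.

    ``interval_aware`` applies :func:`classify_shared_subject` per subject —
    the rule used for isotigs and contigs.  ``one_per_subject`` counts one
    gene per subject regardless of coordinates — the stricter rule used for
    singletons, whose frequent identical duplicates would otherwise inflate
    the tally.
    """
    if mode not in ("interval_aware", "one_per_subject"):
        raise ValueError(f"unknown tally mode {mode!r}")
    per_subject: dict[str, SubjectTally] = {}
    for subject, hits in top.subjects().items():
        intervals = [h.subject_span for h in hits]
        if mode == "interval_aware":
            classification, count = classify_shared_subject(intervals, tolerance)
        else:
            classification, count = (
                Classification.SINGLE if len(hits) == 1 else Classification.MERGED_FRAGMENTS,
                1,
            )
        per_subject[subject] = SubjectTally(
            query_ids=[h.query_id for h in hits],
            intervals=intervals,
            classification=classification,
            gene_count=count,
        )
    return GeneTally(per_subject=per_subject, mode=mode)


def mixed_unique_gene_count(
    top_assembled: TopHitTable, top_singletons: TopHitTable, tolerance: int = 0
) -> int:
    """Combined unique-gene count for a sub-assembly.

    Assembled sequences (longest isotig per isogroup, plus secondary contigs)
    are tallied interval-aware; singletons contribute one gene per subject,
    and only for subjects not already hit by an assembled sequence (a
    singleton sharing a subject with an assembled query is taken to be a
    fragment of the gene already counted).
    """
    assembled = unique_gene_tally(top_assembled, mode="interval_aware", tolerance=tolerance)
    singleton = unique_gene_tally(top_singletons, mode="one_per_subject")
    extra = sum(
        tally.gene_count
        for subject, tally in singleton.per_subject.items()
        if subject not in assembled.per_subject
    )
    return assembled.total_unique_genes + extra


def species_breakdown(
    top: TopHitTable, taxon_map: Mapping[str, str], min_count: int = 1
) -> dict[str, int]:
    """Count top hits per subject taxon.

    Subjects missing from the map fall into ``"unknown"``; taxa with fewer
    than `min_count` hits are collapsed into ``"other"``.
    """
    counts: Counter[str] = Counter()
    for hit in top.hits.values():
        counts[taxon_map.get(hit.subject_id, "unknown")] += 1
    if min_count > 1:
        collapsed: Counter[str] = Counter()
        for taxon, count in counts.items():
            if count < min_count and taxon not in ("unknown", "other"):
                collapsed["other"] += count
            else:
                collapsed[taxon] += count
        counts = collapsed
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
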