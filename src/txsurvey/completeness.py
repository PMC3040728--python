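"""Transcript completeness: ortholog hit ratios and reference extension gain.

The ortholog hit ratio (OHR) compares the length of a newly assembled
sequence's aligned region against the full length of its top database hit.
A ratio of one implies a transcript assembled to its true full length; values
over one suggest insertions in the query relative to the ortholog.  For
protein subjects (translated searches with nucleotide queries) the aligned
query span is converted to codons before dividing, so that "ratio = 1 means
full length" holds; nucleotide mode divides spans directly.

Poorly conserved regions may fail to align at all, which makes the OHR an
underestimate for such transcripts; no correction is applied, the caveat is
simply surfaced here.

Extension gain asks, for a transcript already represented by a reference
accession, how many bases the new assembly adds beyond the known 5' and 3'
ends, projecting each transcript's unaligned overhang through its alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .io_formats import BlastHit
from .reporting import round_half_up

__all__ = [
    "OhrRecord",
    "TranscriptAlignment",
    "ortholog_hit_ratio",
    "ohr_distribution",
    "extension_gain",
]


@dataclass(frozen=True)
class OhrRecord:
    """One query's ortholog hit ratio against its top hit."""

    query_id: str
    subject_id: str
    aligned_query_span: int  # nt
    subject_len: int         # residues of the subject (aa or nt)
    subject_kind: str        # "protein" | "nucleotide"
    ratio: float
    possible_insertion: bool

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("OHR must be > 0")
        if self.aligned_query_span < 1 or self.subject_len < 1:
            raise ValueError("spans and subject length must be >= 1")


def ortholog_hit_ratio(hit: BlastHit, subject_kind: str = "protein") -> OhrRecord:
    """OHR of one hit: aligned query span over the subject's full length.

    Protein subjects divide the nucleotide span by 3 first.  The ratio is not
    capped; values over one are flagged as possible insertions.
    """
    if subject_kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown subject kind {subject_kind!r}")
    if hit.subject_len is None:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id} lacks subject_len; parse with the "
            "13-column slen dialect or join a subject-lengths table first"
        )
    span = hit.q_end - hit.q_start + 1
    if subject_kind == "protein":
        ratio = (span / 3.0) / hit.subject_len
    else:
        ratio = span / hit.subject_len
    return OhrRecord(
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        aligned_query_span=span,
        subject_len=hit.subject_len,
        subject_kind=subject_kind,
        ratio=ratio,
        possible_insertion=ratio > 1.0,
    )


def ohr_distribution(
    records: Sequence[OhrRecord],
    bin_width: float = 0.1,
    thresholds: Sequence[float] = (0.5, 0.8),
) -> tuple[list[tuple[float, float, int]], dict[float, float]]:
    """Histogram of ratios plus the fraction strictly above each threshold.

    Bins are half-open ``[k*w, (k+1)*w)``; threshold fractions use strict
    ``>`` (a ratio exactly at a threshold does not count).
    """
    if not records:
        raise ValueError("no OHR records")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    counts: dict[int, int] = {}
    for rec in records:
        k = int(rec.ratio / bin_width)
        counts[k] = counts.get(k, 0) + 1
    hist = [
        (round_half_up(k * bin_width, 10), round_half_up((k + 1) * bin_width, 10), counts[k])
        for k in sorted(counts)
    ]
    n = len(records)
    fractions = {t: sum(1 for r in records if r.ratio > t) / n for t in thresholds}
    return hist, fractions


class TranscriptAlignment(NamedTuple):
    """One plus-strand alignment block between a reference and a transcript."""

    ref_start: int
    ref_end: int
    tx_start: int
    tx_end: int
    tx_len: int


def extension_gain(
    reference_len: int, alignments: Sequence[TranscriptAlignment]
) -> tuple[int, int, list[tuple[int, int]]]:
    """Net sequence gain of new transcripts over a known reference accession.

    For each aligned transcript the unaligned transcript bases upstream
    (downstream) of the alignment are projected beyond the reference's first
    (last) aligned base; the gains reported are the maxima over transcripts,
    clamped at zero.  The merged reference span is the union of the aligned
    reference intervals: blocks are merged only when they overlap or abut, so
    a gap bridged solely by the reference itself remains visible as two
    blocks.

    All alignments must be plus-strand with equal-length spans on both axes
    (pre-orient minus hits before calling).
    """
    if reference_len < 1:
        raise ValueError("reference length must be >= 1")
    gain5 = gain3 = 0
    spans: list[tuple[int, int]] = []
    for aln in alignments:
        if aln.ref_start > aln.ref_end or aln.tx_start > aln.tx_end:
            raise ValueError(f"minus-strand or invalid alignment {aln}; pre-orient first")
        if aln.ref_end - aln.ref_start != aln.tx_end - aln.tx_start:
            raise ValueError(f"alignment spans differ in length: {aln}")
        if aln.tx_end > aln.tx_len:
            raise ValueError(f"transcript span exceeds transcript length: {aln}")
        overhang5 = (aln.tx_start - 1) - (aln.ref_start - 1)
        overhang3 = (aln.tx_len - aln.tx_end) - (reference_len - aln.ref_end)
        gain5 = max(gain5, overhang5)
        gain3 = max(gain3, overhang3)
        spans.append((aln.ref_start, aln.ref_end))
    gain5 = max(gain5, 0)
    gain3 = max(gain3, 0)

    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return gain5, gain3, merged
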