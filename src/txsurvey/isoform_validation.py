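"""In-silico validation of assembler-predicted splice isoforms.

Assemblers that model alternative splicing can predict two transcripts of one
gene differing by a single internal exon (e.g. a ~100 bp exon present in the
longer isoform only).  Such predictions are testable by RT-PCR: primers
flanking the differing region should amplify two products whose sizes differ
by the skipped exon's length.  This module extracts candidate isoform pairs
from the assembly hierarchy, predicts amplicon sizes for given primer pairs,
and scores predicted against observed band sizes.

Primer matching is exact (no mismatches, no degenerate bases) — the
experimental uncertainty lives in the band-size comparison instead, whose
default ±10% relative tolerance reflects agarose-gel resolution.  Multiple
primer binding sites enumerate all products (the conservative choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from Bio.Seq import Seq

from .assembly_stats import AssemblySet
from .reporting import report_percent

__all__ = [
    "IsoformPair",
    "BandStatus",
    "BandComparison",
    "BandSummary",
    "find_isoform_pairs",
    "predict_amplicons",
    "compare_bands",
    "summarize_band_cases",
]


@dataclass(frozen=True)
class IsoformPair:
    """Two isotigs of one isogroup differing by exactly one contig."""

    isogroup_id: str
    long_isotig: str
    short_isotig: str
    differing_contig: str
    size_difference: int  # bp, the differing contig's length


class BandStatus(str, Enum):
    ALL_PREDICTED_SEEN = "all_predicted_seen"
    PREDICTED_SEEN_PLUS_EXTRAS = "predicted_seen_plus_extras"
    PARTIAL = "partial"
    UNSUPPORTED = "unsupported"


@dataclass
class BandComparison:
    case_id: str
    predicted: list[int]
    observed: list[int]
    status: BandStatus
    matched: list[tuple[int, int]]  # (predicted, observed) pairs


@dataclass
class BandSummary:
    """Rates over a table of band-comparison cases (report-rounded %)."""

    n_cases: int
    pct_all_predicted_seen: float        # predicted bands all observed (extras allowed)
    pct_with_extras_among_positive: float
    pct_single_product_false_positive: float  # multiple predicted, one band observed


def find_isoform_pairs(assembly: AssemblySet) -> list[IsoformPair]:
    """Isogroups with exactly two isotigs whose contig lists differ by one
    contig present only in the longer isotig."""
    pairs: list[IsoformPair] = []
    for group, isotigs in sorted(assembly.membership.isogroups.items()):
        if len(isotigs) != 2:
            continue
        c0 = set(assembly.membership.isotig_contigs[isotigs[0]])
        c1 = set(assembly.membership.isotig_contigs[isotigs[1]])
        if c0 == c1:
            continue
        if c1 < c0 and len(c0 - c1) == 1:
            long_i, short_i, extra = isotigs[0], isotigs[1], next(iter(c0 - c1))
        elif c0 < c1 and len(c1 - c0) == 1:
            long_i, short_i, extra = isotigs[1], isotigs[0], next(iter(c1 - c0))
        else:
            continue
        pairs.append(
            IsoformPair(
                isogroup_id=group,
                long_isotig=long_i,
                short_isotig=short_i,
                differing_contig=extra,
                size_difference=assembly.contig_info[extra].length,
            )
        )
    return pairs


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def predict_amplicons(template: str, forward: str, reverse: str) -> list[int]:
    """All PCR product sizes for one template and an exact-matching primer
    pair.

    The forward primer is matched on the given strand; the reverse primer is
    matched as its reverse-complement.  Every non-overlapping combination of
    a forward start and a reverse-site end yields a product of size
    ``r_end - f_start + 1`` (1-based inclusive).  No binding site for either
    primer means no products.
    """
    for name, primer in (("forward", forward), ("reverse", reverse)):
        if len(primer) < 10:
            raise ValueError(f"{name} primer shorter than 10 nt")
        if set(primer.upper()) - set("ACGT"):
            raise ValueError(f"{name} primer contains degenerate bases (exact matching only)")
    template = template.upper()
    fwd = forward.upper()
    rev_site = str(Seq(reverse.upper()).reverse_complement())
    products = []
    for f_start in _find_all(template, fwd):
        for r_start in _find_all(template, rev_site):
            if r_start >= f_start + len(fwd):  # primer sites must not overlap
                products.append(r_start + len(rev_site) - f_start)
    return sorted(products)


def compare_bands(
    case_id: str,
    predicted: Sequence[int],
    observed: Sequence[int],
    rel_tolerance: float = 0.1,
) -> BandComparison:
    """Match predicted band sizes to observed ones within a relative
    tolerance and classify the case.

    Each predicted size is greedily matched (in ascending order) to the
    nearest unmatched observed size within ``rel_tolerance * predicted``.
    """
    if any(x <= 0 for x in list(predicted) + list(observed)):
        raise ValueError("band sizes must be positive")
    remaining = sorted(observed)
    matched: list[tuple[int, int]] = []
    unmatched_predicted = []
    for p in sorted(predicted):
        candidates = [o for o in remaining if abs(o - p) <= rel_tolerance * p]
        if candidates:
            best = min(candidates, key=lambda o: abs(o - p))
            remaining.remove(best)
            matched.append((p, best))
        else:
            unmatched_predicted.append(p)
    if not matched:
        status = BandStatus.UNSUPPORTED
    elif unmatched_predicted:
        status = BandStatus.PARTIAL
    elif remaining:
        status = BandStatus.PREDICTED_SEEN_PLUS_EXTRAS
    else:
        status = BandStatus.ALL_PREDICTED_SEEN
    return BandComparison(
        case_id=case_id,
        predicted=sorted(predicted),
        observed=sorted(observed),
        status=status,
        matched=matched,
    )


def summarize_band_cases(cases: Sequence[BandComparison]) -> BandSummary:
    """Aggregate rates over many validation cases.

    A case is positive when every predicted band was observed (extras
    allowed).  The single-product false-positive rate is the fraction of
    multi-band predictions for which only one band was observed at all.
    """
    if not cases:
        raise ValueError("no cases to summarize")
    n = len(cases)
    positive = [
        c
        for c in cases
        if c.status in (BandStatus.ALL_PREDICTED_SEEN, BandStatus.PREDICTED_SEEN_PLUS_EXTRAS)
    ]
    extras = [c for c in positive if c.status is BandStatus.PREDICTED_SEEN_PLUS_EXTRAS]
    multi_pred = [c for c in cases if len(c.predicted) >= 2]
    single_observed = [c for c in multi_pred if len(c.observed) == 1]
    return BandSummary(
        n_cases=n,
        pct_all_predicted_seen=report_percent(len(positive), n),
        pct_with_extras_among_positive=report_percent(len(extras), len(positive))
        if positive
        else 0.0,
        pct_single_product_false_positive=report_percent(len(single_observed), len(multi_pred))
        if multi_pred
        else 0.0,
    )
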