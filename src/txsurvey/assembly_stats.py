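"""Assembly accounting for a contig/isotig/isogroup hierarchy plus singletons.

In the assembler's vocabulary a contig is a branch-free stretch of assembled
reads (an exon or co-transcribed exon set), an isotig is one continuous path
through a set of contigs (a transcript), and an isogroup is the set of isotigs
over one contig set (a gene).  Reads that assemble nowhere remain singletons.
This module computes the summary counts, ratios, N50, length histograms and
per-contig coverage that describe such an assembly.

A caveat for comparisons against assembler reports: some assembler versions
discard contigs shorter than 100 bp from their own accounting; no minimum
length is enforced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import MembershipTable, SequenceRecord
from .reporting import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "ContigInfo",
    "AssemblySet",
    "AssemblySummary",
    "compute_n50",
    "summarize",
    "length_histogram",
    "contig_coverage",
    "longest_isotig_per_isogroup",
]


@dataclass(frozen=True)
class ContigInfo:
    """Per-contig accounting: length (bp), reads used, and their base total."""

    length: int
    n_reads: int
    read_bp: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("contig length must be >= 1")
        if self.read_bp < self.n_reads:
            raise ValueError("read_bp must be >= n_reads (reads are >= 1 bp)")


@dataclass
class AssemblySet:
    """One assembly: hierarchy, isotig sequences, contig info, singletons."""

    membership: MembershipTable
    isotig_seqs: dict[str, SequenceRecord]
    contig_info: dict[str, ContigInfo]
    singleton_seqs: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        missing = self.membership.contig_ids - set(self.contig_info)
        if missing:
            raise ValueError(f"contigs referenced without contig_info: {sorted(missing)[:5]}")

    @property
    def n_isotigs(self) -> int:
        return len(self.membership)

    @property
    def isotig_lengths(self) -> dict[str, int]:
        return {i: len(r) for i, r in self.isotig_seqs.items()}


@dataclass
class AssemblySummary:
    """Raw summary values; `report()` applies one-decimal table rounding."""

    n_isogroups: int
    n_isotigs: int
    n_contigs: int
    n_singletons: int
    mean_isotigs_per_isogroup: float
    frac_single_isotig_isogroups: float
    mean_contigs_per_isotig: float
    isotig_n50: int

    def report(self) -> dict[str, float | int]:
        return {
            "n_isogroups": self.n_isogroups,
            "n_isotigs": self.n_isotigs,
            "n_contigs": self.n_contigs,
            "n_singletons": self.n_singletons,
            "mean_isotigs_per_isogroup": round_half_up(self.mean_isotigs_per_isogroup, 1),
            "pct_single_isotig_isogroups": round_half_up(
                100.0 * self.frac_single_isotig_isogroups, 1
            ),
            "mean_contigs_per_isotig": round_half_up(self.mean_contigs_per_isotig, 1),
            "isotig_n50": self.isotig_n50,
        }


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: sort descending and return the length at which the cumulative sum
    first reaches at least half of the total bases."""
    if not lengths:
        raise ValueError("N50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable: cumulative sum must reach half the total")


def longest_isotig_per_isogroup(assembly: AssemblySet) -> dict[str, str]:
    """For each isogroup, its maximal-length isotig (ties: smallest id)."""
    missing = set(assembly.membership.isotig_to_isogroup) - set(assembly.isotig_seqs)
    if missing:
        raise ValueError(f"isotigs without sequence: {sorted(missing)[:5]}")
    chosen: dict[str, str] = {}
    for group, isotigs in assembly.membership.isogroups.items():
        chosen[group] = min(isotigs, key=lambda i: (-len(assembly.isotig_seqs[i]), i))
    return chosen


def summarize(assembly: AssemblySet, n50_scope: str = "all") -> AssemblySummary:
    """Counts, ratios and N50 for one assembly.

    `n50_scope` selects the isotig set the N50 is computed over: ``"all"``
    isotigs or the ``"longest_per_isogroup"`` representatives.
    """
    membership = assembly.membership
    if len(membership) == 0:
        raise ValueError("cannot summarize an empty assembly")
    groups = membership.isogroups
    n_isogroups = len(groups)
    n_isotigs = len(membership)
    n_single = sum(1 for isotigs in groups.values() if len(isotigs) == 1)
    n_contig_refs = sum(len(c) for c in membership.isotig_contigs.values())

    if n50_scope == "all":
        n50_ids: Iterable[str] = membership.isotig_to_isogroup
    elif n50_scope == "longest_per_isogroup":
        n50_ids = longest_isotig_per_isogroup(assembly).values()
    else:
        raise ValueError(f"unknown n50_scope {n50_scope!r}")
    n50 = compute_n50([len(assembly.isotig_seqs[i]) for i in n50_ids])

    return AssemblySummary(
        n_isogroups=n_isogroups,
        n_isotigs=n_isotigs,
        n_contigs=len(membership.contig_ids),
        n_singletons=len(assembly.singleton_seqs),
        mean_isotigs_per_isogroup=n_isotigs / n_isogroups,
        frac_single_isotig_isogroups=n_single / n_isogroups,
        mean_contigs_per_isotig=n_contig_refs / n_isotigs,
        isotig_n50=n50,
    )


def length_histogram(lengths: Sequence[int], bin_width: int) -> list[tuple[int, int, int]]:
    """Half-open bins ``[k*w, (k+1)*w)`` as (lo, hi, count) triples.

    Only occupied bins are returned, in ascending order; counts sum to the
    number of inputs.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    counts: dict[int, int] = {}
    for length in lengths:
        counts[length // bin_width] = counts.get(length // bin_width, 0) + 1
    return [(k * bin_width, (k + 1) * bin_width, counts[k]) for k in sorted(counts)]


def contig_coverage(info: ContigInfo) -> float:
    """Average read coverage of a contig: read base pairs / contig length."""
    if info.length < 1:
        raise ValueError("contig length must be >= 1")
    if info.read_bp == 0:
        log.warning("contig without assigned reads: coverage 0.0")
        return 0.0
    return info.read_bp / info.length
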