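"""Gene-discovery saturation: seeded subsampling, pluggable assembly, curves.

To ask how thoroughly a sequencing effort sampled the underlying transcript
diversity, progressively larger subsets of the reads are assembled and the
unique annotated genes tallied for each sub-assembly, together with the N50
length of the representative isotigs.  Discovery plateaus while N50 keeps
rising when sequencing has saturated gene content but not transcript length.

Subsets are prefixes of one seeded Fisher–Yates shuffle (numpy PCG64), so
subsets at increasing sizes are nested and the tally is monotone by
construction; pass ``independent=True`` for independent draws per size, which
mimics separately drawn sub-samples at the cost of monotonicity.

The assembler itself is external and sits behind an adapter contract: a
callable ``reads -> (AssemblySet, singleton records)`` that is deterministic
for a fixed input order.  Tests and the bundled analyses use the synthetic
emulator; a real assembler can be wrapped the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .assembly_stats import AssemblySet, compute_n50, longest_isotig_per_isogroup
from .blast_summarizer import filter_by_evalue, mixed_unique_gene_count, select_top_hits
from .io_formats import BlastHit, SequenceRecord

__all__ = [
    "DiscoveryCurvePoint",
    "AssemblerAdapter",
    "BlastSource",
    "interleave_samples",
    "subsample_reads",
    "discovery_curve",
    "plateau_estimate",
]

AssemblerAdapter = Callable[[Sequence[SequenceRecord]], tuple[AssemblySet, list[SequenceRecord]]]
BlastSource = Callable[[Sequence[SequenceRecord]], list[BlastHit]]


@dataclass(frozen=True)
class DiscoveryCurvePoint:
    """(reads used, unique annotated genes, N50) for one sub-assembly."""

    n_reads: int
    unique_hits: int
    n50: int


def interleave_samples(
    reads_a: Sequence[SequenceRecord], reads_b: Sequence[SequenceRecord], seed: int
) -> list[SequenceRecord]:
    """Combine two read sets in seeded uniform random order."""
    combined = list(reads_a) + list(reads_b)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]


def subsample_reads(
    reads: Sequence[SequenceRecord], n: int, seed: int
) -> list[SequenceRecord]:
    """Sample `n` reads without replacement: the first `n` of one seeded
    shuffle, so samples at increasing `n` (same seed) are nested."""
    if not 0 <= n <= len(reads):
        raise ValueError(f"cannot sample {n} of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order[:n]]


def discovery_curve(
    reads: Sequence[SequenceRecord],
    sizes: Sequence[int],
    assembler: AssemblerAdapter,
    blast_source: BlastSource,
    seed: int,
    evalue_cutoff: float = 1e-10,
    independent: bool = False,
) -> list[DiscoveryCurvePoint]:
    """Assemble nested (or independent) read subsets and tally unique genes.

    Per size: subsample -> assemble -> BLAST the longest isotig per isogroup
    (interval-aware tally) and the singletons (one gene per subject) -> count
    unique genes with the mixed rule; N50 is computed over the representative
    isotigs.  Sub-assemblies with no isotigs report N50 = 0.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    points: list[DiscoveryCurvePoint] = []
    for i, size in enumerate(sizes):
        sub_seed = seed + 1 + i if independent else seed
        sub = subsample_reads(reads, size, sub_seed)
        try:
            assembly, singletons = assembler(sub)
        except Exception as exc:  # propagate with the failing size attached
            raise RuntimeError(f"assembler failed at subset size {size}") from exc

        representatives = [
            assembly.isotig_seqs[iso]
            for iso in sorted(longest_isotig_per_isogroup(assembly).values())
        ]
        top_assembled = select_top_hits(
            filter_by_evalue(blast_source(representatives), evalue_cutoff),
            evalue_cutoff=evalue_cutoff,
        )
        top_singletons = select_top_hits(
            filter_by_evalue(blast_source(singletons), evalue_cutoff),
            evalue_cutoff=evalue_cutoff,
        )
        unique = mixed_unique_gene_count(top_assembled, top_singletons)
        n50 = compute_n50([len(r) for r in representatives]) if representatives else 0
        points.append(DiscoveryCurvePoint(n_reads=size, unique_hits=unique, n50=n50))
    return points


def plateau_estimate(
    curve: Sequence[DiscoveryCurvePoint], slope_threshold: float
) -> int | None:
    """Smallest read count at which the forward slope of unique genes per
    read falls below `slope_threshold`; None if discovery never flattens."""
    if len(curve) < 2:
        raise ValueError("plateau estimation needs at least two curve points")
    n = [p.n_reads for p in curve]
    if n != sorted(n) or len(set(n)) != len(n):
        raise ValueError("curve points must have strictly increasing read counts")
    for a, b in zip(curve, curve[1:]):
        slope = (b.unique_hits - a.unique_hits) / (b.n_reads - a.n_reads)
        if slope < slope_threshold:
            return a.n_reads
    return None
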