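"""Worked-example counts from a published 454 transcriptome survey.

A deep pyrosequencing survey of the ovarian and early embryonic transcriptome
of the milkweed bug (a hemimetabolous insect without a sequenced genome) is
the canonical worked example for this pipeline.  Its printed accounting —
reads per sequencing run, assembly tallies, BLASTX hit counts, ortholog hit
ratio fractions and isoform-validation outcomes — is bundled here so that the
derived identities and percentages can be recomputed through the package's
report-rounding path and compared against the published one-decimal figures.

Only printed primary counts are stored; every ratio and percentage is
computed, never transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reporting import report_percent, report_ratio

__all__ = ["SurveyCounts", "MILKWEED_BUG", "accounting_identities", "derived_report"]


@dataclass(frozen=True)
class SurveyCounts:
    """Primary counts printed in a survey report."""

    # reads per sequencing run (ovary pilot, embryo pilot, normalized
    # Titanium, non-normalized Titanium)
    reads_per_run: tuple[int, ...]
    reads_total: int
    reads_used: int            # after quality trimming and adapter screening
    reads_assembled: int       # wholly or partially in contigs
    reads_singleton: int       # left unassembled by the primary assembler

    # assembly hierarchy
    n_isogroups: int
    n_isotigs: int
    n_contigs: int
    n_single_isotig_isogroups: int
    isotig_n50: int

    # secondary assembly of the singletons
    n_cap3_contigs: int
    n_cap3_singlets: int
    n_singletons_after_cap3: int
    n_sequences_total: int     # isotigs + cap3_contigs + cap3_singlets

    # annotation (translated search of the reference protein database)
    n_isotig_hits: int         # longest isotig per isogroup with >= 1 hit
    n_cap3_contig_hits: int
    n_cap3_singlet_hits: int
    n_queries_with_hits: int
    n_nonoverlapping_shared: int  # fragments of one transcript, merged away
    n_overlapping_shared: int     # potential paralogs, all retained
    n_unique_genes: int

    # ortholog hit ratio of the isotigs with hits
    n_ohr_records: int
    n_ohr_gt_05: int
    n_ohr_gt_08: int

    # isoform validation (RT-PCR of predicted isoform pairs)
    n_isoform_cases: int
    n_isoform_single_product: int  # multiple bands predicted, one product seen


MILKWEED_BUG = SurveyCounts(
    reads_per_run=(65_394, 71_911, 656_782, 1_293_323),
    reads_total=2_087_410,
    reads_used=2_041_966,
    reads_assembled=1_773_450,
    reads_singleton=178_770,
    n_isogroups=16_617,
    n_isotigs=21_097,
    n_contigs=22_235,
    n_single_isotig_isogroups=14_562,
    isotig_n50=1_735,
    n_cap3_contigs=28_143,
    n_cap3_singlets=84_388,
    n_singletons_after_cap3=112_531,
    n_sequences_total=133_628,
    n_isotig_hits=7_219,
    n_cap3_contig_hits=2_594,
    n_cap3_singlet_hits=2_367,
    n_queries_with_hits=12_180,
    n_nonoverlapping_shared=1_455,
    n_overlapping_shared=825,
    n_unique_genes=10_775,
    n_ohr_records=7_219,
    n_ohr_gt_05=3_953,
    n_ohr_gt_08=2_689,
    n_isoform_cases=11,
    n_isoform_single_product=1,
)


def accounting_identities(counts: SurveyCounts = MILKWEED_BUG) -> dict[str, int]:
    """Totals recomputed by summation from the primary counts."""
    return {
        "reads_total": sum(counts.reads_per_run),
        "sequences_total": counts.n_isotigs + counts.n_cap3_contigs + counts.n_cap3_singlets,
        "singletons_after_cap3": counts.n_cap3_contigs + counts.n_cap3_singlets,
    }


def derived_report(counts: SurveyCounts = MILKWEED_BUG) -> dict[str, float]:
    """Derived percentages and ratios at report (one-decimal) precision."""
    return {
        "pct_reads_used": report_percent(counts.reads_used, counts.reads_total),
        "pct_reads_assembled": report_percent(counts.reads_assembled, counts.reads_used),
        "pct_reads_singleton": report_percent(counts.reads_singleton, counts.reads_used),
        "pct_single_isotig_isogroups": report_percent(
            counts.n_single_isotig_isogroups, counts.n_isogroups
        ),
        "mean_isotigs_per_isogroup": report_ratio(counts.n_isotigs, counts.n_isogroups),
        "pct_isotig_hit_rate": report_percent(counts.n_isotig_hits, counts.n_isogroups),
        "pct_cap3_contig_hit_rate": report_percent(
            counts.n_cap3_contig_hits, counts.n_cap3_contigs
        ),
        "pct_cap3_singlet_hit_rate": report_percent(
            counts.n_cap3_singlet_hits, counts.n_cap3_singlets
        ),
        "pct_ohr_gt_05": report_percent(counts.n_ohr_gt_05, counts.n_ohr_records),
        "pct_ohr_gt_08": report_percent(counts.n_ohr_gt_08, counts.n_ohr_records),
        "pct_isoform_single_product_false_positive": report_percent(
            counts.n_isoform_single_product, counts.n_isoform_cases
        ),
    }
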