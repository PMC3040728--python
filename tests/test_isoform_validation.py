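"""Isoform pair extraction and in-silico RT-PCR band scoring."""

import numpy as np
import pytest
from Bio.Seq import Seq

from txsurvey.assembly_stats import AssemblySet, ContigInfo
from txsurvey.io_formats import MembershipTable, SequenceRecord
from txsurvey.isoform_validation import (
    BandStatus,
    compare_bands,
    find_isoform_pairs,
    predict_amplicons,
    summarize_band_cases,
)


def assembly_from(groups, contig_lengths):
    """groups: {isogroup: {isotig: [contigs]}}"""
    isotig_to_isogroup = {}
    isotig_contigs = {}
    for g, isotigs in groups.items():
        for isotig, contigs in isotigs.items():
            isotig_to_isogroup[isotig] = g
            isotig_contigs[isotig] = tuple(contigs)
    membership = MembershipTable(isotig_to_isogroup, isotig_contigs)
    seqs = {
        i: SequenceRecord(i, "A" * sum(contig_lengths[c] for c in cs), role="isotig")
        for i, cs in isotig_contigs.items()
    }
    info = {c: ContigInfo(n, 1, n) for c, n in contig_lengths.items()}
    return AssemblySet(membership, seqs, info, {})


def test_find_isoform_pairs_single_differing_contig():
    assembly = assembly_from(
        {"g": {"I1": ["c1", "c2", "c3"], "I2": ["c1", "c3"]}},
        {"c1": 200, "c2": 100, "c3": 150},
    )
    (pair,) = find_isoform_pairs(assembly)
    assert pair.long_isotig == "I1" and pair.short_isotig == "I2"
    assert pair.differing_contig == "c2"
    assert pair.size_difference == 100


def test_find_isoform_pairs_excludes_disjoint_and_triple_groups():
    assembly = assembly_from(
        {
            "g1": {"I1": ["c1", "c2"], "I2": ["c3", "c4"]},       # disjoint paths
            "g2": {"J1": ["c1"], "J2": ["c1", "c2"], "J3": ["c2"]},  # three isotigs
        },
        {"c1": 100, "c2": 100, "c3": 100, "c4": 100},
    )
    assert find_isoform_pairs(assembly) == []


def test_find_isoform_pairs_invariant_to_isotig_order():
    a = assembly_from(
        {"g": {"I1": ["c1", "c2", "c3"], "I2": ["c1", "c3"]}},
        {"c1": 10, "c2": 77, "c3": 10},
    )
    b = assembly_from(
        {"g": {"I2": ["c1", "c3"], "I1": ["c1", "c2", "c3"]}},
        {"c1": 10, "c2": 77, "c3": 10},
    )
    assert find_isoform_pairs(a) == find_isoform_pairs(b)


# ---------------------------------------------------------------------------
# amplicon prediction


def template_with_sites(fwd, insert, rev, rng, flank=60):
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    rev_site = str(Seq(rev).reverse_complement())
    return left + fwd + insert + rev_site + right


def test_predict_amplicons_coordinate_arithmetic():
    fwd, rev = "ACGTACGTAC", "TTGGCCAATT"
    rng = np.random.default_rng(1)
    insert = "".join(rng.choice(list("ACGT"), size=100))
    template = template_with_sites(fwd, insert, rev, rng)
    (size,) = predict_amplicons(template, fwd, rev)
    assert size == len(fwd) + 100 + len(rev)


def test_predict_amplicons_isoforms_differ_by_insert_length():
    fwd, rev = "ACGTACGTAC", "TTGGCCAATT"
    rng = np.random.default_rng(2)
    shared = "".join(rng.choice(list("ACGT"), size=80))
    extra = "".join(rng.choice(list("ACGT"), size=100))
    long_t = template_with_sites(fwd, shared + extra, rev, np.random.default_rng(3))
    short_t = template_with_sites(fwd, shared, rev, np.random.default_rng(3))
    (long_size,) = predict_amplicons(long_t, fwd, rev)
    (short_size,) = predict_amplicons(short_t, fwd, rev)
    assert long_size - short_size == 100


def test_predict_amplicons_absent_primer_gives_no_products():
    rng = np.random.default_rng(4)
    template = "".join(rng.choice(list("ACGT"), size=300))
    assert predict_amplicons(template, "A" * 20, "C" * 20) == []


def test_predict_amplicons_rejects_degenerate_and_short_primers():
    with pytest.raises(ValueError, match="degenerate"):
        predict_amplicons("ACGT" * 50, "ACGTNACGTA", "ACGTACGTAC")
    with pytest.raises(ValueError, match="shorter"):
        predict_amplicons("ACGT" * 50, "ACGTA", "ACGTACGTAC")


def test_predict_amplicons_matches_bruteforce_scan():
    rng = np.random.default_rng(5)
    fwd, rev = "ACGGATCCGT", "TAGGCCTAAT"
    rev_site = str(Seq(rev).reverse_complement())
    for _ in range(25):
        template = "".join(rng.choice(list("ACGT"), size=int(rng.integers(200, 2000))))
        # plant 0-2 of each site at random positions
        for site in (fwd, rev_site):
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, len(template) - len(site)))
                template = template[:pos] + site + template[pos + len(site):]
        expected = sorted(
            j + len(rev_site) - i
            for i in range(len(template))
            if template.startswith(fwd, i)
            for j in range(len(template))
            if template.startswith(rev_site, j) and j >= i + len(fwd)
        )
        assert predict_amplicons(template, fwd, rev) == expected


# ---------------------------------------------------------------------------
# band comparison


@pytest.mark.parametrize(
    "predicted, observed, status",
    [
        ([300, 400], [300, 400], BandStatus.ALL_PREDICTED_SEEN),
        ([300, 400], [300, 400, 650], BandStatus.PREDICTED_SEEN_PLUS_EXTRAS),
        ([300, 400], [300], BandStatus.PARTIAL),
        ([300, 400], [900], BandStatus.UNSUPPORTED),
    ],
)
def test_compare_bands_statuses(predicted, observed, status):
    assert compare_bands("case", predicted, observed).status is status


def test_compare_bands_zero_tolerance_identical_lists():
    comp = compare_bands("case", [150, 250], [150, 250], rel_tolerance=0.0)
    assert comp.status is BandStatus.ALL_PREDICTED_SEEN


def test_compare_bands_tolerance_window():
    assert compare_bands("c", [300], [329]).status is BandStatus.ALL_PREDICTED_SEEN
    assert compare_bands("c", [300], [331]).status is BandStatus.UNSUPPORTED


def test_band_summary_single_product_false_positive_rate():
    # eleven cases, each predicting two bands; one shows a single product
    cases = [
        compare_bands(f"c{k}", [300, 400], [300, 400]) for k in range(10)
    ] + [compare_bands("c10", [300, 400], [300])]
    summary = summarize_band_cases(cases)
    assert summary.n_cases == 11
    assert summary.pct_single_product_false_positive == 9.1
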