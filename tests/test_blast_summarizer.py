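"""Top-hit selection and fragment-vs-paralog collapsing."""

import numpy as np
import pytest

from txsurvey.blast_summarizer import (
    Classification,
    classify_shared_subject,
    filter_by_evalue,
    mixed_unique_gene_count,
    select_top_hits,
    species_breakdown,
    unique_gene_tally,
)
from txsurvey.io_formats import BlastHit


def hit(q, s, evalue=1e-20, bitscore=100.0, span=(1, 100)):
    return BlastHit(
        query_id=q, subject_id=s, pct_identity=95.0, aln_len=span[1] - span[0] + 1,
        mismatches=0, gap_opens=0, q_start=1, q_end=span[1] - span[0] + 1,
        s_start=span[0], s_end=span[1], evalue=evalue, bitscore=bitscore,
    )


def min_chain_partition_bruteforce(intervals):
    """Oracle: minimum number of mutually non-overlapping chains covering all
    intervals, by depth-first search over chain assignments."""
    order = sorted(intervals)
    best = [len(order)]

    def place(i, chain_ends):
        if len(chain_ends) >= best[0]:
            return
        if i == len(order):
            best[0] = len(chain_ends)
            return
        start, end = order[i]
        for j, chain_end in enumerate(chain_ends):
            if start > chain_end:  # closed intervals: no shared position
                old = chain_ends[j]
                chain_ends[j] = end
                place(i + 1, chain_ends)
                chain_ends[j] = old
        chain_ends.append(end)
        place(i + 1, chain_ends)
        chain_ends.pop()

    place(0, [])
    return best[0]


# ---------------------------------------------------------------------------
# filtering and top-hit selection


def test_filter_by_evalue_keeps_at_or_below_cutoff():
    hits = [hit("q1", "s1", evalue=1e-12), hit("q2", "s2", evalue=1e-8)]
    assert [h.query_id for h in filter_by_evalue(hits, 1e-10)] == ["q1"]
    assert filter_by_evalue(hits, 1.0) == hits
    assert filter_by_evalue([], 1e-10) == []


def test_select_top_hits_tie_breaking():
    hits = [
        hit("q1", "s1", evalue=1e-5),
        hit("q1", "s2", evalue=1e-20),
        hit("q2", "sA", evalue=1e-9, bitscore=100.0),
        hit("q2", "sB", evalue=1e-9, bitscore=200.0),
        hit("q3", "sX", evalue=1e-9, bitscore=50.0),
        hit("q3", "sY", evalue=1e-9, bitscore=50.0),
    ]
    top = select_top_hits(hits)
    assert top.hits["q1"].subject_id == "s2"   # lower e-value wins
    assert top.hits["q2"].subject_id == "sB"   # tie -> higher bitscore
    assert top.hits["q3"].subject_id == "sX"   # full tie -> first in input


# ---------------------------------------------------------------------------
# interval classification


@pytest.mark.parametrize(
    "intervals, classification, count",
    [
        ([(1, 100)], Classification.SINGLE, 1),
        ([(1, 100), (150, 250)], Classification.MERGED_FRAGMENTS, 1),
        ([(1, 100), (50, 150)], Classification.PARALOGS, 2),
        ([(1, 100), (90, 160), (150, 250)], Classification.MIXED, 2),
    ],
)
def test_classify_shared_subject_examples(intervals, classification, count):
    assert classify_shared_subject(intervals) == (classification, count)


def test_classify_rejects_invalid_interval():
    with pytest.raises(ValueError):
        classify_shared_subject([(10, 5)])
    with pytest.raises(ValueError):
        classify_shared_subject([])


def test_overlap_tolerance_ignores_micro_overlaps():
    # 5-position overlap: paralogs at tolerance 0, fragments at tolerance >= 5
    intervals = [(1, 100), (96, 200)]
    assert classify_shared_subject(intervals, tolerance=0)[0] is Classification.PARALOGS
    assert classify_shared_subject(intervals, tolerance=5)[0] is Classification.MERGED_FRAGMENTS


def test_gene_count_matches_chain_partition_bruteforce():
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = int(rng.integers(1, 8))
        starts = rng.integers(1, 200, size=n)
        lens = rng.integers(1, 120, size=n)
        intervals = [(int(s), int(s + l)) for s, l in zip(starts, lens)]
        _, count = classify_shared_subject(intervals)
        assert count == min_chain_partition_bruteforce(intervals)


# ---------------------------------------------------------------------------
# tallies


def test_tally_distinct_subjects():
    top = select_top_hits([hit("q1", "s1"), hit("q2", "s2"), hit("q3", "s3")])
    assert unique_gene_tally(top).total_unique_genes == 3


def test_tally_one_per_subject_collapses_regardless_of_overlap():
    top = select_top_hits(
        [
            hit("q1", "s1", span=(1, 50)),
            hit("q2", "s1", span=(60, 90)),
            hit("q3", "s1", span=(10, 40)),
        ]
    )
    tally = unique_gene_tally(top, mode="one_per_subject")
    assert tally.total_unique_genes == 1
    assert tally.n_merged_away == 2


def test_tally_interval_aware_per_subject_sum():
    top = select_top_hits(
        [
            hit("q1", "S1", span=(1, 50)),
            hit("q2", "S1", span=(60, 90)),
            hit("q3", "S2", span=(1, 80)),
            hit("q4", "S2", span=(40, 120)),
        ]
    )
    tally = unique_gene_tally(top, mode="interval_aware")
    assert tally.per_subject["S1"].gene_count == 1
    assert tally.per_subject["S2"].gene_count == 2
    assert tally.total_unique_genes == 3


def test_tally_is_query_order_invariant():
    hits = [
        hit("q1", "S1", span=(1, 50)),
        hit("q2", "S1", span=(30, 90)),
        hit("q3", "S2", span=(1, 80)),
    ]
    forward = unique_gene_tally(select_top_hits(hits))
    backward = unique_gene_tally(select_top_hits(hits[::-1]))
    assert forward.total_unique_genes == backward.total_unique_genes
    assert {
        s: t.gene_count for s, t in forward.per_subject.items()
    } == {s: t.gene_count for s, t in backward.per_subject.items()}


def test_mixed_count_singletons_only_add_new_subjects():
    top_assembled = select_top_hits([hit("i1", "S1"), hit("i2", "S2", span=(1, 60))])
    top_singletons = select_top_hits(
        [hit("r1", "S2", span=(200, 260)), hit("r2", "S3"), hit("r3", "S3")]
    )
    # S1, S2 from assembled sequences; singletons add S3 once and S2 not at all
    assert mixed_unique_gene_count(top_assembled, top_singletons) == 3


def test_species_breakdown_with_collapsing():
    top = select_top_hits([hit("q1", "s1"), hit("q2", "s2"), hit("q3", "s3")])
    taxa = {"s1": "A", "s2": "A", "s3": "B"}
    assert species_breakdown(top, taxa) == {"A": 2, "B": 1}
    assert species_breakdown(top, taxa, min_count=2) == {"A": 2, "other": 1}
    assert species_breakdown(top, {}) == {"unknown": 3}
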