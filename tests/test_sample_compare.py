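"""Library comparison: base equalization, read counts, exact test, FDR."""

import io
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from txsurvey.io_formats import SequenceRecord, read_go_mapping
from txsurvey.reporting import round_half_up
from txsurvey.sample_compare import (
    bh_fdr,
    equalize_bases,
    exclusive_hit_sets,
    fisher_exact_2x2,
    go_term_comparison,
    max_reads_per_contig,
    per_contig_read_counts,
)


def reads(label, lengths):
    return [
        SequenceRecord(f"{label}{i}", "A" * n, role="read") for i, n in enumerate(lengths)
    ]


def fisher_column_enumeration(a, b, c, d):
    """Oracle: exact two-sided p via column-margin binomial products."""
    n = a + b + c + d
    c1, c2, r1 = a + c, b + d, a + b
    lo, hi = max(0, r1 - c2), min(r1, c1)
    weights = {k: comb(c1, k) * comb(c2, r1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


# ---------------------------------------------------------------------------
# base equalization


def test_equalize_bases_equal_totals_unchanged():
    a, b = reads("a", [100, 200]), reads("b", [300])
    pa, pb, target = equalize_bases(a, b)
    assert pa == a and pb == b and target == 300


def test_equalize_bases_truncates_at_read_boundary():
    a = reads("a", [500, 500])
    b = reads("b", [400, 400, 400])
    pa, pb, target = equalize_bases(a, b)
    assert pa == a
    assert [len(r) for r in pb] == [400, 400]  # 800 bp <= 1000 bp target
    assert target == 1000


def test_equalize_bases_oversized_first_read_gives_empty_prefix():
    a = reads("a", [1000])
    b = reads("b", [1500])
    pa, pb, target = equalize_bases(a, b)
    assert pa == a and pb == [] and target == 1000


# ---------------------------------------------------------------------------
# per-contig counts and exclusive sets


def read_hit(read_id, contig, evalue=1e-30, bitscore=100.0):
    from txsurvey.io_formats import BlastHit

    return BlastHit(
        query_id=read_id, subject_id=contig, pct_identity=99.0, aln_len=100,
        mismatches=0, gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
        evalue=evalue, bitscore=bitscore,
    )


def test_per_contig_read_counts_top_hit_rule():
    hits = [
        read_hit("n1", "c1"),
        read_hit("n2", "c1"),
        read_hit("n3", "c1"),
        read_hit("n3", "c2", evalue=1e-10),  # weaker second hit: not counted
        read_hit("x1", "c2"),
    ]
    sample_map = {"n1": "N", "n2": "N", "n3": "N", "x1": "NN"}
    counts = per_contig_read_counts(hits, sample_map)
    assert counts["N"] == {"c1": 3}
    assert counts["NN"] == {"c2": 1}
    assert max_reads_per_contig(counts) == {"N": 3, "NN": 1}


def test_per_contig_read_counts_unknown_read_rejected():
    with pytest.raises(KeyError):
        per_contig_read_counts([read_hit("r1", "c1")], {})


def test_per_contig_read_counts_empty_input():
    assert per_contig_read_counts([], {}) == {}


def test_exclusive_hit_sets_partition():
    only_n, only_nn, both = exclusive_hit_sets({"c1": 2, "c2": 1}, {"c2": 5, "c3": 1})
    assert (only_n, only_nn, both) == ({"c1"}, {"c3"}, {"c2"})
    only_n, only_nn, both = exclusive_hit_sets({"c1": 1}, {})
    assert (only_n, only_nn, both) == ({"c1"}, set(), set())


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_identical_proportions_gives_p_one():
    assert fisher_exact_2x2(5, 95, 5, 95) == pytest.approx(1.0)


def test_fisher_small_table_exact_value():
    # margins (3,3)/(3,3): 4 tables, the two extremes carry 1/20 each
    assert fisher_exact_2x2(3, 0, 0, 3) == pytest.approx(0.1, rel=1e-12)


def test_fisher_published_enrichment_table_bounds_fdr_value():
    # 14/750 annotated in one library vs 1/1124 in the other; the published
    # FDR-adjusted value was 0.006 and the raw p can only be smaller
    p = fisher_exact_2x2(14, 736, 1, 1123)
    assert p <= 0.006
    assert p == pytest.approx(fisher_column_enumeration(14, 736, 1, 1123), rel=1e-12)


def test_fisher_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


def test_fisher_matches_scipy_on_small_tables():
    rng = np.random.default_rng(23)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 6, size=4))
        if a + b + c + d == 0:
            continue
        ours = fisher_exact_2x2(a, b, c, d)
        theirs = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-10)


def test_fisher_doubling_convention():
    p_min = fisher_exact_2x2(3, 0, 0, 3, convention="minlike")
    p_dbl = fisher_exact_2x2(3, 0, 0, 3, convention="doubling")
    assert p_dbl == pytest.approx(0.1, rel=1e-12)  # 2 * one-tail 1/20
    assert p_dbl >= p_min - 1e-15


# ---------------------------------------------------------------------------
# FDR


@pytest.mark.parametrize(
    "ps, expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),  # hand step-up
        ([0.1, 0.1], [0.1, 0.1]),
    ],
)
def test_bh_fdr_examples(ps, expected):
    assert bh_fdr(ps) == pytest.approx(expected)


def test_bh_fdr_dominates_raw_p_and_is_monotone():
    rng = np.random.default_rng(9)
    ps = rng.random(50).tolist()
    qs = bh_fdr(ps)
    assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
    order = np.argsort(ps)
    sorted_qs = [qs[i] for i in order]
    assert all(x <= y + 1e-12 for x, y in zip(sorted_qs, sorted_qs[1:]))
    assert max(qs) <= 1.0


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# GO comparison


def small_annotation():
    return read_go_mapping(
        io.StringIO("q1\tGO:10\nq2\tGO:10\nq3\tGO:11\nq4\tGO:11\nq5\tGO:10;GO:11"),
        io.StringIO("GO:10\tGO:1\nGO:11\tGO:1\nGO:1\t"),
    )


def test_go_comparison_identical_sets_all_p_one():
    ann = small_annotation()
    table = go_term_comparison(["q1", "q3"], ["q1", "q3"], ann)
    assert (table["p"] == 1.0).all()
    assert (table["pct_test"] == table["pct_ref"]).all()


def test_go_comparison_counts_ancestors_once_per_query():
    ann = small_annotation()
    table = go_term_comparison(["q5"], ["q1"], ann).set_index("term")
    # q5 carries GO:10, GO:11 and their shared parent GO:1 exactly once
    assert table.loc["GO:1", "a"] == 1
    assert table.loc["GO:10", "a"] == 1
    assert table.loc["GO:11", "a"] == 1


def test_go_comparison_percentages_at_report_precision():
    # published exemplar: 14/750 = 1.9% vs 1/1124 = 0.09%
    assert round_half_up(100 * 14 / 750, 1) == 1.9
    assert round_half_up(100 * 1 / 1124, 2) == 0.09


def test_go_comparison_q_dominates_p():
    ann = small_annotation()
    table = go_term_comparison(["q1", "q2", "q5"], ["q3", "q4"], ann)
    assert (table["q"] >= table["p"] - 1e-12).all()


def test_go_comparison_rejects_empty_sets():
    with pytest.raises(ValueError):
        go_term_comparison([], [], small_annotation())
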