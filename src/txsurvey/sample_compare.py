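"""Normalized (N) vs non-normalized (NN) cDNA library comparison.

cDNA normalization enzymatically reduces the representation of highly
abundant transcripts before sequencing.  Whether it pays off for de novo
transcriptome surveys is assessed here by mapping each library's reads
against the complete assembly at equal base totals and comparing (a) the
per-contig read counts — normalization should specifically reduce the read
counts of the most abundant contigs — and (b) the GO-term composition of the
genes hit exclusively by one of the two libraries, using a two-sided Fisher's
exact test per term with Benjamini–Hochberg FDR control across terms.

The exact test is computed from integer binomial-product weights with exact
tie comparison (the "point probability <= observed" two-sided convention);
a doubled-one-tail convention is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .blast_summarizer import select_top_hits
from .io_formats import BlastHit, GoAnnotation, SequenceRecord
from .reporting import percent, round_half_up

__all__ = [
    "equalize_bases",
    "per_contig_read_counts",
    "max_reads_per_contig",
    "exclusive_hit_sets",
    "fisher_exact_2x2",
    "bh_fdr",
    "go_term_comparison",
]


def equalize_bases(
    reads_a: Sequence[SequenceRecord], reads_b: Sequence[SequenceRecord]
) -> tuple[list[SequenceRecord], list[SequenceRecord], int]:
    """Equalize two read lists to the same base total.

    The list with more total bases is truncated at a read boundary to the
    largest prefix not exceeding the smaller list's total; the smaller list
    is kept whole.  Returns ``(prefix_a, prefix_b, bp_target)`` where
    `bp_target` is the smaller total (the truncated prefix may undershoot it
    by less than one read).
    """
    if not reads_a or not reads_b:
        raise ValueError("both read lists must be non-empty")
    total_a = sum(len(r) for r in reads_a)
    total_b = sum(len(r) for r in reads_b)
    target = min(total_a, total_b)

    def prefix(reads: Sequence[SequenceRecord], budget: int) -> list[SequenceRecord]:
        out: list[SequenceRecord] = []
        used = 0
        for rec in reads:
            if used + len(rec) > budget:
                break
            out.append(rec)
            used += len(rec)
        return out

    pa = list(reads_a) if total_a <= target else prefix(reads_a, target)
    pb = list(reads_b) if total_b <= target else prefix(reads_b, target)
    return pa, pb, target


def per_contig_read_counts(
    read_hits: Sequence[BlastHit],
    sample_map: Mapping[str, str],
    evalue_cutoff: float = 1e-4,
) -> dict[str, Counter[str]]:
    """Per-sample read counts per contig from read-vs-assembly hits.

    Each read contributes once, at its top hit (after e-value filtering).
    Every read that has a hit must appear in `sample_map`.
    """
    top = select_top_hits(
        [h for h in read_hits if h.evalue <= evalue_cutoff], evalue_cutoff=evalue_cutoff
    )
    counts: dict[str, Counter[str]] = {}
    for read_id, hit in top.hits.items():
        if read_id not in sample_map:
            raise KeyError(f"read {read_id!r} missing from the sample map")
        counts.setdefault(sample_map[read_id], Counter())[hit.subject_id] += 1
    return counts


def max_reads_per_contig(counts: Mapping[str, Counter[str]]) -> dict[str, int]:
    """The most-covered contig's read count, per sample (0 if no hits)."""
    return {sample: (max(c.values()) if c else 0) for sample, c in counts.items()}


def exclusive_hit_sets(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[set[str], set[str], set[str]]:
    """Partition the union of hit ids into (only_a, only_b, both)."""
    a, b = set(counts_a), set(counts_b)
    return a - b, b - a, a & b


def fisher_exact_2x2(a: int, b: int, c: int, d: int, convention: str = "minlike") -> float:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    ``minlike`` (default) sums the probabilities of all tables with the given
    margins whose point probability does not exceed the observed table's —
    the convention of the common exact-test implementations — with ties
    decided exactly on integer weights.  ``doubling`` doubles the smaller
    tail (observed included), capped at 1.
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not isinstance(x, (int,)) or x < 0:
            raise ValueError(f"cell {name} must be a non-negative integer, got {x!r}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table: margins are degenerate")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # integer weights proportional to the hypergeometric point probabilities
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    w_obs = weights[a - lo]
    if convention == "minlike":
        p_num = sum(w for w in weights if w <= w_obs)
    elif convention == "doubling":
        left = sum(weights[: a - lo + 1])
        right = sum(weights[a - lo :])
        p_num = min(2 * min(left, right), total)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return p_num / total


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    ps = list(pvalues)
    if not ps:
        return []
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def go_term_comparison(
    set_a: Iterable[str],
    set_b: Iterable[str],
    annotation: GoAnnotation,
    label_a: str = "A",
    label_b: str = "B",
    convention: str = "minlike",
    pct_digits: int = 1,
) -> pd.DataFrame:
    """Per-term enrichment between two gene/contig id sets.

    Each query contributes each ancestor-closed term at most once.  For a
    term with `a` annotated queries of ``n_a`` in set A and `b` of ``n_b`` in
    set B, the two-sided exact p comes from the table [[a, n_a - a],
    [b, n_b - b]]; q is the BH-FDR adjustment across all tested terms.
    Unannotated queries count toward the set sizes but carry no terms.

    Returns one row per term with counts, percentages (full precision and at
    report precision), p and q, sorted by p.
    """
    ids_a, ids_b = list(dict.fromkeys(set_a)), list(dict.fromkeys(set_b))
    if not ids_a and not ids_b:
        raise ValueError("both query sets are empty")
    n_a, n_b = len(ids_a), len(ids_b)

    term_counts_a: Counter[str] = Counter()
    term_counts_b: Counter[str] = Counter()
    for qid in ids_a:
        term_counts_a.update(annotation.terms_for(qid))
    for qid in ids_b:
        term_counts_b.update(annotation.terms_for(qid))

    terms = sorted(set(term_counts_a) | set(term_counts_b))
    rows = []
    for term in terms:
        count_a, count_b = term_counts_a.get(term, 0), term_counts_b.get(term, 0)
        p = fisher_exact_2x2(count_a, n_a - count_a, count_b, n_b - count_b, convention)
        rows.append(
            {
                "term": term,
                "label": annotation.labels.get(term, ""),
                "a": count_a,
                "n_test": n_a,
                "b": count_b,
                "n_ref": n_b,
                "pct_test": percent(count_a, n_a) if n_a else 0.0,
                "pct_ref": percent(count_b, n_b) if n_b else 0.0,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "label", "a", "n_test", "b", "n_ref", "pct_test", "pct_ref", "p"],
    )
    if len(table):
        table["q"] = bh_fdr(table["p"].tolist())
        table["pct_test_report"] = [round_half_up(x, pct_digits) for x in table["pct_test"]]
        table["pct_ref_report"] = [round_half_up(x, pct_digits) for x in table["pct_ref"]]
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = []
    return table
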