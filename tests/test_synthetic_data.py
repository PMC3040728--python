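"""Ground-truth simulator and assembler/BLAST emulator."""

import numpy as np
import pytest
from Bio.Seq import Seq

from txsurvey import synthetic_data as sd
from txsurvey.blast_summarizer import (
    Classification,
    filter_by_evalue,
    select_top_hits,
    unique_gene_tally,
)
from txsurvey.completeness import ortholog_hit_ratio


def test_simulation_is_deterministic_for_a_seed():
    cfg = sd.SimConfig(n_genes=8, n_paralog_pairs=1, seed=5)
    t1, t2 = sd.simulate_transcriptome(cfg), sd.simulate_transcriptome(cfg)
    assert [g.protein.residues for g in t1.genes.values()] == [
        g.protein.residues for g in t2.genes.values()
    ]
    assert {i: t1.transcript_seq(i) for i in t1.isoforms} == {
        i: t2.transcript_seq(i) for i in t2.isoforms
    }
    r1 = sd.simulate_reads(t1, "N", n_reads=50, seed=3)
    r2 = sd.simulate_reads(t2, "N", n_reads=50, seed=3)
    assert [(a.id, a.residues) for a in r1.records] == [(b.id, b.residues) for b in r2.records]


def test_no_isoforms_means_one_transcript_per_gene():
    cfg = sd.SimConfig(n_genes=3, n_paralog_pairs=0, isoform_probability=0.0, seed=1)
    truth = sd.simulate_transcriptome(cfg)
    assert len(truth.isoforms) == 3
    assert len(truth.reference_proteins) == 3


def test_skipped_exon_isoform_length_difference():
    cfg = sd.SimConfig(
        n_genes=4, n_paralog_pairs=0, isoform_probability=1.0,
        exons_per_transcript=(3, 3), exon_length=(100, 100), seed=2,
    )
    truth = sd.simulate_transcriptome(cfg)
    for gid in truth.genes:
        long_t = truth.transcript_seq(f"{gid}.i0")
        short_t = truth.transcript_seq(f"{gid}.i1")
        assert len(long_t) - len(short_t) == 100


def test_coding_region_translates_to_reference_protein():
    cfg = sd.SimConfig(n_genes=5, n_paralog_pairs=1, seed=7)
    truth = sd.simulate_transcriptome(cfg)
    for gene in truth.genes.values():
        coding = "".join(
            u.seq[: u.coding_bp] for u in gene.units if u.kind == "exon"
        )
        assert str(Seq(coding).translate()) == gene.protein.residues


def test_paralog_pairs_share_subject_at_high_identity():
    cfg = sd.SimConfig(n_genes=6, n_paralog_pairs=2, seed=3)
    truth = sd.simulate_transcriptome(cfg)
    assert len(truth.paralog_pairs) == 2
    for anchor_id, copy_id in truth.paralog_pairs:
        anchor, copy = truth.genes[anchor_id], truth.genes[copy_id]
        assert copy.subject_id == anchor.protein.id
        identical = sum(
            a == b for a, b in zip(anchor.protein.residues, copy.protein.residues)
        )
        assert identical / len(anchor.protein) >= 0.80
        # the copy's own protein is not part of the reference proteome
        assert copy.protein.id not in {p.id for p in truth.reference_proteins}


def test_gamma_zero_samples_transcripts_uniformly():
    cfg = sd.SimConfig(
        n_genes=10, n_paralog_pairs=0, isoform_probability=0.0,
        abundance_sigma=2.0, seed=11,
    )
    truth = sd.simulate_transcriptome(cfg)
    rs = sd.simulate_reads(truth, "U", n_reads=5000, gamma=0.0, seed=1)
    counts = np.zeros(10)
    for origin in rs.provenance.values():
        counts[int(origin.isoform_id[1:4])] += 1
    # each transcript expects 500 reads; allow generous sampling noise
    assert counts.min() > 350 and counts.max() < 650


def test_read_lengths_respect_floor_and_transcript_end():
    cfg = sd.SimConfig(n_genes=4, n_paralog_pairs=0, seed=13)
    truth = sd.simulate_transcriptome(cfg)
    rs = sd.simulate_reads(truth, "N", n_reads=300, seed=5)
    for rec in rs.records:
        origin = rs.provenance[rec.id]
        tx_len = len(truth.transcript_seq(origin.isoform_id))
        assert len(rec) == origin.length
        assert origin.start + origin.length <= tx_len
        assert origin.length >= cfg.read_length_min or origin.start + origin.length == tx_len


def test_zero_reads_gives_empty_readset_and_assembly():
    cfg = sd.SimConfig(n_genes=3, n_paralog_pairs=0, seed=1)
    truth = sd.simulate_transcriptome(cfg)
    rs = sd.simulate_reads(truth, "N", n_reads=0, seed=1)
    assert rs.records == []
    emulated = sd.emulate_assembly(rs, truth)
    assert len(emulated.assembly.membership) == 0 and emulated.singletons == []


def test_two_expressed_isoforms_become_two_isotigs_in_one_isogroup(small_truth):
    truth = small_truth
    two_iso_genes = {
        g for g in truth.genes if f"{g}.i1" in truth.isoforms
    }
    assert two_iso_genes, "fixture should contain at least one spliced gene"
    reads = sd.simulate_reads(truth, "N", n_reads=4000, gamma=0.0, seed=9)
    emulated = sd.emulate_assembly(reads, truth, k_min=1)
    groups = emulated.assembly.membership.isogroups
    for gid in two_iso_genes:
        assert len(groups[gid]) == 2


def test_undersampled_gene_remains_singletons():
    cfg = sd.SimConfig(n_genes=1, n_paralog_pairs=0, isoform_probability=0.0, seed=4)
    truth = sd.simulate_transcriptome(cfg)
    rs = sd.simulate_reads(truth, "N", n_reads=1, seed=4)
    emulated = sd.emulate_assembly(rs, truth, k_min=2)
    assert len(emulated.singletons) == 1
    assert len(emulated.assembly.membership) == 0


def test_emulated_blast_coordinates_give_expected_ohr():
    cfg = sd.SimConfig(
        n_genes=1, n_paralog_pairs=0, isoform_probability=0.0,
        exons_per_transcript=(1, 1), exon_length=(300, 300), utr_length=(50, 50), seed=6,
    )
    truth = sd.simulate_transcriptome(cfg)
    iso_id = next(iter(truth.isoforms))
    # one synthetic read covering exactly the first half of the coding exon
    tx = truth.transcript_seq(iso_id)
    rec = sd.SequenceRecord("r0", tx[50 : 50 + 150], role="read")
    rs = sd.ReadSet("N", [rec], {"r0": sd.ReadOrigin(iso_id, 50, 150)})
    emulated = sd.emulate_assembly(rs, truth, k_min=1)
    (hit,) = sd.emulate_blast(emulated, truth)
    assert hit.subject_span == (1, 50)  # codons 1..50 of the 100-aa protein
    assert ortholog_hit_ratio(hit).ratio == pytest.approx(0.5, abs=1 / 100)


def test_emulated_blast_rejects_unknown_query(small_truth, small_reads):
    emulated = sd.emulate_assembly(small_reads, small_truth)
    with pytest.raises(KeyError, match="provenance"):
        sd.emulate_blast(emulated, small_truth, queries=["nonsense"])


def test_fully_expressed_paralog_pair_counts_as_two(small_truth, small_reads, small_assembly):
    from txsurvey.assembly_stats import longest_isotig_per_isogroup

    longest = longest_isotig_per_isogroup(small_assembly.assembly)
    hits = sd.emulate_blast(small_assembly, small_truth, queries=sorted(longest.values()))
    top = select_top_hits(filter_by_evalue(hits, 1e-10))
    tally = unique_gene_tally(top)
    for anchor_id, _ in small_truth.paralog_pairs:
        subject = small_truth.genes[anchor_id].subject_id
        assert tally.per_subject[subject].classification is Classification.PARALOGS
        assert tally.per_subject[subject].gene_count == 2


def test_end_to_end_unique_gene_recovery(small_truth, small_reads, small_assembly):
    """At saturating coverage the pipeline's unique-gene count equals the
    number of simulated genes (paralog pairs contributing two each)."""
    from txsurvey.assembly_stats import longest_isotig_per_isogroup
    from txsurvey.blast_summarizer import mixed_unique_gene_count

    longest = longest_isotig_per_isogroup(small_assembly.assembly)
    top_a = select_top_hits(
        filter_by_evalue(
            sd.emulate_blast(small_assembly, small_truth, queries=sorted(longest.values())),
            1e-10,
        )
    )
    top_s = select_top_hits(
        filter_by_evalue(
            sd.emulate_blast(
                small_assembly, small_truth, queries=[r.id for r in small_assembly.singletons]
            ),
            1e-10,
        )
    )
    assert mixed_unique_gene_count(top_a, top_s) == small_truth.config.n_genes


def test_read_mapping_hits_own_gene_contigs(small_truth, small_reads, small_assembly):
    hits = sd.emulate_read_mapping(small_reads, small_assembly, small_truth)
    assert hits, "saturating coverage should map nearly all reads"
    for hit in hits[:200]:
        origin = small_reads.provenance[hit.query_id]
        gene = small_truth.gene_of_read(origin)
        assert small_assembly.contig_gene[hit.subject_id] == gene


def test_go_annotation_is_closed_and_deterministic(small_truth):
    ann1 = sd.simulate_go_annotation(small_truth, seed=3)
    ann2 = sd.simulate_go_annotation(small_truth, seed=3)
    assert ann1.query_terms == ann2.query_terms
    for gid in small_truth.genes:
        terms = ann1.terms_for(gid)
        assert "GO:0000001" in terms  # root reached through the closure


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        sd.SimConfig(n_genes=2, n_paralog_pairs=3)
    with pytest.raises(ValueError):
        sd.SimConfig(gamma=1.5)
    with pytest.raises(ValueError):
        sd.SimConfig(exon_length=(200, 100))
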