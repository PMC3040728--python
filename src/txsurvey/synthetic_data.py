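"""Synthetic transcriptomes with known ground truth for pipeline testing.

Generates a reference proteome, genes with exon structure and UTRs, optional
skipped-exon splice isoforms, paralog pairs, log-normal expression levels,
pyrosequencing-style reads, an emulated assembly (contig/isotig/isogroup
hierarchy plus singletons), and emulated tabular BLAST hits with exact
coordinates — so every downstream stage is testable against known truth
without external data or external tools.

Two deliberate simplifications, documented prominently:

* **The assembler emulator assembles by read provenance, not by overlap
  detection.**  It exists to produce structurally faithful input for the
  downstream statistics (hierarchy, coverage, singletons), not to model any
  real assembler's graph algorithm.  Exon regions of a gene covered by at
  least ``k_min`` reads become contigs; expressed isoforms over those contigs
  become isotigs within one isogroup per gene; genes with fewer than
  ``k_min`` reads contribute their reads as singletons.
* **Emulated e-values are rank-faithful stand-ins** (monotone decreasing in
  aligned length); downstream logic uses only ordering and thresholds, so
  nothing more is needed.

cDNA normalization is modeled as a flattening exponent ``gamma`` on the
sampling weights (weight ∝ abundance**gamma): ``gamma = 1`` reproduces the
abundance distribution (non-normalized), smaller values preferentially
reduce the sampling of the most abundant transcripts, ``gamma = 0`` is
uniform.  Enzymatic normalization kinetics are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .assembly_stats import AssemblySet, ContigInfo
from .io_formats import (
    BlastHit,
    GoAnnotation,
    MembershipTable,
    SequenceRecord,
    _closure,
    write_fasta,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReadSet",
    "EmulatedAssembly",
    "EmulatorPipeline",
    "simulate_transcriptome",
    "simulate_reads",
    "emulate_assembly",
    "emulate_blast",
    "emulate_read_mapping",
    "simulate_go_annotation",
    "export_simulation",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid, so back-translation is exact and stop-free
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the simulated study.

    Defaults emulate a deep 454-style survey at desk scale: Titanium-like
    read lengths (mean 310 bp, sd 80, floor 50 bp — shorter reads are the
    ones a real pipeline discards), log-normal expression with sigma 1.5
    (the dispersion typical of bulk transcriptomes), a handful of paralog
    pairs, and an assembly threshold of 2 reads per exon region.
    """

    n_genes: int = 60
    n_paralog_pairs: int = 3
    isoform_probability: float = 0.2
    exons_per_transcript: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (90, 360)       # bp
    utr_length: tuple[int, int] = (30, 200)        # bp, each end
    abundance_mu: float = 0.0                      # log-normal location
    abundance_sigma: float = 1.5                   # log-normal scale
    read_length_mean: float = 310.0                # bp
    read_length_sd: float = 80.0
    read_length_min: int = 50
    n_reads: int = 4000                            # per sample
    gamma: float = 1.0                             # normalization exponent
    k_min: int = 2                                 # reads needed to assemble a region
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_paralog_pairs or 2 * self.n_paralog_pairs > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_paralog_pairs")
        if not 0.0 <= self.isoform_probability <= 1.0:
            raise ValueError("isoform_probability must be in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        for name, (lo, hi) in (
            ("exons_per_transcript", self.exons_per_transcript),
            ("exon_length", self.exon_length),
            ("utr_length", self.utr_length),
        ):
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is infeasible")
        if self.exons_per_transcript[0] < 1 or self.exon_length[0] < 3:
            raise ValueError("need at least one exon of >= 3 bp")
        if self.read_length_min < 1 or self.k_min < 1 or self.n_reads < 0:
            raise ValueError("read_length_min and k_min must be >= 1, n_reads >= 0")


@dataclass(frozen=True)
class Unit:
    """One transcribed block of a gene: a UTR flank or a coding exon.

    ``coding_offset`` is the unit's start on the gene's coding axis (bp,
    0-based); ``coding_bp`` is how many of its leading bases are coding (the
    last exon may carry a <3 bp non-coding tail from frame rounding).
    """

    id: str
    kind: str  # "utr5" | "exon" | "utr3"
    seq: str
    coding_offset: int | None
    coding_bp: int

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Isoform:
    id: str
    gene_id: str
    unit_ids: tuple[str, ...]
    abundance: float


@dataclass(frozen=True)
class Gene:
    id: str
    units: tuple[Unit, ...]
    protein: SequenceRecord
    subject_id: str          # best reference subject (the anchor's protein for paralog copies)
    coding_len: int          # bp
    paralog_of: str | None


@dataclass
class ReadOrigin:
    isoform_id: str
    start: int   # 0-based on the transcript
    length: int


@dataclass
class ReadSet:
    sample: str
    records: list[SequenceRecord]
    provenance: dict[str, ReadOrigin]

    def total_bp(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass
class GroundTruth:
    """The simulator's full truth: genes, isoforms, proteins, provenance."""

    config: SimConfig
    genes: dict[str, Gene]
    isoforms: dict[str, Isoform]
    paralog_pairs: list[tuple[str, str]]
    _units: dict[str, Unit] = field(default_factory=dict, repr=False)
    _tx_cache: dict[str, str] = field(default_factory=dict, repr=False)
    _off_cache: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            for unit in gene.units:
                self._units[unit.id] = unit

    @property
    def proteins(self) -> dict[str, SequenceRecord]:
        return {g.protein.id: g.protein for g in self.genes.values()}

    @property
    def reference_proteins(self) -> list[SequenceRecord]:
        """The reference proteome: paralog-copy proteins are excluded, so
        both members of a pair share one best subject."""
        return [g.protein for g in self.genes.values() if g.paralog_of is None]

    def unit(self, unit_id: str) -> Unit:
        return self._units[unit_id]

    def transcript_units(self, isoform_id: str) -> list[Unit]:
        return [self._units[u] for u in self.isoforms[isoform_id].unit_ids]

    def transcript_seq(self, isoform_id: str) -> str:
        if isoform_id not in self._tx_cache:
            self._tx_cache[isoform_id] = "".join(
                u.seq for u in self.transcript_units(isoform_id)
            )
        return self._tx_cache[isoform_id]

    def unit_offsets(self, isoform_id: str) -> dict[str, tuple[int, int]]:
        """unit id -> half-open [start, end) span on the transcript."""
        if isoform_id not in self._off_cache:
            offsets: dict[str, tuple[int, int]] = {}
            pos = 0
            for unit in self.transcript_units(isoform_id):
                offsets[unit.id] = (pos, pos + len(unit))
                pos += len(unit)
            self._off_cache[isoform_id] = offsets
        return self._off_cache[isoform_id]

    def protein_len(self, subject_id: str) -> int:
        return len(self.proteins[subject_id])

    def gene_of_read(self, origin: ReadOrigin) -> str:
        return self.isoforms[origin.isoform_id].gene_id


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float = 0.10) -> str:
    """Substitute ~`rate` of residues, each with a random different one."""
    out = list(protein)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        choices = [a for a in _AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def backtranslate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _build_units(
    rng: np.random.Generator,
    gid: str,
    protein_seq: str,
    exon_lens: Sequence[int],
    utr5_len: int,
    utr3_len: int,
) -> tuple[Unit, ...]:
    coding = backtranslate(protein_seq)
    units = [Unit(f"{gid}.u5", "utr5", _random_nt(rng, utr5_len), None, 0)]
    off = 0
    for j, length in enumerate(exon_lens):
        seq = coding[off : off + length]
        if len(seq) < length:  # tail of the last exon beyond the frame
            seq += _random_nt(rng, length - len(seq))
        coding_bp = max(0, min(length, len(coding) - off))
        units.append(Unit(f"{gid}.e{j}", "exon", seq, off, coding_bp))
        off += length
    units.append(Unit(f"{gid}.u3", "utr3", _random_nt(rng, utr3_len), None, 0))
    return tuple(units)


def simulate_transcriptome(config: SimConfig) -> GroundTruth:
    """Draw a ground-truth transcriptome; deterministic for a fixed seed.

    The first ``2 * n_paralog_pairs`` genes form paralog pairs: each
    odd-indexed gene is a copy of its predecessor with ~10% of residues
    substituted, sharing the predecessor's protein as best reference subject.
    Genes selected for alternative splicing (and with >= 3 exons) get a
    second isoform lacking one internal exon.
    """
    rng = np.random.default_rng(config.seed)
    e_lo, e_hi = config.exons_per_transcript
    x_lo, x_hi = config.exon_length
    u_lo, u_hi = config.utr_length

    genes: dict[str, Gene] = {}
    isoforms: dict[str, Isoform] = {}
    pairs: list[tuple[str, str]] = []

    for i in range(config.n_genes):
        gid = f"g{i:03d}"
        is_copy = i < 2 * config.n_paralog_pairs and i % 2 == 1
        utr5_len = int(rng.integers(u_lo, u_hi + 1))
        utr3_len = int(rng.integers(u_lo, u_hi + 1))
        if is_copy:
            anchor = genes[f"g{i - 1:03d}"]
            exon_lens = [len(u) for u in anchor.units if u.kind == "exon"]
            protein_seq = _mutate_protein(rng, anchor.protein.residues)
            subject_id = anchor.protein.id
            paralog_of = anchor.id
            pairs.append((anchor.id, gid))
        else:
            n_exons = int(rng.integers(e_lo, e_hi + 1))
            exon_lens = [int(rng.integers(x_lo, x_hi + 1)) for _ in range(n_exons)]
            protein_seq = _random_protein(rng, sum(exon_lens) // 3)
            subject_id = f"{gid}.p"
            paralog_of = None
        if not protein_seq:
            raise ValueError("exon length ranges too small to encode any protein")
        protein = SequenceRecord(
            f"{gid}.p", protein_seq, description=f"protein of {gid}", role="reference_protein"
        )
        units = _build_units(rng, gid, protein_seq, exon_lens, utr5_len, utr3_len)
        genes[gid] = Gene(
            id=gid,
            units=units,
            protein=protein,
            subject_id=subject_id,
            coding_len=3 * len(protein_seq),
            paralog_of=paralog_of,
        )

        n_exons = len(exon_lens)
        wants_isoform = rng.random() < config.isoform_probability
        has_isoform = wants_isoform and n_exons >= 3 and not is_copy
        abundance = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
        n_iso = 2 if has_isoform else 1
        all_unit_ids = tuple(u.id for u in units)
        isoforms[f"{gid}.i0"] = Isoform(f"{gid}.i0", gid, all_unit_ids, abundance / n_iso)
        if has_isoform:
            skip = int(rng.integers(1, n_exons - 1))  # internal exon index
            short_ids = tuple(u for u in all_unit_ids if u != f"{gid}.e{skip}")
            isoforms[f"{gid}.i1"] = Isoform(f"{gid}.i1", gid, short_ids, abundance / n_iso)

    return GroundTruth(config=config, genes=genes, isoforms=isoforms, paralog_pairs=pairs)


def simulate_reads(
    truth: GroundTruth,
    sample_label: str,
    n_reads: int | None = None,
    gamma: float | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw reads: transcripts with weight ∝ abundance**gamma, start uniform
    along the transcript, length from the configured (truncated) normal."""
    cfg = truth.config
    n_reads = cfg.n_reads if n_reads is None else n_reads
    gamma = cfg.gamma if gamma is None else gamma
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")

    rng = np.random.default_rng(seed)
    iso_ids = sorted(truth.isoforms)
    abundances = np.array([truth.isoforms[i].abundance for i in iso_ids])
    weights = np.ones_like(abundances) if gamma == 0.0 else abundances**gamma
    probs = weights / weights.sum()

    records: list[SequenceRecord] = []
    provenance: dict[str, ReadOrigin] = {}
    if n_reads == 0:
        return ReadSet(sample_label, records, provenance)
    picks = rng.choice(len(iso_ids), size=n_reads, p=probs)
    raw_lengths = rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=n_reads)
    start_fracs = rng.random(n_reads)
    for k in range(n_reads):
        iso_id = iso_ids[picks[k]]
        tx = truth.transcript_seq(iso_id)
        start = int(start_fracs[k] * max(1, len(tx) - cfg.read_length_min + 1))
        length = max(cfg.read_length_min, int(round(raw_lengths[k])))
        length = min(length, len(tx) - start)
        rid = f"{sample_label}_r{k:06d}"
        records.append(SequenceRecord(rid, tx[start : start + length], role="read"))
        provenance[rid] = ReadOrigin(iso_id, start, length)
    return ReadSet(sample_label, records, provenance)


@dataclass
class QueryOrigin:
    """Where an assembled sequence (or singleton read) came from: its gene,
    its best reference subject, and the coding span it covers, in query-local
    (1-based nt) and subject (1-based codon) coordinates."""

    gene_id: str
    subject_id: str
    q_start: int
    q_end: int
    codon_start: int
    codon_end: int


@dataclass
class EmulatedAssembly:
    """An emulated assembly plus the provenance the emulated BLAST needs."""

    assembly: AssemblySet
    singletons: list[SequenceRecord]
    origins: dict[str, QueryOrigin]             # queries with coding overlap
    known_queries: set[str]                     # all isotig + singleton ids
    contig_gene: dict[str, str]
    contig_spans: dict[str, tuple[str, int, int]]  # contig -> (unit, lo, hi) unit-local


def _coding_blocks_for_span(
    unit: Unit, lo: int, hi: int
) -> tuple[int, int] | None:
    """Coding sub-range of a unit-local half-open span, or None."""
    if unit.kind != "exon" or unit.coding_bp == 0:
        return None
    c_lo, c_hi = max(lo, 0), min(hi, unit.coding_bp)
    return (c_lo, c_hi) if c_hi > c_lo else None


def _read_origin(truth: GroundTruth, read_id: str, origin: ReadOrigin) -> QueryOrigin | None:
    """Coding coverage of one raw read, as a QueryOrigin (None if UTR-only)."""
    iso = truth.isoforms[origin.isoform_id]
    gene = truth.genes[iso.gene_id]
    offsets = truth.unit_offsets(origin.isoform_id)
    r_lo, r_hi = origin.start, origin.start + origin.length
    qs = qe = cs = ce = None
    for unit in truth.transcript_units(origin.isoform_id):
        us, ue = offsets[unit.id]
        ov_lo, ov_hi = max(r_lo, us), min(r_hi, ue)
        if ov_hi <= ov_lo:
            continue
        block = _coding_blocks_for_span(unit, ov_lo - us, ov_hi - us)
        if block is None:
            continue
        c_lo, c_hi = block
        g_lo, g_hi = unit.coding_offset + c_lo, unit.coding_offset + c_hi
        q_lo, q_hi = (us + c_lo) - r_lo, (us + c_hi) - r_lo
        cs = g_lo if cs is None else min(cs, g_lo)
        ce = g_hi if ce is None else max(ce, g_hi)
        qs = q_lo if qs is None else min(qs, q_lo)
        qe = q_hi if qe is None else max(qe, q_hi)
    if cs is None:
        return None
    return QueryOrigin(
        gene_id=gene.id,
        subject_id=gene.subject_id,
        q_start=qs + 1,
        q_end=qe,
        codon_start=cs // 3 + 1,
        codon_end=(ce - 1) // 3 + 1,
    )


def emulate_assembly(
    reads: ReadSet | Sequence[ReadSet],
    truth: GroundTruth,
    k_min: int | None = None,
) -> EmulatedAssembly:
    """Assemble reads by provenance into the contig/isotig/isogroup hierarchy.

    Per gene: each transcribed unit covered by >= `k_min` reads becomes a
    contig truncated to its covered span; every expressed isoform's surviving
    contig path becomes an isotig (identical paths are merged); the gene is
    one isogroup.  Genes with fewer than `k_min` reads in total — and reads
    all of whose units failed the threshold — remain singletons.
    """
    readsets = [reads] if isinstance(reads, ReadSet) else list(reads)
    k_min = truth.config.k_min if k_min is None else k_min

    by_gene: dict[str, list[tuple[SequenceRecord, ReadOrigin]]] = {}
    for rs in readsets:
        for rec in rs.records:
            origin = rs.provenance[rec.id]
            by_gene.setdefault(truth.gene_of_read(origin), []).append((rec, origin))

    isotig_to_isogroup: dict[str, str] = {}
    isotig_contigs: dict[str, tuple[str, ...]] = {}
    isotig_seqs: dict[str, SequenceRecord] = {}
    contig_info: dict[str, ContigInfo] = {}
    contig_gene: dict[str, str] = {}
    contig_spans: dict[str, tuple[str, int, int]] = {}
    singletons: list[SequenceRecord] = []
    origins: dict[str, QueryOrigin] = {}
    known: set[str] = set()

    for gid in sorted(by_gene):
        gene = truth.genes[gid]
        greads = by_gene[gid]
        if len(greads) < k_min:
            for rec, origin in greads:
                singletons.append(rec)
                known.add(rec.id)
                q_origin = _read_origin(truth, rec.id, origin)
                if q_origin is not None:
                    origins[rec.id] = q_origin
            continue

        # unit-local read overlaps
        unit_hits: dict[str, list[tuple[int, int]]] = {}
        read_units: dict[str, list[str]] = {}
        for rec, origin in greads:
            offsets = truth.unit_offsets(origin.isoform_id)
            r_lo, r_hi = origin.start, origin.start + origin.length
            for unit in truth.transcript_units(origin.isoform_id):
                us, ue = offsets[unit.id]
                ov_lo, ov_hi = max(r_lo, us), min(r_hi, ue)
                if ov_hi > ov_lo:
                    unit_hits.setdefault(unit.id, []).append((ov_lo - us, ov_hi - us))
                    read_units.setdefault(rec.id, []).append(unit.id)

        surviving: dict[str, str] = {}  # unit id -> contig id
        for unit in gene.units:
            hits = unit_hits.get(unit.id, [])
            if len(hits) >= k_min:
                lo = min(h[0] for h in hits)
                hi = max(h[1] for h in hits)
                cid = f"{unit.id}.c"
                contig_info[cid] = ContigInfo(
                    length=hi - lo,
                    n_reads=len(hits),
                    read_bp=sum(h1 - h0 for h0, h1 in hits),
                )
                contig_gene[cid] = gid
                contig_spans[cid] = (unit.id, lo, hi)
                surviving[unit.id] = cid

        # expressed isoforms -> isotigs (deduplicated by contig path)
        expressed = sorted({o.isoform_id for _, o in greads})
        paths: dict[tuple[str, ...], str] = {}
        for iso_id in expressed:
            path = tuple(
                surviving[u.id] for u in truth.transcript_units(iso_id) if u.id in surviving
            )
            if not path or path in paths:
                continue
            tid = f"{gid}.t{len(paths)}"
            paths[path] = tid
            seq = "".join(
                truth.unit(contig_spans[c][0]).seq[contig_spans[c][1] : contig_spans[c][2]]
                for c in path
            )
            isotig_to_isogroup[tid] = gid
            isotig_contigs[tid] = path
            isotig_seqs[tid] = SequenceRecord(tid, seq, role="isotig")
            known.add(tid)
            origin = _isotig_origin(truth, gene, path, contig_spans)
            if origin is not None:
                origins[tid] = origin

        # reads whose units all failed the threshold stay singletons
        for rec, origin in greads:
            if not any(u in surviving for u in read_units.get(rec.id, [])):
                singletons.append(rec)
                known.add(rec.id)
                q_origin = _read_origin(truth, rec.id, origin)
                if q_origin is not None:
                    origins[rec.id] = q_origin

    membership = MembershipTable(isotig_to_isogroup, isotig_contigs)
    singleton_seqs = {rec.id: rec for rec in singletons}
    assembly = AssemblySet(
        membership=membership,
        isotig_seqs=isotig_seqs,
        contig_info=contig_info,
        singleton_seqs=singleton_seqs,
    )
    return EmulatedAssembly(
        assembly=assembly,
        singletons=singletons,
        origins=origins,
        known_queries=known,
        contig_gene=contig_gene,
        contig_spans=contig_spans,
    )


def _isotig_origin(
    truth: GroundTruth,
    gene: Gene,
    path: tuple[str, ...],
    contig_spans: dict[str, tuple[str, int, int]],
) -> QueryOrigin | None:
    """Coding coverage of an isotig built from a contig path."""
    pos = 0
    qs = qe = cs = ce = None
    for cid in path:
        unit_id, lo, hi = contig_spans[cid]
        unit = truth.unit(unit_id)
        block = _coding_blocks_for_span(unit, lo, hi)
        if block is not None:
            c_lo, c_hi = block
            g_lo, g_hi = unit.coding_offset + c_lo, unit.coding_offset + c_hi
            q_lo, q_hi = pos + (c_lo - lo), pos + (c_hi - lo)
            cs = g_lo if cs is None else min(cs, g_lo)
            ce = g_hi if ce is None else max(ce, g_hi)
            qs = q_lo if qs is None else min(qs, q_lo)
            qe = q_hi if qe is None else max(qe, q_hi)
        pos += hi - lo
    if cs is None:
        return None
    return QueryOrigin(
        gene_id=gene.id,
        subject_id=gene.subject_id,
        q_start=qs + 1,
        q_end=qe,
        codon_start=cs // 3 + 1,
        codon_end=(ce - 1) // 3 + 1,
    )


def emulate_blast(
    emulated: EmulatedAssembly,
    truth: GroundTruth,
    queries: Iterable[str] | None = None,
    evalue_floor: float = 1e-180,
) -> list[BlastHit]:
    """Emulated BLASTX-style hits of assembled sequences against the
    reference proteome, with exact coordinates of the covered coding span.

    E-values decrease monotonically with aligned length (10^(-codons/2),
    floored); bitscores increase with it.  Queries covering no coding
    sequence obtain no hit; unknown query ids are an error.
    """
    if queries is None:
        query_ids = sorted(emulated.known_queries)
    else:
        query_ids = list(queries)
    hits: list[BlastHit] = []
    for qid in query_ids:
        if qid not in emulated.known_queries:
            raise KeyError(f"query {qid!r} has no provenance in this emulated assembly")
        origin = emulated.origins.get(qid)
        if origin is None:
            continue
        codons = origin.codon_end - origin.codon_start + 1
        is_copy = truth.genes[origin.gene_id].paralog_of is not None
        hits.append(
            BlastHit(
                query_id=qid,
                subject_id=origin.subject_id,
                pct_identity=90.0 if is_copy else 98.0,
                aln_len=codons,
                mismatches=0,
                gap_opens=0,
                q_start=origin.q_start,
                q_end=origin.q_end,
                s_start=origin.codon_start,
                s_end=origin.codon_end,
                evalue=max(10.0 ** (-codons / 2.0), evalue_floor),
                bitscore=2.0 * codons,
                subject_len=truth.protein_len(origin.subject_id),
            )
        )
    return hits


def emulate_read_mapping(
    reads: ReadSet | Sequence[ReadSet],
    emulated: EmulatedAssembly,
    truth: GroundTruth,
) -> list[BlastHit]:
    """Emulated BLASTN-style hits of raw reads against the assembly's contigs
    (each read hits the contig of its own gene it overlaps most)."""
    readsets = [reads] if isinstance(reads, ReadSet) else list(reads)
    gene_contigs: dict[str, list[str]] = {}
    for cid, gid in emulated.contig_gene.items():
        gene_contigs.setdefault(gid, []).append(cid)

    hits: list[BlastHit] = []
    for rs in readsets:
        for rec in rs.records:
            origin = rs.provenance[rec.id]
            gid = truth.gene_of_read(origin)
            offsets = truth.unit_offsets(origin.isoform_id)
            r_lo, r_hi = origin.start, origin.start + origin.length
            best: tuple[int, str, int, int] | None = None  # (overlap, cid, q_lo, s_lo)
            for cid in sorted(gene_contigs.get(gid, [])):
                unit_id, lo, hi = emulated.contig_spans[cid]
                if unit_id not in offsets:
                    continue
                us, _ = offsets[unit_id]
                span_lo, span_hi = us + lo, us + hi
                ov_lo, ov_hi = max(r_lo, span_lo), min(r_hi, span_hi)
                overlap = ov_hi - ov_lo
                if overlap > 0 and (best is None or overlap > best[0]):
                    best = (overlap, cid, ov_lo - r_lo, ov_lo - span_lo)
            if best is None:
                continue
            overlap, cid, q_lo, s_lo = best
            hits.append(
                BlastHit(
                    query_id=rec.id,
                    subject_id=cid,
                    pct_identity=100.0,
                    aln_len=overlap,
                    mismatches=0,
                    gap_opens=0,
                    q_start=q_lo + 1,
                    q_end=q_lo + overlap,
                    s_start=s_lo + 1,
                    s_end=s_lo + overlap,
                    evalue=max(10.0 ** (-overlap / 4.0), 1e-180),
                    bitscore=float(2 * overlap),
                    subject_len=emulated.contig_spans[cid][2] - emulated.contig_spans[cid][1],
                )
            )
    return hits


class EmulatorPipeline:
    """Adapter pairing for saturation analyses: a provenance-aware assembler
    plus a BLAST source over the most recent assembly."""

    def __init__(
        self, readsets: Sequence[ReadSet], truth: GroundTruth, k_min: int | None = None
    ) -> None:
        self.truth = truth
        self.k_min = k_min
        self.provenance: dict[str, ReadOrigin] = {}
        for rs in readsets:
            self.provenance.update(rs.provenance)
        self._last: EmulatedAssembly | None = None

    def assemble(self, records: Sequence[SequenceRecord]) -> tuple[AssemblySet, list[SequenceRecord]]:
        subset = ReadSet(
            "subset", list(records), {r.id: self.provenance[r.id] for r in records}
        )
        self._last = emulate_assembly(subset, self.truth, self.k_min)
        return self._last.assembly, self._last.singletons

    def blast(self, records: Sequence[SequenceRecord]) -> list[BlastHit]:
        if self._last is None:
            raise RuntimeError("blast() called before assemble()")
        return emulate_blast(self._last, self.truth, queries=[r.id for r in records])


def simulate_go_annotation(
    truth: GroundTruth, seed: int = 0, n_leaf_terms: int = 8
) -> GoAnnotation:
    """A small synthetic GO DAG (root, two branches, leaves) with each gene
    annotated by 1-3 leaf terms; queries are gene ids."""
    root, proc, func = "GO:0000001", "GO:0000002", "GO:0000003"
    leaves = [f"GO:00001{i:02d}" for i in range(n_leaf_terms)]
    parents = {proc: frozenset({root}), func: frozenset({root})}
    for i, leaf in enumerate(leaves):
        parents[leaf] = frozenset({proc if i % 2 == 0 else func})
    rng = np.random.default_rng(seed)
    query_terms: dict[str, frozenset[str]] = {}
    for gid in sorted(truth.genes):
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        query_terms[gid] = frozenset(leaves[i] for i in picks)
    ancestors = _closure(parents)
    for leaf in leaves:
        ancestors.setdefault(leaf, frozenset())
    return GoAnnotation(query_terms=query_terms, ancestors=ancestors)


def export_simulation(
    truth: GroundTruth, readsets: Sequence[ReadSet], outdir: str | Path
) -> None:
    """Write the simulation to plain-text files: reference proteome,
    transcripts, per-sample reads, and a truth.json summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.reference_proteins, outdir / "reference.faa")
    transcripts = [
        SequenceRecord(iso_id, truth.transcript_seq(iso_id), role="reference_mrna")
        for iso_id in sorted(truth.isoforms)
    ]
    write_fasta(transcripts, outdir / "transcripts.fa")
    for rs in readsets:
        write_fasta(rs.records, outdir / f"reads_{rs.sample}.fa")
    summary = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in vars(truth.config).items()},
        "paralog_pairs": truth.paralog_pairs,
        "genes": {
            gid: {
                "protein_len": len(g.protein),
                "subject": g.subject_id,
                "units": [[u.id, u.kind, len(u)] for u in g.units],
            }
            for gid, g in truth.genes.items()
        },
        "isoforms": {
            iso_id: {
                "gene": iso.gene_id,
                "units": list(iso.unit_ids),
                "abundance": iso.abundance,
                "length": len(truth.transcript_seq(iso_id)),
            }
            for iso_id, iso in truth.isoforms.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(summary, indent=1))
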