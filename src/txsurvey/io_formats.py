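"""Readers and writers for the external formats the survey pipeline touches.

Covers FASTA sequence files, 12/13-column tabular BLAST output, the sidecar
TSV serializing the assembler's contig/isotig/isogroup hierarchy, and the two
GO mapping tables (query -> terms, term -> ancestors).  All readers accept a
path (plain or ``.gz``) or an open text stream, validate strictly, and raise
:class:`FormatError` with a line number on malformed input.

Coordinates follow the BLAST tabular convention: 1-based, inclusive.  Rows in
minus orientation are normalized at parse time so start <= end always holds,
with the original orientation kept on the strand flags; the writer restores
the original column order, so read/write round-trips are bit-exact.
"""

from __future__ import annotations

import gzip
import logging
import re
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SequenceRecord",
    "BlastHit",
    "MembershipTable",
    "GoAnnotation",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_membership",
    "write_membership",
    "membership_from_newbler_headers",
    "read_go_mapping",
]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# Sequence roles and their alphabets.  Nucleotide roles allow the IUPAC
# ambiguity codes; the protein role allows the 20 amino acids plus X.
NT_ROLES = frozenset({"isotig", "cap3_contig", "cap3_singlet", "read", "reference_mrna"})
PROTEIN_ROLES = frozenset({"reference_protein"})
ROLES = NT_ROLES | PROTEIN_ROLES

_NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceRecord:
    """One sequence with its header metadata.

    `id` is the first whitespace-delimited token of the FASTA header and must
    be unique within a file; `description` is the rest of the header line.
    """

    id: str
    residues: str
    description: str = ""
    role: str = "read"

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise FormatError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has empty residues")
        if self.role not in ROLES:
            raise FormatError(f"record {self.id!r} has unknown role {self.role!r}")
        alphabet = _AA_ALPHABET if self.role in PROTEIN_ROLES else _NT_ALPHABET
        bad = set(self.residues.upper()) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r} (role {self.role}) contains characters "
                f"outside its alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@contextmanager
def _open_text(source: str | Path | IO[str], mode: str = "rt") -> Iterator[IO[str]]:
    """Yield a text stream from a path (plain or gzip) or pass a stream through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, mode) as handle:  # type: ignore[operator]
            yield handle
    else:
        yield source


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: str | Path | IO[str], role: str = "read") -> list[SequenceRecord]:
    """Parse FASTA records in file order.

    Multi-line bodies are concatenated; the description is the header text
    after the first whitespace.  A body line before any header and duplicate
    ids are errors (with line numbers); an empty stream yields an empty list
    with a logged warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        assert header is not None
        parts = header.split(None, 1)
        rec_id = parts[0]
        if rec_id in seen:
            raise FormatError(f"line {header_line}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues="".join(chunks),
                description=parts[1] if len(parts) > 1 else "",
                role=role,
            )
        )

    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence body before any '>' header")
                chunks.append(line.strip())
        if header is not None:
            flush()
    if not records:
        log.warning("FASTA input contained no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: str | Path | IO[str], width: int = 70) -> None:
    """Write records as FASTA, wrapping bodies at `width` columns."""
    with _open_text(dest, "wt") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular


@dataclass
class BlastHit:
    """One row of 12(13)-column tabular BLAST output, coordinate-normalized.

    Spans satisfy ``q_start <= q_end`` and ``s_start <= s_end``; the strand
    flags record the orientation of the original row.  ``subject_len`` is the
    optional 13th column (``slen``), needed for ortholog hit ratios.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_len: int | None = None
    q_strand: str = "plus"
    s_strand: str = "plus"
    # original text fields, kept so writing reproduces the input bit-exactly
    raw: tuple[str, ...] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: spans must be normalized (start <= end)"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.aln_len < 1:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: alignment length < 1")
        if self.q_strand not in ("plus", "minus") or self.s_strand not in ("plus", "minus"):
            raise FormatError("strand flags must be 'plus' or 'minus'")

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


def _parse_number(text: str, kind: type, lineno: int, column: str):
    try:
        return kind(text)
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric value {text!r} in column {column}") from None


def read_blast_tab(source: str | Path | IO[str], expect_subject_len: bool = False) -> list[BlastHit]:
    """Parse tabular BLAST rows, preserving row order.

    With `expect_subject_len` the rows must carry a 13th ``slen`` column.
    Coordinates are normalized so start <= end, with the original orientation
    recorded on the strand flags.
    """
    expected = 13 if expect_subject_len else 12
    hits: list[BlastHit] = []
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise FormatError(
                    f"line {lineno}: expected {expected} columns, found {len(fields)}"
                )
            qs = _parse_number(fields[6], int, lineno, "q_start")
            qe = _parse_number(fields[7], int, lineno, "q_end")
            ss = _parse_number(fields[8], int, lineno, "s_start")
            se = _parse_number(fields[9], int, lineno, "s_end")
            q_strand = "plus" if qs <= qe else "minus"
            s_strand = "plus" if ss <= se else "minus"
            hit = BlastHit(
                query_id=fields[0],
                subject_id=fields[1],
                pct_identity=_parse_number(fields[2], float, lineno, "pct_identity"),
                aln_len=_parse_number(fields[3], int, lineno, "aln_len"),
                mismatches=_parse_number(fields[4], int, lineno, "mismatches"),
                gap_opens=_parse_number(fields[5], int, lineno, "gap_opens"),
                q_start=min(qs, qe),
                q_end=max(qs, qe),
                s_start=min(ss, se),
                s_end=max(ss, se),
                evalue=_parse_number(fields[10], float, lineno, "evalue"),
                bitscore=_parse_number(fields[11], float, lineno, "bitscore"),
                subject_len=_parse_number(fields[12], int, lineno, "subject_len")
                if expect_subject_len
                else None,
                q_strand=q_strand,
                s_strand=s_strand,
                raw=tuple(fields),
            )
            hits.append(hit)
    return hits


def _format_float(x: float) -> str:
    return f"{x:g}"


def write_blast_tab(hits: Iterable[BlastHit], dest: str | Path | IO[str]) -> None:
    """Write hits as tabular BLAST rows.

    Hits parsed by :func:`read_blast_tab` are written back from their original
    text fields, so round-trips are bit-exact; synthesized hits are formatted
    from their values, de-normalizing coordinates per the strand flags.
    """
    with _open_text(dest, "wt") as handle:
        for hit in hits:
            if hit.raw is not None:
                handle.write("\t".join(hit.raw) + "\n")
                continue
            qs, qe = (hit.q_start, hit.q_end) if hit.q_strand == "plus" else (hit.q_end, hit.q_start)
            ss, se = (hit.s_start, hit.s_end) if hit.s_strand == "plus" else (hit.s_end, hit.s_start)
            fields = [
                hit.query_id,
                hit.subject_id,
                f"{hit.pct_identity:.2f}",
                str(hit.aln_len),
                str(hit.mismatches),
                str(hit.gap_opens),
                str(qs),
                str(qe),
                str(ss),
                str(se),
                _format_float(hit.evalue),
                _format_float(hit.bitscore),
            ]
            if hit.subject_len is not None:
                fields.append(str(hit.subject_len))
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Assembly membership (isotig -> isogroup -> contigs)


@dataclass
class MembershipTable:
    """The assembler's transcript hierarchy as a sidecar table.

    Each isotig (transcript) appears exactly once, belongs to one isogroup
    (gene), and lists the ordered contigs (exons) it traverses.
    """

    isotig_to_isogroup: dict[str, str]
    isotig_contigs: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.isotig_to_isogroup) != set(self.isotig_contigs):
            raise FormatError("membership: isotig keys of the two maps differ")
        for isotig, contigs in self.isotig_contigs.items():
            if not contigs:
                raise FormatError(f"membership: isotig {isotig!r} has an empty contig list")

    @property
    def isogroups(self) -> dict[str, list[str]]:
        """isogroup id -> isotig ids, in table order."""
        groups: dict[str, list[str]] = {}
        for isotig, group in self.isotig_to_isogroup.items():
            groups.setdefault(group, []).append(isotig)
        return groups

    @property
    def contig_ids(self) -> set[str]:
        return {c for contigs in self.isotig_contigs.values() for c in contigs}

    def __len__(self) -> int:
        return len(self.isotig_to_isogroup)


def read_membership(source: str | Path | IO[str]) -> MembershipTable:
    """Parse TSV rows ``isotig_id<TAB>isogroup_id<TAB>contig1,contig2,...``."""
    isotig_to_isogroup: dict[str, str] = {}
    isotig_contigs: dict[str, tuple[str, ...]] = {}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: expected 3 columns, found {len(fields)}")
            isotig, isogroup, contig_field = fields
            if isotig in isotig_to_isogroup:
                raise FormatError(f"line {lineno}: duplicate isotig id {isotig!r}")
            contigs = tuple(c for c in contig_field.split(",") if c)
            if not contigs:
                raise FormatError(f"line {lineno}: isotig {isotig!r} has an empty contig list")
            isotig_to_isogroup[isotig] = isogroup
            isotig_contigs[isotig] = contigs
    return MembershipTable(isotig_to_isogroup, isotig_contigs)


def write_membership(table: MembershipTable, dest: str | Path | IO[str]) -> None:
    with _open_text(dest, "wt") as handle:
        for isotig, group in table.isotig_to_isogroup.items():
            handle.write(f"{isotig}\t{group}\t{','.join(table.isotig_contigs[isotig])}\n")


_NEWBLER_GROUP_RE = re.compile(r"\bisogroup(\d+)\b")


def membership_from_newbler_headers(records: Sequence[SequenceRecord]) -> MembershipTable:
    """Convenience converter from ``isotigNNNNN ... isogroupNNNNN`` headers.

    Header dialects do not carry contig composition, so each isotig is given a
    single pseudo-contig named after itself; use a real membership TSV when
    contig-level structure matters.
    """
    isotig_to_isogroup: dict[str, str] = {}
    isotig_contigs: dict[str, tuple[str, ...]] = {}
    for rec in records:
        match = _NEWBLER_GROUP_RE.search(rec.description)
        if match is None:
            raise FormatError(f"record {rec.id!r}: no isogroupNNNNN token in header")
        isotig_to_isogroup[rec.id] = f"isogroup{match.group(1)}"
        isotig_contigs[rec.id] = (f"{rec.id}.contig",)
    return MembershipTable(isotig_to_isogroup, isotig_contigs)


# ---------------------------------------------------------------------------
# GO annotation


@dataclass
class GoAnnotation:
    """Query -> GO terms plus the term ancestor closure.

    ``ancestors`` maps every known term to the transitive closure of its
    parents (self excluded); terms absent from the ancestor table are roots.
    Annotation of a term implies annotation of all its ancestors, each counted
    once per query.
    """

    query_terms: dict[str, frozenset[str]]
    ancestors: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def terms_for(self, query: str) -> frozenset[str]:
        """Ancestor-closed term set for one query (empty if unannotated)."""
        direct = self.query_terms.get(query, frozenset())
        closed: set[str] = set()
        for term in direct:
            closed.add(term)
            closed.update(self.ancestors.get(term, frozenset()))
        return frozenset(closed)

    def known_terms(self) -> frozenset[str]:
        out: set[str] = set(self.ancestors)
        for terms in self.query_terms.values():
            out.update(terms)
        return frozenset(out)


def _closure(parents: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Transitive ancestor closure; raises FormatError listing one cycle."""
    state: dict[str, int] = {}  # 0 in-progress, 1 done
    closed: dict[str, frozenset[str]] = {}

    def visit(term: str, stack: list[str]) -> frozenset[str]:
        if state.get(term) == 1:
            return closed[term]
        if state.get(term) == 0:
            cycle = stack[stack.index(term) :] + [term]
            raise FormatError(f"cycle in GO ancestor table: {' -> '.join(cycle)}")
        state[term] = 0
        stack.append(term)
        acc: set[str] = set()
        for parent in parents.get(term, frozenset()):
            acc.add(parent)
            acc.update(visit(parent, stack))
        stack.pop()
        state[term] = 1
        closed[term] = frozenset(acc)
        return closed[term]

    for term in parents:
        visit(term, [])
    return closed


def _parse_term_list(text: str) -> frozenset[str]:
    return frozenset(t for t in (piece.strip() for piece in text.split(";")) if t)


def read_go_mapping(
    query_source: str | Path | IO[str], ancestor_source: str | Path | IO[str]
) -> GoAnnotation:
    """Parse query->terms and term->parents TSVs and close over ancestors.

    The ancestor relation must be acyclic; a cycle aborts the load with one
    witness cycle in the message.  A term with no ancestor row is a root.
    """
    parents: dict[str, frozenset[str]] = {}
    with _open_text(ancestor_source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, found {len(fields)}")
            parents[fields[0]] = _parse_term_list(fields[1])

    query_terms: dict[str, frozenset[str]] = {}
    with _open_text(query_source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, found {len(fields)}")
            query_terms[fields[0]] = _parse_term_list(fields[1])

    ancestors = _closure(parents)
    # terms annotated but absent from the ancestor table are roots
    for terms in query_terms.values():
        for term in terms:
            ancestors.setdefault(term, frozenset())
    return GoAnnotation(query_terms=query_terms, ancestors=ancestors)
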