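# Methods

This note documents the models, conventions and design choices behind
`txsurvey`, in the order a survey analysis uses them.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The assembly hierarchy and its accounting

The package consumes an assembler's contig → isotig → isogroup hierarchy
through a sidecar TSV (`isotig_id, isogroup_id, contig list`) rather than by
parsing FASTA headers, because header dialects vary across assembler
versions; a best-effort converter from `isotigNNNNN ... isogroupNNNNN`
headers exists for convenience but cannot recover contig composition.

N50 follows the cumulative-sum convention: sort lengths descending,
accumulate, and report the length at which the running sum first reaches at
least half the total — over whichever isotig set the caller selects (all
isotigs, or the longest per isogroup; survey reports are ambiguous on this
point, so both modes exist).  Summary ratios and percentages are kept at
full precision and rounded only at the reporting boundary, half-up at one
decimal, matching how published survey tables print them.  No minimum
contig length is enforced; note that some assembler versions drop contigs
under 100 bp from their own reports, which matters when comparing counts.

## Unique gene models from top BLAST hits

Hits are filtered at *e* ≤ 10⁻¹⁰, then each query keeps one best hit:
minimal e-value, ties by maximal bitscore, remaining ties by input order
(BLAST's own output order makes this reproducible).  Queries sharing a
subject are then collapsed:

* all subject spans pairwise disjoint → fragments of one transcript, one
  gene;
* all spans pairwise overlapping → potential paralogs, one gene each;
* mixed systems → the minimum number of mutually non-overlapping chains
  that cover all spans.  For intervals this equals the maximum point-depth
  of overlap (interval graphs are perfect: max clique = chromatic number),
  so the count is exact and cheap via a sweep line.  The binary
  fragment/paralog description in the survey literature is the depth-1 and
  depth-n special case of this rule.

"Overlap" means sharing ≥ 1 subject position on closed 1-based intervals; a
configurable tolerance (default 0) lets callers ignore micro-overlaps.
Subject intervals come from the single best HSP row per query; multi-HSP
merging is out of scope.  Singletons are tallied with the stricter
one-gene-per-subject rule regardless of coordinates, because unassembled
identical reads otherwise inflate the count.  When assembled sequences and
singletons are combined (saturation curves), a subject already hit by an
assembled sequence gains nothing from its singletons — they are treated as
fragments of the gene already counted.  This interaction between the two
rules is not specified in the survey literature; it is this package's
choice, made so that the combined count is monotone under read addition.

## Ortholog hit ratio

OHR = (aligned query span) / (full subject length).  For translated
searches (nucleotide queries against protein subjects) the query span is
divided by 3 first, so that OHR = 1 means "assembled to full length"; a
nucleotide mode divides directly.  The ratio is not capped — values above 1
are flagged as possible insertions.  The aligned span is the best HSP's
query interval; poorly conserved regions that fail to align deflate the
ratio, so it is an underestimate for weakly conserved transcripts.  This is
surfaced as a caveat, not corrected for.  Threshold fractions (> 0.5,
> 0.8) use strict inequality.

Extension gain projects each transcript's unaligned overhang through its
alignment: 5′ gain = (transcript bases upstream of the alignment) −
(reference bases upstream), clamped at 0, maximized over transcripts;
likewise 3′.  Aligned reference spans are merged only when they overlap or
abut, so a gap bridged by the reference alone remains visible as two
blocks.  Only plus-strand, equal-span alignments are accepted; callers
pre-orient.

## Saturation curves

Subsets are prefixes of one seeded Fisher–Yates shuffle (numpy PCG64), so
subsets at increasing sizes are nested and unique-gene counts are monotone
by construction; `independent=True` draws each subset independently, which
mimics separately assembled sub-samples at the cost of monotonicity.  The
assembler sits behind an adapter contract (`reads -> (AssemblySet,
singletons)`, deterministic for a fixed input order); no assembler
algorithm is re-implemented.  The plateau estimate is the smallest read
count whose forward finite-difference slope drops below a caller-given
genes-per-read threshold — a reporting aid, not a model fit.

## Library comparison and enrichment

Base equalization truncates the larger library at a read boundary to the
largest prefix not exceeding the smaller library's base total (the prefix
may undershoot by less than one read).  Per-contig read counts come from
read-vs-assembly mappings at *e* ≤ 10⁻⁴, each read counted once at its top
hit.  The headline statistic is the maximum reads-per-contig per library:
successful normalization reduces it specifically.

Enrichment compares the genes hit *exclusively* by each library (the shared
ones carry no signal about which library found them).  Each query
contributes each ancestor-closed GO term once; per term, a 2×2 table of
annotated/unannotated counts in the two sets is tested with a two-sided
Fisher's exact test.  The test is computed by exact integer enumeration of
row-margin binomial-product weights under the "point probability ≤
observed" convention, with ties decided exactly on the integers — float
implementations need a tie slack (commonly 1+10⁻⁷) that can disagree with
exact ties on large tables.  A doubled-one-tail convention is available
behind a flag, since the software used in older surveys is rarely
identified.  FDR control is Benjamini–Hochberg (delegated to statsmodels);
"FDR-corrected" in survey reports rarely names the procedure, so this is a
documented, swappable choice.  Published q-values cannot be reproduced
exactly without knowing the family size tested; only raw-p ≤ q is a safe
check.

## Isoform validation

Candidate pairs are isogroups with exactly two isotigs whose contig lists
differ by exactly one contig present only in the longer isotig; the
predicted band-size difference is that contig's length.  Primer matching is
exact (no mismatches, no degenerate bases) — no primer-binding
thermodynamics is modeled; experimental slack lives instead in the
band-size comparison, default ±10% relative, motivated by agarose-gel
resolution.  Multiple binding sites enumerate all non-overlapping
forward/reverse combinations (the conservative choice).  A case is positive
when every predicted band is observed (extra bands allowed); the
single-product false-positive rate is the fraction of multi-band
predictions that produced one band.

## The synthetic-data generator

`SimConfig` defaults define the simulated study: 60 genes, 3 paralog pairs,
isoform probability 0.2, 2–5 exons of 90–360 bp, 30–200 bp UTRs, log-normal
abundances (μ = 0, σ = 1.5 — bulk-transcriptome-like dispersion), read
lengths normal(310, 80) floored at 50 bp (Titanium-like; sub-50 bp reads
are what real pipelines discard), 4,000 reads per library, γ = 1, k_min = 2.
Tests and the acceptance script scale n_genes and read counts to the size
each check needs (10–60 genes, 1,200–12,000 reads) — large enough for
saturation where saturation is asserted, small enough to keep every run
cheap.

Proteins are drawn uniformly over the 20 amino acids and back-translated
through a fixed codon per residue, so every coding region translates
exactly to its protein and contains no stop codons.  A skipped-exon isoform
removes one internal exon.  A paralog copy reuses its anchor's exon
structure with ~10% of residues substituted (≥ 80% identity); the copy's
protein is excluded from the reference proteome, so both pair members share
the anchor protein as best subject and produce overlapping subject spans —
the property the paralog counting rule needs.

What the emulator does *not* model, and what passing tests therefore do not
show: sequencing error (454 homopolymer indels), chimeras, mis-assembly,
annotation transfer errors, or any real assembler's behavior in low-coverage
or repetitive regions.  Assembly is by read provenance: the emulator cannot
mis-join, so recovery tests validate the downstream statistics, not
assembler robustness.  Emulated e-values (10^(−codons/2), floored) are
rank-faithful stand-ins adequate because downstream logic only orders and
thresholds them.

## Numerical choices and degenerate inputs

Half-up decimal rounding at the reporting boundary (spreadsheet-style;
Python's banker's rounding would differ on exact .x5).  Interval sweeps use
closed-interval semantics with +1/−1 events at start and end+1.  Ties in
longest-isotig selection break to the lexicographically smallest id.  Empty
inputs: empty FASTA parses to an empty list with a warning; N50 of an empty
list, summaries of empty assemblies, OHR without a subject length, and
enrichment of two empty sets are errors.  Coverage of a contig with no
assigned reads reports 0.0 with a warning.  All randomness flows through
`numpy.random.default_rng` with caller-supplied seeds; nothing reads global
RNG state.
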