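#!/usr/bin/env python
"""Collapse emulated BLAST hits into unique gene models.

BLASTs the representative isotig of each isogroup and all singletons against
the simulated reference proteome, filters at e <= 1e-10, keeps each query's
top hit, and collapses queries sharing a subject: non-overlapping subject
spans merge into one gene (unassembled fragments), overlapping spans count
separately (paralogs).  Writes gene_tally.tsv and checks the count against
the simulator's truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from txsurvey import synthetic_data as sd
from txsurvey.assembly_stats import longest_isotig_per_isogroup
from txsurvey.blast_summarizer import (
    filter_by_evalue,
    mixed_unique_gene_count,
    select_top_hits,
    unique_gene_tally,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = sd.SimConfig(n_genes=60, n_paralog_pairs=3, isoform_probability=0.2,
                       n_reads=6000, k_min=2, seed=args.seed)
    truth = sd.simulate_transcriptome(cfg)
    reads_n = sd.simulate_reads(truth, "N", gamma=0.5, seed=args.seed + 1)
    reads_nn = sd.simulate_reads(truth, "NN", gamma=1.0, seed=args.seed + 2)
    emulated = sd.emulate_assembly([reads_n, reads_nn], truth)

    longest = longest_isotig_per_isogroup(emulated.assembly)
    top_assembled = select_top_hits(filter_by_evalue(
        sd.emulate_blast(emulated, truth, queries=sorted(longest.values())), 1e-10))
    top_singletons = select_top_hits(filter_by_evalue(
        sd.emulate_blast(emulated, truth, queries=[r.id for r in emulated.singletons]),
        1e-10))

    tally = unique_gene_tally(top_assembled)
    rows = [
        {
            "subject": subject,
            "n_queries": len(t.query_ids),
            "classification": t.classification.value,
            "gene_count": t.gene_count,
        }
        for subject, t in sorted(tally.per_subject.items())
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "gene_tally.tsv", sep="\t", index=False)

    unique = mixed_unique_gene_count(top_assembled, top_singletons)
    by_class = pd.DataFrame(rows)["classification"].value_counts().to_dict()
    print(f"queries with hits: {len(top_assembled)} isotigs + {len(top_singletons)} singletons")
    print(f"subjects by classification: {by_class}")
    print(f"unique genes (mixed counting rule): {unique} of {cfg.n_genes} simulated")
    print(f"fragments merged away: {tally.n_merged_away}")


if __name__ == "__main__":
    main()
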