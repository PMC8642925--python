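#!/usr/bin/env python
"""Call imprinted genes from the simulated reciprocal crosses.

Reads the tables written by 01_simulate.py, assigns reads to parental
alleles, sums them per gene and cross direction, tests each analyzable
gene against the 2m:1p endosperm null (chi-square, BH q < 0.05), and
classifies MEG/PEG/MNC/PNC at low and high stringency — independently for
the two cross pairs, then merged as the union call set. Scores the calls
against the planted truth.

Writes results/calls_pair{1,2}.tsv, results/calls_union.tsv and
results/imprinting_summary.tsv.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from imprintscan import (
    assign_sample,
    call_imprinting,
    merge_cross_pairs,
    read_base_counts,
    read_gff3_genes,
    read_snp_table,
    score_ase_recovery,
    summarize_genes,
)
from imprintscan.imprinting_stats import calls_to_frame, frame_to_calls  # noqa: F401

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    snps = read_snp_table(DATA / "snps.tsv")
    genes = read_gff3_genes(DATA / "genes.gff3")
    biotypes = {g.gene_id: g.biotype for g in genes}
    params = json.loads((DATA / "ase_params.json").read_text())
    truth = pd.read_csv(DATA / "truth_ase.tsv", sep="\t")

    per_pair = []
    for i, (fwd, rev) in enumerate(params["pairs"], start=1):
        summaries = {}
        for sample, direction in ((fwd, "forward"), (rev, "reciprocal")):
            counts = read_base_counts(DATA / f"counts_{sample}.tsv")
            assigned = assign_sample(counts, snps, params["orientations"][sample], sample)
            summaries[direction] = summarize_genes(assigned, genes, direction)
        calls = call_imprinting(summaries["forward"], summaries["reciprocal"], biotypes)
        per_pair.append(calls)
        calls_to_frame(calls).to_csv(OUT / f"calls_pair{i}.tsv", sep="\t", index=False)
        tally = Counter(c.status.value for c in calls.values())
        print(f"pair {i} ({fwd}/{rev}): " + ", ".join(f"{k}={v}" for k, v in sorted(tally.items())))

    merged = merge_cross_pairs(per_pair)
    pd.DataFrame(
        sorted((g, s.value) for g, s in merged.items()), columns=["gene_id", "status"]
    ).to_csv(OUT / "calls_union.tsv", sep="\t", index=False)

    scores = score_ase_recovery(merged, truth)
    pd.DataFrame([scores]).to_csv(OUT / "imprinting_summary.tsv", sep="\t", index=False)
    print(f"union: {scores['n_called']} imprinted transcripts; "
          f"recovered {scores['n_recovered']}/{scores['n_planted']} planted "
          f"({100 * scores['recovery']:.1f}%), observed FDR {100 * scores['fdr']:.1f}%")


if __name__ == "__main__":
    main()
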