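#!/usr/bin/env python
"""Scan the union imprinting calls for genomic clusters.

A cluster is >= 2 imprinted transcripts with consecutive members <= 1 Mb
apart and no analyzed non-imprinted gene between them; non-analyzed genes
(typically without informative SNPs) do not break chains. Also reports the
cluster-size composition and the mean spacing between imprinted
transcripts.

Writes results/clusters.bed and results/cluster_sizes.tsv.
"""

from pathlib import Path

import pandas as pd

from imprintscan import (
    cluster_size_distribution,
    find_clusters,
    read_gff3_genes,
    spacing_stats,
    write_bed,
)
from imprintscan.imprinting_stats import Status

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    genes = read_gff3_genes(DATA / "genes.gff3")
    union = pd.read_csv(OUT / "calls_union.tsv", sep="\t")
    statuses = {r.gene_id: Status(r.status) for r in union.itertuples(index=False)}

    clusters = find_clusters(statuses, genes)
    write_bed(clusters, OUT / "clusters.bed")
    summary = cluster_size_distribution(clusters)
    pd.DataFrame(
        {"size": list(summary.counts), "n_clusters": list(summary.counts.values()),
         "pct": [100 * summary.proportions[k] for k in summary.counts]}
    ).to_csv(OUT / "cluster_sizes.tsv", sep="\t", index=False)

    mean_dist, distances = spacing_stats(statuses, genes)
    comp = ", ".join(f"{100 * v:.1f}% size-{k}" for k, v in summary.proportions.items())
    print(f"{len(clusters)} clusters holding {summary.total_members} imprinted transcripts "
          f"({summary.n_meg} maternal, {summary.n_peg} paternal); composition: {comp}")
    print(f"mean spacing between consecutive imprinted transcripts: "
          f"{mean_dist / 1e3:.1f} kb over {distances.size} gaps")


if __name__ == "__main__":
    main()
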