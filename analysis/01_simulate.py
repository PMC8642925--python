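#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Emulates the study design: two reciprocal cross pairs of hybrid endosperm
samples (per-SNP base counts at a 2:1 maternal:paternal baseline, planted
MEGs at maternal fraction 0.95 and PEGs at 0.10, negative-binomial depth
with mean 100), gene models with a 2% noncoding fraction, and paired
embryo/endosperm bisulfite methylomes with CG-hypomethylated-in-endosperm
regions planted at the 5' ends of a quarter of the planted PEGs.

Writes all tables under results/data/ in the formats the readers consume.
"""

from pathlib import Path

from imprintscan import AseConfig, MethylomeConfig, generate_ase, generate_methylome
from imprintscan.synthetic_data import write_ase_dataset, write_methylome_dataset

SEED = 1
OUT = Path("results/data")


def main() -> None:
    ase = generate_ase(AseConfig(n_genes=1000, depth_mean=100.0), seed=SEED)
    files = write_ase_dataset(ase, OUT)
    pegs = ase.truth.loc[ase.truth["true_status"] == "PEG", "gene_id"].tolist()
    meth = generate_methylome(
        MethylomeConfig(), seed=SEED + 1, gene_models=ase.genes, peg_gene_ids=pegs
    )
    files.update(write_methylome_dataset(meth, OUT))

    n = ase.truth["true_status"].value_counts()
    print(f"genes: {len(ase.genes)} ({n.get('MEG', 0)} MEG, {n.get('PEG', 0)} PEG planted), "
          f"SNPs: {len(ase.snps)}, samples: {sorted(ase.base_counts)}")
    print(f"methylome: {len(meth.embryo):,} embryo / {len(meth.endosperm):,} endosperm "
          f"cytosines, {len(meth.regions)} planted endosperm-hypo regions")
    print(f"wrote {len(files)} files to {OUT}")


if __name__ == "__main__":
    main()
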