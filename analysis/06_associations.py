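#!/usr/bin/env python
"""Downstream syntheses: imprinting-DMR association, conservation and
tissue specificity.

Tests whether imprinted genes (gene body ± 2 kb) carry
endosperm-hypomethylated DMRs more often than other analyzed genes
(two-sided Fisher exact); computes cross-species imprinting-conservation
ratios from a synthetic homolog table; and splits MEGs/PEGs into
endosperm-specific vs constitutive subgroups from a synthetic FPKM matrix.

Writes results/association.tsv, results/conservation.tsv and
results/tissue_specificity.tsv.
"""

from pathlib import Path

import pandas as pd

from imprintscan import (
    association_test,
    conservation_ratios,
    gene_dmr_overlap,
    generate_fpkm_matrix,
    generate_homolog_table,
    read_gff3_genes,
    tissue_specificity,
)
from imprintscan.dmr_calling import MethWindow, frame_to_dmrs
from imprintscan.imprinting_stats import Status

DATA = Path("results/data")
OUT = Path("results")
SEED = 3


def main() -> None:
    genes = read_gff3_genes(DATA / "genes.gff3")
    union = pd.read_csv(OUT / "calls_union.tsv", sep="\t")
    statuses = {r.gene_id: Status(r.status) for r in union.itertuples(index=False)}
    dmrs = frame_to_dmrs(pd.read_csv(OUT / "dmrs.tsv", sep="\t"))
    tested = [
        MethWindow(r.chrom, int(r.start), int(r.end), "CG", 0, 1, 0, 1, 1.0)
        for r in pd.read_csv(OUT / "tested_windows.tsv", sep="\t").itertuples(index=False)
    ]

    flags = gene_dmr_overlap(genes, dmrs, flank=2000, assessed_regions=tested)
    table = association_test(flags, statuses)
    pd.DataFrame([{
        "imprinted_with_dmr": table.imprinted_with_dmr,
        "imprinted_without_dmr": table.imprinted_without_dmr,
        "other_with_dmr": table.other_with_dmr,
        "other_without_dmr": table.other_without_dmr,
        "odds_ratio": table.odds_ratio,
        "p_value": table.p_value,
    }]).to_csv(OUT / "association.tsv", sep="\t", index=False)
    total_imp = table.imprinted_with_dmr + table.imprinted_without_dmr
    print(f"imprinted genes with an endosperm-hypo DMR within ±2 kb: "
          f"{table.imprinted_with_dmr}/{total_imp} "
          f"vs {table.other_with_dmr}/{table.other_with_dmr + table.other_without_dmr} "
          f"other analyzed genes (OR {table.odds_ratio:.1f}, Fisher p {table.p_value:.2e})")

    homologs = generate_homolog_table(statuses, seed=SEED)
    cons = conservation_ratios(homologs, statuses)
    pd.DataFrame(
        [{"species": s.species, "foreign_status": s.foreign_status,
          "n_analyzable": s.n_analyzable, "n_concordant_low": s.n_concordant_low,
          "pct_low": s.pct_low, "n_concordant_high": s.n_concordant_high,
          "pct_high": s.pct_high} for s in cons]
    ).to_csv(OUT / "conservation.tsv", sep="\t", index=False)
    for s in cons:
        print(f"{s.species} {s.foreign_status}s: {s.n_concordant_low}/{s.n_analyzable} "
              f"({s.pct_low:.1f}%) direction-concordant in the synthetic calls")

    truth = pd.read_csv(DATA / "truth_ase.tsv", sep="\t")
    fpkm = generate_fpkm_matrix(truth, seed=SEED + 1)
    rows = []
    for label in (Status.MEG, Status.PEG):
        gids = [g for g, s in statuses.items() if s is label]
        spec = tissue_specificity(fpkm, gids)
        pct = 100 * (spec == "endo_specific").mean()
        rows.append({"status": label.value, "n": len(spec),
                     "n_endo_specific": int((spec == "endo_specific").sum()),
                     "pct_endo_specific": pct})
        print(f"{label.value}s endosperm-specific: "
              f"{int((spec == 'endo_specific').sum())}/{len(spec)} ({pct:.1f}%)")
    pd.DataFrame(rows).to_csv(OUT / "tissue_specificity.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
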