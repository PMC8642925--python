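"""Assign per-SNP read bases to the maternal/paternal allele and sum per gene.

A hybrid endosperm sample comes from a cross between parent line A and parent
line B; its *orientation* says which line is the mother. In the forward
sample line A is maternal, in the reciprocal sample line B is. Reads carrying
neither parental base ("other") are sequencing error: they are excluded from
the maternal/paternal sums but tracked, and a SNP whose other-fraction
exceeds ``other_frac_max`` in a sample is considered unreliable and excluded
from that sample's gene sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, SnpRecord, VALID_BASES

#: Minimum parentally assignable reads (M+P) per cross direction for a gene
#: to be allelically analyzable.
MIN_ASSIGNABLE_READS = 10

#: Per-SNP other-allele fraction above which the site is excluded from gene
#: sums (likely mismapping rather than simple base error).
DEFAULT_OTHER_FRAC_MAX = 0.20


@dataclass(frozen=True)
class AllelicSnpCount:
    """Reads at one SNP in one sample, split by parental origin."""

    chrom: str
    pos: int
    sample_id: str
    maternal_reads: int
    paternal_reads: int
    other_reads: int

    @property
    def assignable(self) -> int:
        return self.maternal_reads + self.paternal_reads


@dataclass(frozen=True)
class GeneAllelicSummary:
    """Maternal (M) and paternal (P) read totals for one gene in one cross
    direction, summed over the gene's informative SNPs."""

    gene_id: str
    cross_direction: str  # "forward" or "reciprocal"
    maternal_total: int
    paternal_total: int
    n_informative_snps: int

    @property
    def assignable(self) -> int:
        return self.maternal_total + self.paternal_total

    @property
    def maternal_fraction(self) -> float:
        n = self.assignable
        return np.nan if n == 0 else self.maternal_total / n


def assign_alleles(
    base_counts: Mapping[str, int], snp: SnpRecord, maternal_line: str, sample_id: str = ""
) -> AllelicSnpCount:
    """Split base counts at one SNP into maternal/paternal/other reads.

    ``base_counts`` maps base -> read count at the site; ``maternal_line``
    ("A" or "B") declares which parent line is the mother in this sample.
    """
    if snp.allele_a not in VALID_BASES or snp.allele_b not in VALID_BASES:
        raise ValueError(f"SNP at {snp.chrom}:{snp.pos} has non-ACGT alleles")
    if maternal_line not in ("A", "B"):
        raise ValueError(f"maternal_line must be 'A' or 'B', got {maternal_line!r}")
    maternal_base = snp.allele_a if maternal_line == "A" else snp.allele_b
    paternal_base = snp.allele_b if maternal_line == "A" else snp.allele_a
    m = int(base_counts.get(maternal_base, 0))
    p = int(base_counts.get(paternal_base, 0))
    total = sum(int(base_counts.get(b, 0)) for b in "ACGT")
    return AllelicSnpCount(snp.chrom, snp.pos, sample_id, m, p, total - m - p)


def assign_sample(
    base_counts: pd.DataFrame,
    snps: Sequence[SnpRecord],
    maternal_line: str,
    sample_id: str = "",
) -> pd.DataFrame:
    """Vectorised allele assignment for one sample.

    ``base_counts`` has columns chrom, pos, count_A..count_T (one row per
    SNP). Returns a DataFrame with columns chrom, pos, maternal, paternal,
    other for SNPs present in both inputs.
    """
    if maternal_line not in ("A", "B"):
        raise ValueError(f"maternal_line must be 'A' or 'B', got {maternal_line!r}")
    snp_df = pd.DataFrame(
        [(s.chrom, s.pos, s.allele_a, s.allele_b) for s in snps],
        columns=["chrom", "pos", "allele_a", "allele_b"],
    )
    merged = snp_df.merge(base_counts, on=["chrom", "pos"], how="inner")
    counts = merged[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    base_idx = {b: i for i, b in enumerate("ACGT")}
    ia = merged["allele_a"].map(base_idx).to_numpy()
    ib = merged["allele_b"].map(base_idx).to_numpy()
    rows = np.arange(len(merged))
    a_counts = counts[rows, ia]
    b_counts = counts[rows, ib]
    maternal, paternal = (a_counts, b_counts) if maternal_line == "A" else (b_counts, a_counts)
    out = merged[["chrom", "pos"]].copy()
    out["sample_id"] = sample_id
    out["maternal"] = maternal
    out["paternal"] = paternal
    out["other"] = counts.sum(axis=1) - maternal - paternal
    return out


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    return trees


def summarize_genes(
    assigned: pd.DataFrame,
    genes: Sequence[GeneModel],
    cross_direction: str,
    other_frac_max: float = DEFAULT_OTHER_FRAC_MAX,
) -> dict[str, GeneAllelicSummary]:
    """Sum assigned reads over each gene's SNPs for one cross direction.

    A SNP belongs to a gene iff its position lies within [start, end]; SNPs
    inside two overlapping genes contribute to both. SNPs whose other-read
    fraction exceeds ``other_frac_max`` are excluded as unreliable. Genes
    with no informative SNP get M = P = 0.
    """
    trees = _gene_trees(genes)
    m_sum: dict[str, int] = {g.gene_id: 0 for g in genes}
    p_sum: dict[str, int] = {g.gene_id: 0 for g in genes}
    n_snp: dict[str, int] = {g.gene_id: 0 for g in genes}
    for chrom, pos, m, p, o in assigned[["chrom", "pos", "maternal", "paternal", "other"]].itertuples(index=False):
        total = m + p + o
        if total > 0 and o / total > other_frac_max:
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            gid = iv.data
            m_sum[gid] += int(m)
            p_sum[gid] += int(p)
            n_snp[gid] += 1
    return {
        gid: GeneAllelicSummary(gid, cross_direction, m_sum[gid], p_sum[gid], n_snp[gid])
        for gid in m_sum
    }


def is_analyzable(
    summary_fwd: GeneAllelicSummary | None,
    summary_rev: GeneAllelicSummary | None,
    min_reads: int = MIN_ASSIGNABLE_READS,
) -> bool:
    """A gene is allelically analyzable iff it has at least ``min_reads``
    parentally assignable reads (M+P) in *each* direction of the reciprocal
    cross. A missing direction makes the gene non-analyzed."""
    if summary_fwd is None or summary_rev is None:
        return False
    return summary_fwd.assignable >= min_reads and summary_rev.assignable >= min_reads


def summaries_to_frame(summaries: Iterable[GeneAllelicSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.gene_id, s.cross_direction, s.maternal_total, s.paternal_total, s.n_informative_snps)
            for s in summaries
        ],
        columns=["gene_id", "direction", "M", "P", "n_snps"],
    )
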