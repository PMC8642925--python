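"""Downstream syntheses: imprinting-DMR association, conservation ratios,
tissue-specificity subgroups, and the seed-coat contamination report.

The association analysis asks whether imprinted genes (with their 2-kb
up/downstream flanks) overlap DMRs that are hypomethylated in endosperm and
hypermethylated in embryo more often than non-imprinted genes do, via a
two-sided Fisher exact test on the 2x2 gene-by-overlap table. Genes whose
flanked span does not touch any analyzed methylated region (tested windows)
are unassessable and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dmr_calling import ENDOSPERM_HYPO, Dmr, MethWindow
from .imprinting_stats import (
    IMPRINTED_STATUSES,
    MATERNAL_STATUSES,
    PATERNAL_STATUSES,
    Status,
)
from .io_formats import GeneModel

DEFAULT_FLANK = 2000


def _interval_trees(items: Sequence, get=lambda x: (x.chrom, x.start, x.end)) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for it in items:
        chrom, start, end = get(it)
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, it)
    return trees


def gene_dmr_overlap(
    gene_models: Sequence[GeneModel],
    dmrs: Sequence[Dmr],
    flank: int = DEFAULT_FLANK,
    assessed_regions: Sequence[MethWindow] | None = None,
) -> pd.DataFrame:
    """Flag each gene for DMR overlap within gene body ± ``flank``.

    Returns a DataFrame indexed by gene_id with boolean columns
    ``endosperm_hypo``, ``embryo_hypo`` and ``assessable``. When
    ``assessed_regions`` (e.g. the tested methylation windows) is given, a
    gene is assessable only if its flanked span intersects at least one of
    them; otherwise all genes are assessable. The flank is strict: a DMR
    ending exactly ``flank`` bp away overlaps, one bp further does not.
    """
    dmr_trees = _interval_trees(dmrs)
    assess_trees = _interval_trees(assessed_regions) if assessed_regions is not None else None
    rows = []
    for g in gene_models:
        lo, hi = g.start - flank, g.end + flank
        hits = dmr_trees.get(g.chrom, IntervalTree()).overlap(lo, hi + 1)
        directions = {iv.data.direction for iv in hits}
        if assess_trees is None:
            assessable = True
        else:
            assessable = bool(assess_trees.get(g.chrom, IntervalTree()).overlap(lo, hi + 1))
        rows.append(
            (g.gene_id, ENDOSPERM_HYPO in directions, "embryo_hypo" in directions, assessable)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "endosperm_hypo", "embryo_hypo", "assessable"]
    ).set_index("gene_id")


@dataclass(frozen=True)
class AssociationTable:
    """2x2 association of imprinting status with directional DMR overlap."""

    imprinted_with_dmr: int
    imprinted_without_dmr: int
    other_with_dmr: int
    other_without_dmr: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.imprinted_with_dmr, self.imprinted_without_dmr],
            [self.other_with_dmr, self.other_without_dmr],
        ]


def association_test(
    overlap_flags: pd.DataFrame,
    statuses: Mapping[str, Status],
    direction: str = ENDOSPERM_HYPO,
    imprinted_statuses: frozenset[Status] = IMPRINTED_STATUSES,
) -> AssociationTable:
    """Fisher exact test of imprinted vs non-imprinted genes against
    presence of a ``direction`` DMR within the flanked gene span.

    Only assessable, allelically analyzed genes enter the table; both the
    imprinted and the non-imprinted margin must be non-empty.
    """
    a = b = c = d = 0
    for gene_id, row in overlap_flags.iterrows():
        if not row["assessable"]:
            continue
        status = statuses.get(gene_id, Status.NON_ANALYZED)
        if status is Status.NON_ANALYZED:
            continue
        has = bool(row[direction])
        if status in imprinted_statuses:
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    if a + b == 0 or c + d == 0:
        raise ValueError("association_test: a margin of the 2x2 table is empty")
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return AssociationTable(a, b, c, d, float(odds_ratio), float(p))


@dataclass(frozen=True)
class ConservationSummary:
    """Concordance of a foreign species' imprinted genes with the local calls."""

    species: str
    foreign_status: str  # "MEG" or "PEG"
    n_homologs: int
    n_analyzable: int
    n_concordant_low: int
    n_concordant_high: int

    @property
    def pct_low(self) -> float:
        return 100.0 * self.n_concordant_low / self.n_analyzable if self.n_analyzable else float("nan")

    @property
    def pct_high(self) -> float:
        return 100.0 * self.n_concordant_high / self.n_analyzable if self.n_analyzable else float("nan")


def conservation_ratios(
    homolog_table: pd.DataFrame,
    statuses: Mapping[str, Status],
) -> list[ConservationSummary]:
    """Direction concordance of foreign imprinted genes with local calls.

    ``homolog_table`` columns: species, foreign_gene_id, foreign_status
    (MEG/PEG), local_gene_id. Denominators are homologs whose local gene is
    allelically analyzable; numerators count direction-concordant calls at
    low stringency (any maternal/paternal bias call) and, separately, at
    high stringency (MEG/PEG). Homolog ids absent from the calls count as
    non-analyzable. Percentages are per homolog row, so duplicating every
    row leaves them unchanged.
    """
    out = []
    for (species, f_status), grp in homolog_table.groupby(["species", "foreign_status"], sort=True):
        concordant_set = MATERNAL_STATUSES if f_status == "MEG" else PATERNAL_STATUSES
        high_status = Status.MEG if f_status == "MEG" else Status.PEG
        n_analyzable = n_low = n_high = 0
        for gid in grp["local_gene_id"]:
            status = statuses.get(gid, Status.NON_ANALYZED)
            if status is Status.NON_ANALYZED:
                continue
            n_analyzable += 1
            if status in concordant_set:
                n_low += 1
            if status is high_status:
                n_high += 1
        out.append(
            ConservationSummary(species, f_status, len(grp), n_analyzable, n_low, n_high)
        )
    return out


def tissue_specificity(
    fpkm: pd.DataFrame,
    gene_ids: Sequence[str],
    endosperm_column: str = "endosperm",
    endo_ratio: float = 4.0,
    min_fpkm: float = 1.0,
) -> pd.Series:
    """Label genes endosperm-specific vs constitutive.

    A gene is endosperm-specific iff its endosperm FPKM is at least
    ``min_fpkm`` and at least ``endo_ratio`` times the maximum FPKM over the
    other tissues. (This cutoff is a package default, not a published one.)
    Genes absent from the matrix are dropped; the returned labels partition
    the genes with expression data.
    """
    if endosperm_column not in fpkm.columns:
        raise ValueError(f"FPKM matrix lacks an {endosperm_column!r} column")
    others = [c for c in fpkm.columns if c != endosperm_column]
    if not others:
        raise ValueError("FPKM matrix needs at least one non-endosperm tissue")
    present = [g for g in gene_ids if g in fpkm.index]
    sub = fpkm.loc[present]
    endo = sub[endosperm_column]
    max_other = sub[others].max(axis=1)
    specific = (endo >= min_fpkm) & (endo >= endo_ratio * max_other)
    return pd.Series(
        np.where(specific, "endo_specific", "constitutive"), index=sub.index, name="specificity"
    )


def contamination_report(
    fpkm: pd.DataFrame,
    marker_gene_ids: Sequence[str],
    endosperm_column: str = "endosperm",
    max_fpkm: float = 0.5,
) -> pd.DataFrame:
    """Seed-coat contamination check: endosperm FPKM of maternal seed-coat
    marker genes, flagged clean when below ``max_fpkm``."""
    rows = []
    for gid in marker_gene_ids:
        value = float(fpkm.loc[gid, endosperm_column]) if gid in fpkm.index else float("nan")
        rows.append((gid, value, bool(value < max_fpkm) if value == value else False))
    return pd.DataFrame(rows, columns=["gene_id", "endosperm_fpkm", "clean"]).set_index("gene_id")
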