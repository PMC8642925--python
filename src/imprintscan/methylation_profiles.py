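"""Bulk methylation levels and gene-anchored metaprofiles.

Methylation is summarised as the *weighted* level: sum of methylated read
counts over sum of total read counts across qualifying cytosines, per
sequence context (CG, CHG, CHH). Bulk levels use sites with at least 5
reads. Metaprofiles average per-gene binned levels over a gene set: a 2-kb
upstream flank in fixed 100-bp bins, the gene body rescaled into 40 bins,
and a 2-kb downstream flank, with minus-strand genes flipped so bins always
run 5' to 3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel

DEFAULT_MIN_DEPTH = 5


def bulk_level(
    cytosines: pd.DataFrame, context: str, min_depth: int = DEFAULT_MIN_DEPTH
) -> float:
    """Weighted methylation level over all sites of one context with at
    least ``min_depth`` reads: sum(meth) / sum(meth + unmeth).

    Returns NaN (a missing value, not 0) when no site qualifies.
    """
    sub = cytosines[cytosines["context"] == context]
    depth = sub["meth"] + sub["unmeth"]
    sub = sub[depth >= min_depth]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        return float("nan")
    return float(sub["meth"].sum() / total)


@dataclass(frozen=True)
class MetaProfile:
    """Average methylation around a gene set: upstream flank bins, scaled
    gene-body bins, downstream flank bins, 5'→3'."""

    context: str
    label: str
    bins: np.ndarray  # length n_flank + n_body + n_flank; NaN = no coverage
    n_flank_bins: int
    n_body_bins: int
    n_genes: int

    @property
    def upstream(self) -> np.ndarray:
        return self.bins[: self.n_flank_bins]

    @property
    def body(self) -> np.ndarray:
        return self.bins[self.n_flank_bins : self.n_flank_bins + self.n_body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.bins[self.n_flank_bins + self.n_body_bins :]


def _bin_edges(gene: GeneModel, n_body_bins: int, flank: int, flank_bin: int) -> np.ndarray:
    """Left-to-right genomic bin edges (inclusive-start positions), as
    floats; bin i covers [edges[i], edges[i+1])."""
    n_flank = flank // flank_bin
    up = gene.start - flank + flank_bin * np.arange(n_flank + 1, dtype=float)
    body = gene.start + (gene.end - gene.start + 1) * np.arange(n_body_bins + 1) / n_body_bins
    down = gene.end + 1 + flank_bin * np.arange(n_flank + 1, dtype=float)
    return np.concatenate([up[:-1], body[:-1], down])


def _per_gene_counts(
    pos: np.ndarray, meth_cum: np.ndarray, tot_cum: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.searchsorted(pos, edges)
    meth = meth_cum[idx[1:]] - meth_cum[idx[:-1]]
    tot = tot_cum[idx[1:]] - tot_cum[idx[:-1]]
    return meth, tot


def metaprofile(
    cytosines: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    gene_ids: Sequence[str],
    context: str,
    label: str = "",
    n_body_bins: int = 40,
    flank: int = 2000,
    flank_bin: int = 100,
    pooled: bool = False,
) -> MetaProfile:
    """Average methylation profile of a gene set.

    Default mode computes each gene's per-bin weighted level and averages
    across genes, ignoring bins with no covered cytosine; ``pooled=True``
    instead pools read counts across genes before dividing.
    """
    wanted = set(gene_ids)
    genes = [g for g in gene_models if g.gene_id in wanted]
    if not genes:
        raise ValueError("metaprofile: empty gene set")
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + n_body_bins

    sub = cytosines[cytosines["context"] == context].sort_values(["chrom", "pos"])
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy(dtype=float)
        tot = meth + grp["unmeth"].to_numpy(dtype=float)
        by_chrom[chrom] = (
            pos,
            np.concatenate([[0.0], np.cumsum(meth)]),
            np.concatenate([[0.0], np.cumsum(tot)]),
        )

    levels = np.full((len(genes), n_bins), np.nan)
    meth_pool = np.zeros(n_bins)
    tot_pool = np.zeros(n_bins)
    for i, g in enumerate(genes):
        if g.chrom not in by_chrom:
            continue
        pos, meth_cum, tot_cum = by_chrom[g.chrom]
        meth, tot = _per_gene_counts(pos, meth_cum, tot_cum, _bin_edges(g, n_body_bins, flank, flank_bin))
        if g.strand == "-":
            meth, tot = meth[::-1], tot[::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            levels[i] = np.where(tot > 0, meth / tot, np.nan)
        meth_pool += meth
        tot_pool += tot

    if pooled:
        with np.errstate(invalid="ignore", divide="ignore"):
            bins = np.where(tot_pool > 0, meth_pool / tot_pool, np.nan)
    else:
        import warnings

        with warnings.catch_warnings():
            # bins with no covered cytosine in any gene stay NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            bins = np.nanmean(levels, axis=0)
    return MetaProfile(context, label, bins, n_flank, n_body_bins, len(genes))


def profiles_to_frame(profiles: Sequence[MetaProfile]) -> pd.DataFrame:
    """Bin x group matrix for TSV output; bin labels mark the three zones."""
    if not profiles:
        return pd.DataFrame()
    p0 = profiles[0]
    labels = (
        [f"up_{i}" for i in range(p0.n_flank_bins)]
        + [f"body_{i}" for i in range(p0.n_body_bins)]
        + [f"down_{i}" for i in range(p0.n_flank_bins)]
    )
    return pd.DataFrame(
        {f"{p.label}:{p.context}": p.bins for p in profiles}, index=pd.Index(labels, name="bin")
    )
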