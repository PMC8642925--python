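"""Clusters of imprinted transcripts along the genome.

A cluster is a maximal chain of imprinted transcripts (MEG/PEG/MNC/PNC by
default) in which consecutive members are at most 1 Mb apart and no
allelically analyzed non-imprinted gene lies between members. Non-analyzed
genes — typically genes without informative SNPs — do not break chains.
Chains need at least two members to be reported. Mixed maternal/paternal
clusters are allowed.

Distances are measured start-to-start. "Within a region of 1 Mb" is applied
to consecutive-member gaps (chaining); a strict variant additionally caps
the whole chain span at 1 Mb (``strict_total_span=True``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .imprinting_stats import (
    IMPRINTED_STATUSES,
    MATERNAL_STATUSES,
    PATERNAL_STATUSES,
    Status,
)
from .io_formats import GeneModel

DEFAULT_MAX_SPAN = 1_000_000


@dataclass(frozen=True)
class ImprintCluster:
    """A run of >= 2 imprinted transcripts; span covers member gene bodies."""

    chrom: str
    start: int
    end: int
    members: tuple[str, ...]
    n_meg: int
    n_peg: int

    @property
    def size(self) -> int:
        return len(self.members)

    def bed_name(self) -> str:
        return ",".join(self.members)

    def bed_score(self) -> int:
        return self.size


def _sorted_genes(gene_models: Sequence[GeneModel]) -> list[GeneModel]:
    genes = list(gene_models)
    for a, b in zip(genes, genes[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("gene models must be sorted by (chrom, start)")
    return genes


def _make_cluster(
    members: list[GeneModel], statuses: Mapping[str, Status]
) -> ImprintCluster:
    n_meg = sum(1 for g in members if statuses[g.gene_id] in MATERNAL_STATUSES)
    n_peg = sum(1 for g in members if statuses[g.gene_id] in PATERNAL_STATUSES)
    return ImprintCluster(
        chrom=members[0].chrom,
        start=min(g.start for g in members),
        end=max(g.end for g in members),
        members=tuple(g.gene_id for g in members),
        n_meg=n_meg,
        n_peg=n_peg,
    )


def find_clusters(
    statuses: Mapping[str, Status],
    gene_models: Sequence[GeneModel],
    max_span: int = DEFAULT_MAX_SPAN,
    imprinted_statuses: frozenset[Status] = IMPRINTED_STATUSES,
    strict_total_span: bool = False,
) -> list[ImprintCluster]:
    """Scan the genome for imprinted-transcript clusters.

    ``statuses`` maps gene_id -> imprinting status (genes absent from the
    mapping are treated as non-analyzed). ``gene_models`` must be sorted by
    (chrom, start); unsorted input raises. Chains break at chromosome
    boundaries, when the start-to-start gap between consecutive imprinted
    members exceeds ``max_span``, or when an analyzed non-imprinted gene
    lies between members.
    """
    genes = _sorted_genes(gene_models)
    clusters: list[ImprintCluster] = []
    chain: list[GeneModel] = []
    blocked = False  # analyzed non-imprinted gene seen since last member
    current_chrom: str | None = None

    def flush() -> None:
        nonlocal chain
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain, statuses))
        chain = []

    for g in genes:
        status = statuses.get(g.gene_id, Status.NON_ANALYZED)
        if g.chrom != current_chrom:
            flush()
            blocked = False
            current_chrom = g.chrom
        if status in imprinted_statuses:
            if chain:
                gap_ok = g.start - chain[-1].start <= max_span
                if strict_total_span:
                    gap_ok = gap_ok and g.start - chain[0].start <= max_span
                if blocked or not gap_ok:
                    flush()
            chain.append(g)
            blocked = False
        elif status is not Status.NON_ANALYZED:
            blocked = True  # analyzed, not imprinted: breaks any chain
    flush()
    return clusters


def spacing_stats(
    statuses: Mapping[str, Status],
    gene_models: Sequence[GeneModel],
    imprinted_statuses: frozenset[Status] = IMPRINTED_STATUSES,
) -> tuple[float, np.ndarray]:
    """Start-to-start distances between consecutive imprinted transcripts
    within each chromosome, and their mean over all pairs. Chromosomes with
    fewer than two imprinted transcripts contribute no distances."""
    by_chrom: dict[str, list[int]] = {}
    for g in _sorted_genes(gene_models):
        if statuses.get(g.gene_id, Status.NON_ANALYZED) in imprinted_statuses:
            by_chrom.setdefault(g.chrom, []).append(g.start)
    distances = np.concatenate(
        [np.diff(starts) for starts in by_chrom.values() if len(starts) >= 2]
        or [np.empty(0, dtype=int)]
    )
    mean = float(distances.mean()) if distances.size else float("nan")
    return mean, distances


@dataclass(frozen=True)
class ClusterSizeSummary:
    """Distribution of cluster sizes with member totals."""

    proportions: dict[int, float] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)
    total_members: int = 0
    n_meg: int = 0
    n_peg: int = 0


def cluster_size_distribution(
    clusters: Iterable[ImprintCluster] | Iterable[int],
) -> ClusterSizeSummary:
    """Fraction of clusters with each member count, plus the total member
    count and maternal/paternal breakdown. Accepts clusters or bare sizes
    (for summarising an external cluster table); empty input gives an empty
    distribution."""
    items = list(clusters)
    if not items:
        return ClusterSizeSummary()
    if isinstance(items[0], ImprintCluster):
        sizes = [c.size for c in items]
        n_meg = sum(c.n_meg for c in items)
        n_peg = sum(c.n_peg for c in items)
    else:
        sizes = [int(s) for s in items]
        n_meg = n_peg = 0
    counts = Counter(sizes)
    n = len(sizes)
    return ClusterSizeSummary(
        proportions={k: counts[k] / n for k in sorted(counts)},
        counts=dict(sorted(counts.items())),
        total_members=sum(sizes),
        n_meg=n_meg,
        n_peg=n_peg,
    )
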