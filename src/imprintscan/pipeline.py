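"""Glue running the per-stage operations end-to-end, plus truth scoring."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .allelic_counting import (
    DEFAULT_OTHER_FRAC_MAX,
    GeneAllelicSummary,
    assign_sample,
    summarize_genes,
)
from .dmr_calling import Dmr
from .imprinting_stats import ImprintingCall, Status, call_imprinting
from .synthetic_data import SyntheticAse


def summarize_pair(
    ase: SyntheticAse,
    pair: tuple[str, str],
    other_frac_max: float = DEFAULT_OTHER_FRAC_MAX,
) -> tuple[dict[str, GeneAllelicSummary], dict[str, GeneAllelicSummary]]:
    """Gene-level allelic summaries for one reciprocal cross pair."""
    fwd_sample, rev_sample = pair
    out = []
    for sample, direction in ((fwd_sample, "forward"), (rev_sample, "reciprocal")):
        assigned = assign_sample(
            ase.base_counts[sample], ase.snps, ase.orientations[sample], sample
        )
        out.append(summarize_genes(assigned, ase.genes, direction, other_frac_max))
    return out[0], out[1]


def call_pair(ase: SyntheticAse, pair: tuple[str, str], **kwargs) -> dict[str, ImprintingCall]:
    """Imprinting calls for one reciprocal cross pair of a synthetic dataset."""
    fwd, rev = summarize_pair(ase, pair)
    biotypes = {g.gene_id: g.biotype for g in ase.genes}
    return call_imprinting(fwd, rev, biotypes, **kwargs)


def score_ase_recovery(
    calls: Mapping[str, ImprintingCall] | Mapping[str, Status],
    truth: pd.DataFrame,
) -> dict[str, float]:
    """Precision/recall of high-stringency (and noncoding) imprinting calls
    against the planted truth.

    Recovery = fraction of planted imprinted transcripts called with their
    expected label; observed FDR = fraction of imprinted calls whose
    planted status is not imprinted in that direction.
    """
    status_of = {
        gid: (c.status if isinstance(c, ImprintingCall) else c) for gid, c in calls.items()
    }
    expected = dict(zip(truth["gene_id"], truth["expected_call"]))
    planted = {g: e for g, e in expected.items() if e != Status.BIALLELIC.value}
    n_recovered = sum(
        1 for g, e in planted.items() if status_of.get(g, Status.NON_ANALYZED).value == e
    )
    maternal = {Status.MEG, Status.MNC}
    paternal = {Status.PEG, Status.PNC}
    n_called = n_false = 0
    for gid, s in status_of.items():
        if s in maternal | paternal:
            n_called += 1
            true_call = expected.get(gid, Status.BIALLELIC.value)
            true_dir = maternal if true_call in ("MEG", "MNC") else (
                paternal if true_call in ("PEG", "PNC") else set()
            )
            if s not in true_dir:
                n_false += 1
    return {
        "n_planted": len(planted),
        "n_recovered": n_recovered,
        "recovery": n_recovered / len(planted) if planted else float("nan"),
        "n_called": n_called,
        "n_false": n_false,
        "fdr": n_false / n_called if n_called else 0.0,
    }


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def score_dmr_recovery(
    dmrs: Sequence[Dmr],
    regions: pd.DataFrame,
    min_reciprocal_overlap: float = 0.5,
    direction: str = "endosperm_hypo",
) -> dict[str, float]:
    """Fraction of planted regions matched by a called DMR of the right
    direction with at least ``min_reciprocal_overlap`` of each interval
    covered by the other, plus the count of unmatched (false) calls."""
    called = [d for d in dmrs if d.direction == direction]
    matched_regions = 0
    matched_dmrs: set[int] = set()
    for _, r in regions.iterrows():
        for i, d in enumerate(called):
            if d.chrom != r["chrom"]:
                continue
            if _reciprocal_overlap(int(r["start"]), int(r["end"]), d.start, d.end) >= min_reciprocal_overlap:
                matched_regions += 1
                matched_dmrs.add(i)
                break
    n_regions = len(regions)
    return {
        "n_planted": n_regions,
        "n_recovered": matched_regions,
        "recovery": matched_regions / n_regions if n_regions else float("nan"),
        "n_called": len(called),
        "n_unmatched_calls": len(called) - len(matched_dmrs),
    }
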