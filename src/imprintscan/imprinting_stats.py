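"""Imprinting calls from gene-level allele counts against the 2m:1p null.

Endosperm is triploid with two maternal and one paternal genome copy, so a
biallelically expressed gene is expected to show a 2:1 maternal:paternal
read ratio. Each gene's summed counts (M, P) are tested per cross direction
with a plain Pearson chi-square against expected (2n/3, n/3), n = M + P;
p-values are converted to Benjamini-Hochberg q-values across all analyzable
genes of the cross pair, separately per direction.

Classification (per cross pair):

* low-stringency maternal: q < 0.05 in both directions with a maternal
  fraction above the 2/3 dosage expectation in both;
* low-stringency paternal: mirrored (maternal fraction below 2/3 in both);
* high-stringency MEG/PEG additionally require the favorable allele to
  exceed a five-fold excess over dosage in both directions: maternal
  fraction strictly > 2f/(2f+1) = 10/11 for MEGs, paternal fraction
  strictly > f/(f+2) = 5/7 for PEGs, at the default fold factor f = 5.
  The thresholds are derived from (f, dosage), never hard-coded.

Coding genes get MEG/PEG (high) or low_MEG/low_PEG labels; noncoding
transcripts meeting the low-stringency rule are labelled MNC/PNC. Genes
significant in opposite parental directions in the two crosses reflect a
genotype rather than a parent-of-origin effect and stay biallelic.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .allelic_counting import MIN_ASSIGNABLE_READS, GeneAllelicSummary, is_analyzable

logger = logging.getLogger(__name__)

#: Maternal:paternal genome dosage in endosperm.
ENDOSPERM_DOSAGE = (2, 1)

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_FOLD = 5.0


class Status(str, enum.Enum):
    """Per-gene imprinting status."""

    MEG = "MEG"
    PEG = "PEG"
    MNC = "MNC"
    PNC = "PNC"
    LOW_MEG = "low_MEG"
    LOW_PEG = "low_PEG"
    BIALLELIC = "biallelic"
    NON_ANALYZED = "non_analyzed"


#: Statuses counted as imprinted transcripts downstream (clusters,
#: DMR association): high-stringency coding genes plus noncoding RNAs.
IMPRINTED_STATUSES = frozenset({Status.MEG, Status.PEG, Status.MNC, Status.PNC})

#: Any parental bias call, including low-stringency-only coding genes.
MATERNAL_STATUSES = frozenset({Status.MEG, Status.LOW_MEG, Status.MNC})
PATERNAL_STATUSES = frozenset({Status.PEG, Status.LOW_PEG, Status.PNC})


def dosage_fraction(dosage: tuple[float, float] = ENDOSPERM_DOSAGE) -> float:
    """Expected maternal read fraction under biallelic expression (2/3)."""
    m, p = dosage
    return m / (m + p)


def meg_fraction_threshold(
    fold: float = DEFAULT_FOLD, dosage: tuple[float, float] = ENDOSPERM_DOSAGE
) -> float:
    """Maternal-fraction cutoff for a high-stringency MEG: the maternal
    allele exceeds an f-fold excess over its dosage share, i.e.
    m*f / (m*f + p) — 10/11 at f=5, dosage 2:1."""
    m, p = dosage
    return m * fold / (m * fold + p)


def peg_fraction_threshold(
    fold: float = DEFAULT_FOLD, dosage: tuple[float, float] = ENDOSPERM_DOSAGE
) -> float:
    """Paternal-fraction cutoff for a high-stringency PEG:
    p*f / (m + p*f) — 5/7 at f=5, dosage 2:1."""
    m, p = dosage
    return p * fold / (m + p * fold)


def chi2_two_to_one(
    M, P, dosage: tuple[float, float] = ENDOSPERM_DOSAGE
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Pearson chi-square of observed (M, P) against the dosage null.

    Expected counts are (2n/3, n/3) at the endosperm 2:1 dosage; the
    statistic is Sigma (O-E)^2 / E on 1 df, two-tailed by construction. No
    continuity correction is applied. Accepts scalars or arrays; n = M + P
    must be positive (callers pre-filter non-analyzable genes).
    """
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    n = M + P
    if np.any(n <= 0):
        raise ValueError("chi2_two_to_one requires M + P > 0")
    fm = dosage_fraction(dosage)
    e_m = n * fm
    e_p = n * (1.0 - fm)
    stat = (M - e_m) ** 2 / e_m + (P - e_p) ** 2 / e_p
    p_value = stats.chi2.sf(stat, df=1)
    if stat.ndim == 0:
        return float(stat), float(p_value)
    return stat, p_value


def adjust_q(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ImprintingCall:
    """Classification of one gene from a reciprocal cross pair."""

    gene_id: str
    status: Status
    chi2_fwd: float
    chi2_rev: float
    q_fwd: float
    q_rev: float
    maternal_fraction_fwd: float
    maternal_fraction_rev: float
    m_fwd: int = 0
    p_fwd: int = 0
    m_rev: int = 0
    p_rev: int = 0

    @property
    def is_imprinted(self) -> bool:
        return self.status in IMPRINTED_STATUSES

    @property
    def is_analyzed(self) -> bool:
        return self.status is not Status.NON_ANALYZED


def classify(
    fwd: GeneAllelicSummary,
    rev: GeneAllelicSummary,
    q_fwd: float,
    q_rev: float,
    biotype: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fold: float = DEFAULT_FOLD,
    dosage: tuple[float, float] = ENDOSPERM_DOSAGE,
) -> Status:
    """Classify one analyzable gene from its per-direction summaries and
    q-values. Both directions must be significant with a consistent parental
    direction; high-stringency thresholds are strict inequalities."""
    f0 = dosage_fraction(dosage)
    mf_f, mf_r = fwd.maternal_fraction, rev.maternal_fraction
    significant = q_fwd < q_threshold and q_rev < q_threshold
    if not significant:
        return Status.BIALLELIC
    maternal_bias = mf_f > f0 and mf_r > f0
    paternal_bias = mf_f < f0 and mf_r < f0
    if maternal_bias:
        if biotype == "noncoding":
            return Status.MNC
        thr = meg_fraction_threshold(fold, dosage)
        return Status.MEG if (mf_f > thr and mf_r > thr) else Status.LOW_MEG
    if paternal_bias:
        if biotype == "noncoding":
            return Status.PNC
        thr = peg_fraction_threshold(fold, dosage)
        return Status.PEG if ((1 - mf_f) > thr and (1 - mf_r) > thr) else Status.LOW_PEG
    # significant in both directions but with opposite parental bias:
    # a genotype effect, not imprinting
    return Status.BIALLELIC


def call_imprinting(
    summaries_fwd: Mapping[str, GeneAllelicSummary],
    summaries_rev: Mapping[str, GeneAllelicSummary],
    biotypes: Mapping[str, str],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fold: float = DEFAULT_FOLD,
    min_reads: int = MIN_ASSIGNABLE_READS,
    dosage: tuple[float, float] = ENDOSPERM_DOSAGE,
    expressed: Mapping[str, bool] | None = None,
) -> dict[str, ImprintingCall]:
    """Run the full per-cross-pair imprinting test over all genes.

    The Benjamini-Hochberg family is the set of analyzable genes of this
    cross pair, adjusted separately per direction. ``expressed`` optionally
    restricts the analysis to expressed genes (e.g. FPKM >= 1 upstream);
    genes marked unexpressed are non-analyzed. Low count warning: genes with
    expected counts below 5 in either cell are still tested (flagged in the
    log), matching a plain Pearson test.
    """
    gene_ids = sorted(set(summaries_fwd) | set(summaries_rev))
    analyzable: list[str] = []
    for gid in gene_ids:
        if expressed is not None and not expressed.get(gid, False):
            continue
        if is_analyzable(summaries_fwd.get(gid), summaries_rev.get(gid), min_reads):
            analyzable.append(gid)

    calls: dict[str, ImprintingCall] = {}
    nan = float("nan")
    for gid in gene_ids:
        if gid not in analyzable:
            s_f, s_r = summaries_fwd.get(gid), summaries_rev.get(gid)
            calls[gid] = ImprintingCall(
                gid, Status.NON_ANALYZED, nan, nan, nan, nan,
                s_f.maternal_fraction if s_f else nan,
                s_r.maternal_fraction if s_r else nan,
                s_f.maternal_total if s_f else 0, s_f.paternal_total if s_f else 0,
                s_r.maternal_total if s_r else 0, s_r.paternal_total if s_r else 0,
            )
    if not analyzable:
        return calls

    m_f = np.array([summaries_fwd[g].maternal_total for g in analyzable])
    p_f = np.array([summaries_fwd[g].paternal_total for g in analyzable])
    m_r = np.array([summaries_rev[g].maternal_total for g in analyzable])
    p_r = np.array([summaries_rev[g].paternal_total for g in analyzable])
    stat_f, pv_f = chi2_two_to_one(m_f, p_f, dosage)
    stat_r, pv_r = chi2_two_to_one(m_r, p_r, dosage)
    n_low = int(np.sum((m_f + p_f) * min(dosage) / sum(dosage) < 5))
    if n_low:
        logger.info("call_imprinting: %d genes with expected cell count < 5", n_low)
    q_f = adjust_q(pv_f)
    q_r = adjust_q(pv_r)

    for i, gid in enumerate(analyzable):
        status = classify(
            summaries_fwd[gid], summaries_rev[gid], q_f[i], q_r[i],
            biotypes.get(gid, "coding"), q_threshold, fold, dosage,
        )
        calls[gid] = ImprintingCall(
            gid, status,
            float(stat_f[i]), float(stat_r[i]), float(q_f[i]), float(q_r[i]),
            float(m_f[i] / (m_f[i] + p_f[i])), float(m_r[i] / (m_r[i] + p_r[i])),
            int(m_f[i]), int(p_f[i]), int(m_r[i]), int(p_r[i]),
        )
    return calls


def calls_to_frame(calls: Mapping[str, ImprintingCall]) -> pd.DataFrame:
    """Tabulate calls for TSV output."""
    rows = [
        (
            c.gene_id, c.status.value, c.m_fwd, c.p_fwd, c.m_rev, c.p_rev,
            c.maternal_fraction_fwd, c.maternal_fraction_rev,
            c.chi2_fwd, c.chi2_rev, c.q_fwd, c.q_rev,
        )
        for c in calls.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "status", "M_fwd", "P_fwd", "M_rev", "P_rev",
            "maternal_fraction_fwd", "maternal_fraction_rev",
            "chi2_fwd", "chi2_rev", "q_fwd", "q_rev",
        ],
    ).sort_values("gene_id", ignore_index=True)


def frame_to_calls(df: pd.DataFrame) -> dict[str, ImprintingCall]:
    """Inverse of :func:`calls_to_frame`."""
    calls = {}
    for r in df.itertuples(index=False):
        calls[r.gene_id] = ImprintingCall(
            r.gene_id, Status(r.status), r.chi2_fwd, r.chi2_rev, r.q_fwd, r.q_rev,
            r.maternal_fraction_fwd, r.maternal_fraction_rev,
            int(r.M_fwd), int(r.P_fwd), int(r.M_rev), int(r.P_rev),
        )
    return calls


def merge_cross_pairs(
    per_pair_calls: list[Mapping[str, ImprintingCall]],
) -> dict[str, Status]:
    """Union imprinting status over cross pairs.

    A transcript imprinted (high-stringency or noncoding) in either pair is
    imprinted; conflicting parental directions between pairs demote the gene
    to biallelic. A gene analyzed in any pair counts as analyzed.
    """
    rank = {
        Status.NON_ANALYZED: 0, Status.BIALLELIC: 1,
        Status.LOW_MEG: 2, Status.LOW_PEG: 2,
        Status.MNC: 3, Status.PNC: 3, Status.MEG: 3, Status.PEG: 3,
    }
    merged: dict[str, Status] = {}
    for calls in per_pair_calls:
        for gid, call in calls.items():
            prev = merged.get(gid)
            if prev is None:
                merged[gid] = call.status
                continue
            conflict = (
                prev in MATERNAL_STATUSES and call.status in PATERNAL_STATUSES
            ) or (prev in PATERNAL_STATUSES and call.status in MATERNAL_STATUSES)
            if conflict:
                merged[gid] = Status.BIALLELIC
            elif rank[call.status] > rank[prev]:
                merged[gid] = call.status
    return merged
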