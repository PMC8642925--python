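"""Sliding-window differential methylation between embryo and endosperm.

Windows of 200 bp are tiled at 20-bp steps (phased from each chromosome's
first covered cytosine of the requested context). In each window, read
counts are pooled over sites per tissue and compared with a two-sided
Fisher exact test on the 2x2 table [meth, unmeth] x [embryo, endosperm].
p-values are converted to Benjamini-Hochberg q-values across all tested
windows of the context; windows with q < 0.01 AND an absolute methylation
difference > 30 percentage points are significant. Significant windows of
the same direction within 200 bp of each other (end-to-start, inclusive)
are merged into DMRs labelled endosperm_hypo or embryo_hypo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imprinting_stats import adjust_q

DEFAULT_WINDOW = 200
DEFAULT_STEP = 20
DEFAULT_FDR = 0.01
DEFAULT_MIN_DIFF = 0.30
DEFAULT_MERGE_GAP = 200

ENDOSPERM_HYPO = "endosperm_hypo"
EMBRYO_HYPO = "embryo_hypo"


@dataclass(frozen=True)
class MethWindow:
    """One tested sliding window with pooled per-tissue counts."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    context: str
    emb_meth: int
    emb_unmeth: int
    endo_meth: int
    endo_unmeth: int
    p_value: float
    q_value: float = float("nan")

    @property
    def level_diff(self) -> float:
        """Endosperm level minus embryo level (percentage points / 100)."""
        emb = self.emb_meth / (self.emb_meth + self.emb_unmeth)
        endo = self.endo_meth / (self.endo_meth + self.endo_unmeth)
        return endo - emb

    @property
    def direction(self) -> str:
        return ENDOSPERM_HYPO if self.level_diff < 0 else EMBRYO_HYPO


@dataclass(frozen=True)
class Dmr:
    """Merged run of same-direction significant windows."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str
    n_windows: int
    min_q: float

    def bed_name(self) -> str:
        return f"{self.direction}"

    def bed_score(self) -> float:
        return self.min_q

    def length(self) -> int:
        return self.end - self.start + 1


def window_test(
    emb_meth: int, emb_unmeth: int, endo_meth: int, endo_unmeth: int
) -> tuple[float, float]:
    """Two-sided Fisher exact p and level difference for one window.

    Returns (p, diff) with diff = endosperm level - embryo level. Both
    tissues must have at least one covered cytosine (positive total);
    callers skip windows that do not qualify rather than score them p = 1.
    """
    if emb_meth + emb_unmeth == 0 or endo_meth + endo_unmeth == 0:
        raise ValueError("window_test requires covered cytosines in both tissues")
    _, p = stats.fisher_exact(
        [[emb_meth, emb_unmeth], [endo_meth, endo_unmeth]], alternative="two-sided"
    )
    diff = endo_meth / (endo_meth + endo_unmeth) - emb_meth / (emb_meth + emb_unmeth)
    return float(p), float(diff)


def fisher_two_sided_batch(tables: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Fisher exact p-values for many 2x2 tables.

    ``tables`` is (n, 4): [a, b, c, d] rows. The two-sided p sums, over the
    hypergeometric support fixed by the margins, the probabilities of all
    tables no more likely than the observed one (with the same relative
    tolerance scipy uses for ties). Agrees with
    ``scipy.stats.fisher_exact(..., "two-sided")`` and is the engine behind
    genome-scale window testing.
    """
    tables = np.asarray(tables, dtype=np.int64)
    if tables.size == 0:
        return np.empty(0)
    a, b, c, d = tables.T
    n1 = a + b  # row-1 margin
    m1 = a + c  # col-1 margin
    N = a + b + c + d
    lo = np.maximum(0, n1 + m1 - N)
    hi = np.minimum(n1, m1)
    counts = (hi - lo + 1).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    idx = np.repeat(np.arange(len(tables)), counts)
    k = np.arange(total) - np.repeat(offsets[:-1], counts) + lo[idx]
    logpmf = stats.hypergeom.logpmf(k, N[idx], m1[idx], n1[idx])
    log_obs = stats.hypergeom.logpmf(a, N, m1, n1)
    # scipy counts tables with pmf <= pmf(observed) * (1 + ~1e-7)
    take = logpmf <= log_obs[idx] + 1e-7
    pmf = np.where(take, np.exp(logpmf), 0.0)
    p = np.add.reduceat(pmf, offsets[:-1])
    return np.minimum(p, 1.0)


def _chrom_arrays(df: pd.DataFrame, context: str) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    sub = df[df["context"] == context].sort_values(["chrom", "pos"])
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy(dtype=np.int64)
        tot = meth + grp["unmeth"].to_numpy(dtype=np.int64)
        out[chrom] = (
            pos,
            np.concatenate([[0], np.cumsum(meth)]),
            np.concatenate([[0], np.cumsum(tot)]),
        )
    return out


def tile_windows(
    embryo: pd.DataFrame,
    endosperm: pd.DataFrame,
    context: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    phase: int | None = None,
) -> list[MethWindow]:
    """Tile windows and compute Fisher p-values.

    Tiling starts at each chromosome's first covered cytosine (either
    tissue) unless an explicit 1-based ``phase`` is given. Windows lacking a
    covered cytosine in either tissue are skipped, not scored. q-values are
    left NaN; :func:`call_dmrs` fills them in per context.
    """
    emb = _chrom_arrays(embryo, context)
    endo = _chrom_arrays(endosperm, context)
    windows: list[MethWindow] = []
    all_tables: list[np.ndarray] = []
    meta: list[tuple[str, np.ndarray]] = []
    for chrom in sorted(set(emb) | set(endo)):
        if chrom not in emb or chrom not in endo:
            continue
        pos_e, mcum_e, tcum_e = emb[chrom]
        pos_n, mcum_n, tcum_n = endo[chrom]
        first = min(pos_e[0], pos_n[0]) if phase is None else phase
        last = max(pos_e[-1], pos_n[-1])
        starts = np.arange(first, last + 1, step, dtype=np.int64)
        ends = starts + window - 1
        i0 = np.searchsorted(pos_e, starts)
        i1 = np.searchsorted(pos_e, ends + 1)
        j0 = np.searchsorted(pos_n, starts)
        j1 = np.searchsorted(pos_n, ends + 1)
        emb_m = mcum_e[i1] - mcum_e[i0]
        emb_t = tcum_e[i1] - tcum_e[i0]
        endo_m = mcum_n[j1] - mcum_n[j0]
        endo_t = tcum_n[j1] - tcum_n[j0]
        keep = (emb_t > 0) & (endo_t > 0)
        tables = np.stack(
            [emb_m[keep], (emb_t - emb_m)[keep], endo_m[keep], (endo_t - endo_m)[keep]], axis=1
        )
        all_tables.append(tables)
        meta.append((chrom, starts[keep]))
    if not all_tables:
        return []
    stacked = np.concatenate(all_tables)
    p_values = fisher_two_sided_batch(stacked)
    offset = 0
    for (chrom, starts), tables in zip(meta, all_tables):
        for s, (em, eu, nm, nu), p in zip(
            starts, tables, p_values[offset : offset + len(tables)]
        ):
            windows.append(
                MethWindow(chrom, int(s), int(s) + window - 1, context,
                           int(em), int(eu), int(nm), int(nu), float(p))
            )
        offset += len(tables)
    return windows


def merge_windows(significant: Sequence[MethWindow], merge_gap: int = DEFAULT_MERGE_GAP) -> list[Dmr]:
    """Merge significant windows into DMRs.

    Windows are grouped by chromosome and direction; within a group, sorted
    windows are merged when the gap between them (bases strictly between
    the previous end and the next start) is at most ``merge_gap``.
    Opposite-direction windows are never merged. The operation is
    idempotent and independent of input order.
    """
    groups: dict[tuple[str, str, str], list[MethWindow]] = {}
    for w in significant:
        groups.setdefault((w.chrom, w.context, w.direction), []).append(w)
    dmrs: list[Dmr] = []
    for (chrom, context, direction), ws in groups.items():
        ws = sorted(ws, key=lambda w: w.start)
        run = [ws[0]]
        run_end = ws[0].end
        for w in ws[1:]:
            if w.start - run_end - 1 <= merge_gap:
                run.append(w)
                run_end = max(run_end, w.end)
            else:
                dmrs.append(_finish_run(chrom, context, direction, run))
                run = [w]
                run_end = w.end
        dmrs.append(_finish_run(chrom, context, direction, run))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    return dmrs


def _finish_run(chrom: str, context: str, direction: str, run: list[MethWindow]) -> Dmr:
    return Dmr(
        chrom=chrom,
        start=min(w.start for w in run),
        end=max(w.end for w in run),
        context=context,
        direction=direction,
        n_windows=len(run),
        min_q=min(w.q_value for w in run),
    )


def call_dmrs(
    embryo: pd.DataFrame,
    endosperm: pd.DataFrame,
    context: str = "CG",
    fdr: float = DEFAULT_FDR,
    min_diff: float = DEFAULT_MIN_DIFF,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    merge_gap: int = DEFAULT_MERGE_GAP,
    phase: int | None = None,
) -> tuple[list[Dmr], list[MethWindow]]:
    """Full DMR calling for one context.

    Returns (dmrs, tested_windows); the tested windows carry their BH
    q-values and define the "analyzed methylated regions" used downstream
    to decide which genes are assessable for DMR overlap.
    """
    windows = tile_windows(embryo, endosperm, context, window, step, phase)
    if not windows:
        return [], []
    q = adjust_q([w.p_value for w in windows])
    windows = [
        MethWindow(w.chrom, w.start, w.end, w.context, w.emb_meth, w.emb_unmeth,
                   w.endo_meth, w.endo_unmeth, w.p_value, float(qi))
        for w, qi in zip(windows, q)
    ]
    significant = [w for w in windows if w.q_value < fdr and abs(w.level_diff) > min_diff]
    return merge_windows(significant, merge_gap), windows


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.chrom, d.start, d.end, d.context, d.direction, d.n_windows, d.min_q) for d in dmrs],
        columns=["chrom", "start", "end", "context", "direction", "n_windows", "min_q"],
    )


def frame_to_dmrs(df: pd.DataFrame) -> list[Dmr]:
    return [
        Dmr(r.chrom, int(r.start), int(r.end), r.context, r.direction, int(r.n_windows), float(r.min_q))
        for r in df.itertuples(index=False)
    ]
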