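"""Readers and writers for the pipeline's external formats.

All in-memory coordinates are 1-based inclusive; only BED output converts to
the on-disk 0-based half-open convention. Chromosome names are matched as
exact strings — no "chr" prefix normalisation is attempted.

The tabular formats handled here are bespoke TSVs (parental SNP table,
per-SNP base counts, Bismark-style cytosine report); they are parsed by hand
so that malformed lines can be reported with their line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
METH_CONTEXTS = ("CG", "CHG", "CHH")

#: Parental SNPs must be supported by more than this many genomic reads.
MIN_SNP_DEPTH = 3


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic site distinguishing the two parental lines.

    ``allele_a``/``allele_b`` are the bases carried by parent line A and
    parent line B respectively; which of the two is maternal depends on the
    cross orientation of a given hybrid sample, not on the SNP itself.
    """

    chrom: str
    pos: int  # 1-based
    allele_a: str
    allele_b: str
    depth: int

    def is_valid(self) -> bool:
        return (
            self.allele_a in VALID_BASES
            and self.allele_b in VALID_BASES
            and self.allele_a != self.allele_b
            and self.depth > MIN_SNP_DEPTH
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene-level annotation span (children such as mRNA/exon are ignored:
    imprinting is called on per-gene read sums)."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    biotype: str  # "coding" or "noncoding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite call: methylated/unmethylated read counts in
    one of the CG / CHG / CHH sequence contexts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth_count: int
    unmeth_count: int

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        """Methylation fraction C/(C+T) at this site."""
        return self.meth_count / self.depth


class ParseError(ValueError):
    """Malformed line in a tabular input; the message names the line."""


def _fields(line: str, n: int, path: str, lineno: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n:
        raise ParseError(f"{path}:{lineno}: expected {n} tab-separated fields, got {len(parts)}")
    return parts


# ---------------------------------------------------------------------------
# SNP table

SNP_COLUMNS = ("chrom", "pos", "allele_a", "allele_b", "depth")


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a parental SNP table (TSV: chrom, pos, allele_a, allele_b, depth).

    Records violating the SNP invariants (non-ACGT or identical parental
    alleles, read depth <= 3) are dropped; the number dropped is logged.
    Returned records are sorted by (chrom, pos).
    """
    path = Path(path)
    records: list[SnpRecord] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.startswith("chrom"):
                continue
            if not line.strip():
                continue
            parts = _fields(line, 5, str(path), lineno)
            try:
                rec = SnpRecord(
                    chrom=parts[0],
                    pos=int(parts[1]),
                    allele_a=parts[2].upper(),
                    allele_b=parts[3].upper(),
                    depth=int(parts[4]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.is_valid():
                records.append(rec)
            else:
                n_dropped += 1
    if n_dropped:
        logger.info("read_snp_table(%s): dropped %d invalid SNP rows", path, n_dropped)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.allele_a}\t{r.allele_b}\t{r.depth}\n")


# ---------------------------------------------------------------------------
# Per-SNP base counts (pileup-derived, one file per hybrid sample)

BASE_COUNT_COLUMNS = ("chrom", "pos", "count_A", "count_C", "count_G", "count_T")


def read_base_counts(path: str | Path) -> pd.DataFrame:
    """Read per-SNP base counts for one sample.

    TSV columns: chrom, pos, count_A, count_C, count_G, count_T. Returns a
    DataFrame sorted by (chrom, pos); counts must be non-negative integers.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.startswith("chrom"):
                continue
            if not line.strip():
                continue
            parts = _fields(line, 6, str(path), lineno)
            try:
                counts = [int(x) for x in parts[1:6]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if any(c < 0 for c in counts[1:]):
                raise ParseError(f"{path}:{lineno}: negative base count")
            rows.append((parts[0], *counts))
    df = pd.DataFrame(rows, columns=BASE_COUNT_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def write_base_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(BASE_COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Cytosine report (Bismark-style)


def read_cytosine_report(path: str | Path) -> Iterator[CytosineRecord]:
    """Lazily iterate a Bismark-style cytosine report.

    TSV columns: chrom, pos, strand, meth_count, unmeth_count, context.
    Contexts are normalised to upper-case and must be CG, CHG or CHH
    ("CpG" is accepted as an alias for CG). Counts must be non-negative.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.lower().startswith("chrom"):
                continue
            if not line.strip():
                continue
            parts = _fields(line, 6, str(path), lineno)
            context = parts[5].upper()
            if context == "CPG":
                context = "CG"
            if context not in METH_CONTEXTS:
                raise ParseError(f"{path}:{lineno}: unknown methylation context {parts[5]!r}")
            try:
                meth, unmeth = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative methylation count")
            yield CytosineRecord(parts[0], int(parts[1]), parts[2], context, meth, unmeth)


def load_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Eagerly load a cytosine report into a DataFrame
    (chrom, pos, strand, context, meth, unmeth), sorted by (chrom, pos)."""
    recs = list(read_cytosine_report(path))
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.strand, r.context, r.meth_count, r.unmeth_count) for r in recs],
        columns=["chrom", "pos", "strand", "context", "meth", "unmeth"],
    )
    return df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cytosine DataFrame (columns as from :func:`load_cytosine_report`)
    in Bismark-style column order."""
    out = df[["chrom", "pos", "strand", "meth", "unmeth", "context"]]
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# GFF3 (gene features only)


def _gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene-level features from a GFF3 file.

    Only ``gene``-type rows (and ``ncRNA_gene``/``lnc_RNA`` rows, treated as
    noncoding genes) are consumed; mRNA/exon children are ignored. Biotype is
    taken from a ``biotype=`` attribute when present (any value containing
    "lnc" or equal to "noncoding" maps to noncoding), else from the feature
    type, defaulting to coding.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, 9, str(path), lineno)
            ftype = parts[2]
            if ftype not in ("gene", "ncRNA_gene", "lnc_RNA"):
                continue
            attrs = _gff3_attributes(parts[8])
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            biotype_attr = attrs.get("biotype", "").lower()
            if ftype in ("ncRNA_gene", "lnc_RNA") or "lnc" in biotype_attr or biotype_attr == "noncoding":
                biotype = "noncoding"
            else:
                biotype = "coding"
            try:
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=parts[0],
                        start=int(parts[3]),
                        end=int(parts[4]),
                        strand=parts[6],
                        biotype=biotype,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            biotype = "protein_coding" if g.biotype == "coding" else "lncRNA"
            fh.write(
                f"{g.chrom}\timprintscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={biotype}\n"
            )


# ---------------------------------------------------------------------------
# BED output


def write_bed(intervals: Sequence, path: str | Path) -> None:
    """Write intervals (objects with chrom/start/end, 1-based inclusive) as
    0-based half-open BED. ``name`` and ``score`` columns are filled from a
    ``bed_name()`` / ``bed_score()`` method or ``name``/``score`` attribute
    when available. Intervals are written verbatim — no merging or sorting.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.bed_name() if hasattr(iv, "bed_name") else getattr(iv, "name", ".")
            score = iv.bed_score() if hasattr(iv, "bed_score") else getattr(iv, "score", ".")
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\n")
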