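"""Synthetic reciprocal-cross allele counts and embryo/endosperm methylomes
with planted ground truth.

The generator emulates the study design end-to-end so every pipeline stage
is testable without external downloads: two reciprocal cross pairs of
hybrid endosperm samples with per-SNP base counts around the triploid 2:1
maternal:paternal baseline, planted MEGs/PEGs at extreme allelic fractions,
negative-binomial sequencing depth with a 1% base-error rate, and paired
embryo/endosperm bisulfite methylomes with CG-hypomethylated-in-endosperm
regions planted at the 5' ends of a fraction of the planted PEGs.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical config + seed reproduces identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imprinting_stats import Status
from .io_formats import (
    GeneModel,
    SnpRecord,
    write_base_counts,
    write_cytosine_report,
    write_gff3_genes,
    write_snp_table,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AseConfig:
    """Parameters of the allele-specific-expression generator.

    Defaults mirror the study conditions: a 2:1 maternal:paternal baseline
    for biallelic genes, imprinted genes at maternal fractions 0.95 (MEG)
    and 0.10 (PEG) — beyond the 10/11 and 1 - 5/7 high-stringency cutoffs
    in expectation — negative-binomial total depth (mean 100, dispersion
    0.3) to stress low-count behaviour, 1-8 informative SNPs per gene, 2%
    noncoding transcripts, and two reciprocal cross pairs.
    """

    n_genes: int = 1000
    frac_meg: float = 0.05
    frac_peg: float = 0.10
    frac_noncoding: float = 0.02
    depth_mean: float = 100.0
    depth_dispersion: float = 0.3
    meg_maternal_fraction: float = 0.95
    peg_maternal_fraction: float = 0.10
    base_error: float = 0.01
    min_snps: int = 1
    max_snps: int = 8
    genes_per_chrom: int = 60
    gene_length: tuple[int, int] = (1000, 3000)
    intergenic_gap: tuple[int, int] = (1000, 4000)
    n_pairs: int = 2

    def __post_init__(self) -> None:
        if self.frac_meg + self.frac_peg > 1:
            raise ValueError("frac_meg + frac_peg must be <= 1")
        for name in ("frac_meg", "frac_peg", "frac_noncoding"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class MethylomeConfig:
    """Parameters of the bisulfite methylome generator.

    Baseline weighted levels default to the embryo bulk values the ASE
    study design targets (CG 0.84, CHG 0.68, CHH 0.05 — plant-typical).
    Site-to-site variation is Beta-distributed around the baseline with the
    underlying level shared between tissues, so unplanted regions are null
    by construction. Planted endosperm-hypo regions drop the endosperm CG
    level by ``hypo_delta`` (> 0.30 so the DMR difference filter can fire).
    """

    chrom_length: int = 300_000
    site_rates: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 1 / 20, "CHG": 1 / 25, "CHH": 1 / 8}
    )
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.84, "CHG": 0.68, "CHH": 0.05}
    )
    depth: float = 10.0
    site_concentration: float = 50.0
    hypo_delta: float = 0.5
    region_length: int = 600
    linked_peg_fraction: float = 0.25
    n_random_regions: int = 0


@dataclass
class SyntheticAse:
    """Generated reciprocal-cross dataset with its planted truth."""

    config: AseConfig
    seed: int
    genes: list[GeneModel]
    snps: list[SnpRecord]
    #: sample_id -> per-SNP base-count table (chrom,pos,count_A..count_T)
    base_counts: dict[str, pd.DataFrame]
    #: sample_id -> which parent line ("A"/"B") is maternal in that sample
    orientations: dict[str, str]
    #: (forward_sample, reciprocal_sample) per cross pair
    pairs: list[tuple[str, str]]
    #: gene_id, biotype, true_status, true_maternal_fraction, expected_call
    truth: pd.DataFrame


@dataclass
class SyntheticMethylome:
    config: MethylomeConfig
    seed: int
    embryo: pd.DataFrame
    endosperm: pd.DataFrame
    #: planted endosperm-hypo regions: chrom, start, end, linked_gene
    regions: pd.DataFrame


def _expected_call(status: str, biotype: str) -> str:
    if status == "MEG":
        return Status.MNC.value if biotype == "noncoding" else Status.MEG.value
    if status == "PEG":
        return Status.PNC.value if biotype == "noncoding" else Status.PEG.value
    return Status.BIALLELIC.value


def generate_gene_models(config: AseConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Genes laid head-to-tail with random lengths and intergenic gaps,
    ``genes_per_chrom`` per chromosome."""
    genes: list[GeneModel] = []
    n_chroms = -(-config.n_genes // config.genes_per_chrom)
    gene_idx = 0
    for c in range(n_chroms):
        chrom = f"Chr{c + 1:02d}"
        cursor = 1
        for _ in range(min(config.genes_per_chrom, config.n_genes - gene_idx)):
            cursor += int(rng.integers(*config.intergenic_gap, endpoint=True))
            length = int(rng.integers(*config.gene_length, endpoint=True))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_idx + 1:05d}",
                    chrom=chrom,
                    start=cursor,
                    end=cursor + length - 1,
                    strand=strand,
                    biotype="coding",  # biotype assigned later
                )
            )
            cursor += length
            gene_idx += 1
    return genes


def generate_ase(config: AseConfig = AseConfig(), seed: int = 0) -> SyntheticAse:
    """Generate SNPs, per-sample base counts, gene models, and truth.

    Per gene: a true status (MEG/PEG/biallelic by ``frac_meg``/``frac_peg``)
    sets the true maternal read fraction f (0.95 / 0.10 / 2/3). Per SNP per
    sample: total depth ~ NB(mean, dispersion); error reads ~
    Binomial(depth, base_error) land on the two non-parental bases;
    maternal reads ~ Binomial(depth - errors, f); reciprocal samples swap
    which parental line receives the maternal reads.
    """
    rng = np.random.default_rng(seed)
    genes = generate_gene_models(config, rng)
    n = len(genes)

    status = np.full(n, "biallelic", dtype=object)
    u = rng.random(n)
    status[u < config.frac_meg] = "MEG"
    status[(u >= config.frac_meg) & (u < config.frac_meg + config.frac_peg)] = "PEG"
    noncoding = rng.random(n) < config.frac_noncoding
    genes = [
        dataclasses.replace(g, biotype="noncoding" if nc else "coding")
        for g, nc in zip(genes, noncoding)
    ]
    true_f = np.where(
        status == "MEG",
        config.meg_maternal_fraction,
        np.where(status == "PEG", config.peg_maternal_fraction, 2 / 3),
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "biotype": [g.biotype for g in genes],
            "true_status": status,
            "true_maternal_fraction": true_f,
            "expected_call": [
                _expected_call(s, g.biotype) for s, g in zip(status, genes)
            ],
        }
    )

    # SNPs: 1-8 per gene, distinct parental alleles, genomic depth > 3
    snps: list[SnpRecord] = []
    snp_gene_idx: list[int] = []
    for i, g in enumerate(genes):
        k = int(rng.integers(config.min_snps, config.max_snps, endpoint=True))
        k = min(k, g.end - g.start + 1)
        positions = np.sort(rng.choice(np.arange(g.start, g.end + 1), size=k, replace=False))
        for pos in positions:
            a, b = rng.choice(4, size=2, replace=False)
            snps.append(
                SnpRecord(g.chrom, int(pos), str(BASES[a]), str(BASES[b]),
                          int(rng.integers(10, 100)))
            )
            snp_gene_idx.append(i)
    snp_gene_idx = np.asarray(snp_gene_idx)
    n_snps = len(snps)

    sample_names = []
    orientations: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for p in range(config.n_pairs):
        fwd, rev = f"SY{p + 1}", f"YS{p + 1}"
        sample_names += [fwd, rev]
        orientations[fwd] = "A"
        orientations[rev] = "B"
        pairs.append((fwd, rev))

    # NB depth parameterised by mean m and dispersion a: var = m + a m^2
    r = 1.0 / config.depth_dispersion
    p_nb = r / (r + config.depth_mean)
    snp_f = true_f[snp_gene_idx]
    base_idx = {b: i for i, b in enumerate("ACGT")}
    allele_a_idx = np.array([base_idx[s.allele_a] for s in snps])
    allele_b_idx = np.array([base_idx[s.allele_b] for s in snps])
    chroms = np.array([s.chrom for s in snps])
    positions = np.array([s.pos for s in snps])

    base_counts: dict[str, pd.DataFrame] = {}
    for sample in sample_names:
        depth = rng.negative_binomial(r, p_nb, size=n_snps)
        errors = rng.binomial(depth, config.base_error)
        assignable = depth - errors
        maternal = rng.binomial(assignable, snp_f)
        paternal = assignable - maternal
        err_split = rng.binomial(errors, 0.5)
        counts = np.zeros((n_snps, 4), dtype=np.int64)
        rows = np.arange(n_snps)
        if orientations[sample] == "A":
            m_idx, p_idx = allele_a_idx, allele_b_idx
        else:
            m_idx, p_idx = allele_b_idx, allele_a_idx
        np.add.at(counts, (rows, m_idx), maternal)
        np.add.at(counts, (rows, p_idx), paternal)
        # errors fall on the two non-parental bases
        other = np.array(
            [[i for i in range(4) if i != a and i != b] for a, b in zip(allele_a_idx, allele_b_idx)]
        )
        np.add.at(counts, (rows, other[:, 0]), err_split)
        np.add.at(counts, (rows, other[:, 1]), errors - err_split)
        base_counts[sample] = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "count_A": counts[:, 0],
                "count_C": counts[:, 1],
                "count_G": counts[:, 2],
                "count_T": counts[:, 3],
            }
        )

    return SyntheticAse(config, seed, genes, snps, base_counts, orientations, pairs, truth)


def _plant_regions(
    config: MethylomeConfig,
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    gene_models: Sequence[GeneModel] | None,
    peg_gene_ids: Sequence[str] | None,
) -> pd.DataFrame:
    rows = []
    if gene_models is not None and peg_gene_ids:
        by_id = {g.gene_id: g for g in gene_models}
        pegs = [gid for gid in peg_gene_ids if gid in by_id]
        chosen = [gid for gid in pegs if rng.random() < config.linked_peg_fraction]
        for gid in chosen:
            g = by_id[gid]
            # region over the 5' end of the gene, extending 200 bp into the flank
            if g.strand == "+":
                start = max(1, g.start - 200)
                end = start + config.region_length - 1
            else:
                end = min(chrom_lengths[g.chrom], g.end + 200)
                start = max(1, end - config.region_length + 1)
            rows.append((g.chrom, start, end, gid))
    for i in range(config.n_random_regions):
        chrom = sorted(chrom_lengths)[i % len(chrom_lengths)]
        # spaced deterministically apart so random regions never overlap
        slot = 5 * config.region_length
        n_slots = max(1, chrom_lengths[chrom] // slot - 1)
        start = (i // len(chrom_lengths)) % n_slots * slot + int(rng.integers(1, slot - config.region_length))
        rows.append((chrom, start, start + config.region_length - 1, ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "linked_gene"])


def generate_methylome(
    config: MethylomeConfig = MethylomeConfig(),
    seed: int = 0,
    gene_models: Sequence[GeneModel] | None = None,
    peg_gene_ids: Sequence[str] | None = None,
) -> SyntheticMethylome:
    """Generate paired embryo/endosperm cytosine reports.

    Sites are laid down per context with geometric inter-site gaps at
    ``site_rates``. Each site draws a latent methylation level from a Beta
    distribution centred on the context baseline, *shared* between the two
    tissues (so unplanted regions carry no systematic difference); read
    depth is Poisson(``depth``) per tissue and methylated counts are
    Binomial(depth, level). Inside planted regions the endosperm CG latent
    level is reduced by ``hypo_delta``. Regions are planted at the 5' ends
    of a ``linked_peg_fraction`` of the supplied PEGs, or at
    ``n_random_regions`` deterministic slots when no genes are supplied.
    """
    rng = np.random.default_rng(seed)
    if gene_models is not None:
        chrom_lengths: dict[str, int] = {}
        for g in gene_models:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end + 5000)
    else:
        chrom_lengths = {"Chr01": config.chrom_length}

    regions = _plant_regions(config, rng, chrom_lengths, gene_models, peg_gene_ids)

    frames_emb, frames_endo = [], []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        chrom_regions = regions[regions["chrom"] == chrom]
        for context, rate in config.site_rates.items():
            n_expect = int(length * rate * 1.3) + 10
            gaps = rng.geometric(rate, size=n_expect)
            pos = np.cumsum(gaps)
            pos = pos[pos <= length]
            base = config.baseline[context]
            conc = config.site_concentration
            level = rng.beta(base * conc, (1 - base) * conc, size=pos.size)
            level_endo = level.copy()
            if context == "CG" and len(chrom_regions):
                in_region = np.zeros(pos.size, dtype=bool)
                for _, r in chrom_regions.iterrows():
                    in_region |= (pos >= r["start"]) & (pos <= r["end"])
                level_endo[in_region] = np.clip(level_endo[in_region] - config.hypo_delta, 0.02, 1.0)
            strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
            for frames, lv in ((frames_emb, level), (frames_endo, level_endo)):
                depth = rng.poisson(config.depth, size=pos.size)
                meth = rng.binomial(depth, lv)
                keep = depth > 0
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos[keep],
                            "strand": strand[keep],
                            "context": context,
                            "meth": meth[keep],
                            "unmeth": (depth - meth)[keep],
                        }
                    )
                )

    embryo = pd.concat(frames_emb, ignore_index=True).sort_values(
        ["chrom", "pos"], kind="stable", ignore_index=True
    )
    endosperm = pd.concat(frames_endo, ignore_index=True).sort_values(
        ["chrom", "pos"], kind="stable", ignore_index=True
    )
    return SyntheticMethylome(config, seed, embryo, endosperm, regions)


# ---------------------------------------------------------------------------
# Auxiliary tables for the downstream syntheses


#: Analyzable homolog counts and low-stringency concordance per species and
#: foreign status, mirroring the cross-species comparison design.
DEFAULT_SPECIES_SPECS: dict[tuple[str, str], tuple[int, float]] = {
    ("A_thaliana", "MEG"): (191, 0.162),
    ("A_thaliana", "PEG"): (51, 0.275),
    ("maize", "MEG"): (39, 0.154),
    ("maize", "PEG"): (147, 0.238),
}


def generate_homolog_table(
    statuses: Mapping[str, Status],
    seed: int = 0,
    species_specs: Mapping[tuple[str, str], tuple[int, float]] = DEFAULT_SPECIES_SPECS,
    frac_unanalyzable: float = 0.25,
) -> pd.DataFrame:
    """Map foreign imprinted genes onto local genes with configured
    concordance. Concordant rows target local genes called in the matching
    parental direction; discordant rows target analyzable genes without
    that bias; a further ``frac_unanalyzable`` of rows per species target
    local ids absent from the calls, which downstream counts as
    non-analyzable (they do not enter the denominators). Targets are
    sampled with replacement — the ratios are scale-free.
    """
    rng = np.random.default_rng(seed)
    maternal = [g for g, s in statuses.items() if s in {Status.MEG, Status.MNC, Status.LOW_MEG}]
    paternal = [g for g, s in statuses.items() if s in {Status.PEG, Status.PNC, Status.LOW_PEG}]
    biallelic = [g for g, s in statuses.items() if s is Status.BIALLELIC]
    rows = []
    counter = 0
    for (species, f_status), (n_analyzable, conc) in species_specs.items():
        pool = maternal if f_status == "MEG" else paternal
        n_conc = round(n_analyzable * conc)
        n_extra = round(n_analyzable * frac_unanalyzable / (1 - frac_unanalyzable))
        targets = (
            list(rng.choice(pool, size=n_conc))
            + list(rng.choice(biallelic, size=n_analyzable - n_conc))
            + [f"unmapped_{species}_{i}" for i in range(n_extra)]
        )
        for t in targets:
            counter += 1
            rows.append((species, f"{species}_g{counter:04d}", f_status, t))
    return pd.DataFrame(rows, columns=["species", "foreign_gene_id", "foreign_status", "local_gene_id"])


def generate_fpkm_matrix(
    truth: pd.DataFrame,
    seed: int = 0,
    tissues: Sequence[str] = ("endosperm", "pistil", "stamen", "ligule", "leaf", "root", "seed"),
    endo_specific_frac: Mapping[str, float] = None,
) -> pd.DataFrame:
    """FPKM matrix across tissues with a planted endosperm-specific subset.

    Endosperm-specific genes express high in endosperm and near-zero
    elsewhere; constitutive genes express comparably everywhere. The
    fraction of endosperm-specific genes per true status defaults to 0.62
    for MEGs, 0.39 for PEGs and 0.10 for the rest.
    """
    if endo_specific_frac is None:
        endo_specific_frac = {"MEG": 0.62, "PEG": 0.39, "biallelic": 0.10}
    rng = np.random.default_rng(seed)
    n = len(truth)
    fracs = truth["true_status"].map(endo_specific_frac).fillna(0.1).to_numpy()
    specific = rng.random(n) < fracs
    others = [t for t in tissues if t != "endosperm"]
    data = {}
    endo = rng.lognormal(mean=3.0, sigma=0.7, size=n)
    data["endosperm"] = np.maximum(endo, 1.5)
    for t in others:
        constitutive = rng.lognormal(mean=2.5, sigma=0.8, size=n)
        low = rng.uniform(0, 0.2, size=n) * data["endosperm"] / 4
        data[t] = np.where(specific, low, constitutive)
    return pd.DataFrame(data, index=pd.Index(truth["gene_id"], name="gene_id"))


# ---------------------------------------------------------------------------
# Serialisation


def write_ase_dataset(ase: SyntheticAse, outdir: str | Path) -> dict[str, str]:
    """Write the generated dataset in the formats the readers consume.

    Returns a manifest mapping of logical names to file paths; the truth
    table and the generator parameters are serialised alongside so every
    stage can be scored without re-reading configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    write_snp_table(ase.snps, outdir / "snps.tsv")
    files["snps"] = str(outdir / "snps.tsv")
    write_gff3_genes(ase.genes, outdir / "genes.gff3")
    files["genes"] = str(outdir / "genes.gff3")
    for sample, df in ase.base_counts.items():
        path = outdir / f"counts_{sample}.tsv"
        write_base_counts(df, path)
        files[f"counts_{sample}"] = str(path)
    ase.truth.to_csv(outdir / "truth_ase.tsv", sep="\t", index=False)
    files["truth"] = str(outdir / "truth_ase.tsv")
    meta = {
        "seed": ase.seed,
        "config": dataclasses.asdict(ase.config),
        "orientations": ase.orientations,
        "pairs": ase.pairs,
    }
    (outdir / "ase_params.json").write_text(json.dumps(meta, indent=2))
    files["params"] = str(outdir / "ase_params.json")
    return files


def write_methylome_dataset(meth: SyntheticMethylome, outdir: str | Path) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    write_cytosine_report(meth.embryo, outdir / "embryo.cx.tsv")
    write_cytosine_report(meth.endosperm, outdir / "endosperm.cx.tsv")
    meth.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    files["embryo"] = str(outdir / "embryo.cx.tsv")
    files["endosperm"] = str(outdir / "endosperm.cx.tsv")
    files["truth_regions"] = str(outdir / "truth_regions.tsv")
    cfg = dataclasses.asdict(meth.config)
    cfg["site_rates"] = dict(cfg["site_rates"])
    cfg["baseline"] = dict(cfg["baseline"])
    (outdir / "methylome_params.json").write_text(json.dumps({"seed": meth.seed, "config": cfg}, indent=2))
    files["params"] = str(outdir / "methylome_params.json")
    return files
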