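import math

import numpy as np
import pandas as pd
import pytest

from imprintscan.dmr_calling import Dmr, MethWindow
from imprintscan.imprint_epigenetics import (
    association_test,
    conservation_ratios,
    contamination_report,
    gene_dmr_overlap,
    tissue_specificity,
)
from imprintscan.imprinting_stats import Status
from tests.conftest import make_gene


def dmr(start, end, direction="endosperm_hypo", chrom="Chr01"):
    return Dmr(chrom, start, end, "CG", direction, 1, 1e-6)


class TestGeneDmrOverlap:
    def test_dmr_within_flank_overlaps(self):
        gene = make_gene("g", 10_000, 12_000)
        flags = gene_dmr_overlap([gene], [dmr(12_500, 12_700)])
        assert flags.loc["g", "endosperm_hypo"]

    def test_dmr_just_beyond_flank_does_not(self):
        gene = make_gene("g", 10_000, 12_000)
        # flank is strict: 2001 bp upstream of the gene start misses
        flags = gene_dmr_overlap([gene], [dmr(7_000, 7_999)])
        assert not flags.loc["g", "endosperm_hypo"]
        # while touching the flank edge at start-2000 hits
        flags = gene_dmr_overlap([gene], [dmr(7_000, 8_000)])
        assert bool(flags.loc["g", "endosperm_hypo"])

    def test_directions_flagged_independently(self):
        gene = make_gene("g", 10_000, 12_000)
        flags = gene_dmr_overlap([gene], [dmr(11_000, 11_200, "embryo_hypo")])
        assert flags.loc["g", "embryo_hypo"] and not flags.loc["g", "endosperm_hypo"]

    def test_assessable_requires_tested_region(self):
        genes = [make_gene("g1", 10_000, 12_000), make_gene("g2", 50_000, 52_000)]
        assessed = [MethWindow("Chr01", 11_000, 11_199, "CG", 5, 5, 5, 5, 1.0)]
        flags = gene_dmr_overlap(genes, [], assessed_regions=assessed)
        assert bool(flags.loc["g1", "assessable"]) and not flags.loc["g2", "assessable"]

    def test_matches_all_pairs_oracle(self, rng):
        genes = [
            make_gene(f"g{i}", int(s), int(s) + int(rng.integers(500, 3000)))
            for i, s in enumerate(rng.choice(np.arange(1, 500_000, 100), 100, replace=False))
        ]
        dmrs = [
            dmr(int(s), int(s) + int(rng.integers(100, 2000)))
            for s in rng.choice(np.arange(1, 500_000, 50), 100, replace=False)
        ]
        flags = gene_dmr_overlap(genes, dmrs, flank=2000)
        for g in genes:
            expected = any(
                d.start <= g.end + 2000 and d.end >= g.start - 2000 for d in dmrs
            )
            assert bool(flags.loc[g.gene_id, "endosperm_hypo"]) == expected


def hypergeom_p_oracle(a, b, c, d):
    n1, m1, N = a + b, a + c, a + b + c + d

    def prob(k):
        return math.comb(m1, k) * math.comb(N - m1, n1 - k) / math.comb(N, n1)

    p_obs = prob(a)
    return min(
        sum(prob(k) for k in range(max(0, n1 + m1 - N), min(n1, m1) + 1)
            if prob(k) <= p_obs * (1 + 1e-7)),
        1.0,
    )


class TestAssociationTest:
    def _flags(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "endosperm_hypo", "embryo_hypo", "assessable"]
        ).set_index("gene_id")

    def test_counts_fill_the_table(self):
        # 2 of 10 imprinted genes carry an endosperm-hypo DMR
        rows = [(f"m{i}", i < 2, False, True) for i in range(10)]
        rows += [(f"b{i}", i < 1, False, True) for i in range(20)]
        statuses = {f"m{i}": Status.MEG for i in range(10)}
        statuses |= {f"b{i}": Status.BIALLELIC for i in range(20)}
        table = association_test(self._flags(rows), statuses)
        assert table.table == [[2, 8], [1, 19]]

    def test_unassessable_and_non_analyzed_excluded(self):
        rows = [("m0", True, False, True), ("m1", True, False, False),
                ("b0", False, False, True), ("x0", True, False, True)]
        statuses = {"m0": Status.PEG, "m1": Status.PEG, "b0": Status.BIALLELIC,
                    "x0": Status.NON_ANALYZED}
        table = association_test(self._flags(rows), statuses)
        assert table.table == [[1, 0], [0, 1]]

    def test_zero_overlap_rows_give_p_one(self):
        rows = [("m0", False, False, True), ("b0", False, False, True)]
        statuses = {"m0": Status.MEG, "b0": Status.BIALLELIC}
        table = association_test(self._flags(rows), statuses)
        assert table.p_value == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        rows = [("b0", False, False, True)]
        with pytest.raises(ValueError):
            association_test(self._flags(rows), {"b0": Status.BIALLELIC})

    def test_p_matches_hypergeometric_oracle(self):
        rows = [(f"m{i}", i < 56, False, True) for i in range(56 + 167)]
        rows += [(f"b{i}", i < 100, False, True) for i in range(9100)]
        statuses = {f"m{i}": Status.PEG for i in range(56 + 167)}
        statuses |= {f"b{i}": Status.BIALLELIC for i in range(9100)}
        table = association_test(self._flags(rows), statuses)
        assert table.table == [[56, 167], [100, 9000]]
        assert table.p_value == pytest.approx(hypergeom_p_oracle(56, 167, 100, 9000), rel=1e-6)

    def test_small_table_exact_p(self):
        rows = [("m0", True, False, True), ("m1", True, False, True),
                ("b0", False, False, True), ("b1", False, False, True)]
        statuses = {"m0": Status.MEG, "m1": Status.MEG,
                    "b0": Status.BIALLELIC, "b1": Status.BIALLELIC}
        table = association_test(self._flags(rows), statuses)
        assert table.p_value == pytest.approx(1 / 3)


HOMOLOGS = pd.DataFrame(
    {
        "species": ["sp1"] * 4 + ["sp2"] * 3,
        "foreign_gene_id": [f"f{i}" for i in range(7)],
        "foreign_status": ["MEG", "MEG", "MEG", "PEG", "PEG", "PEG", "PEG"],
        "local_gene_id": ["meg1", "low_meg1", "bial1", "peg1", "peg1", "bial1", "absent"],
    }
)

STATUSES = {
    "meg1": Status.MEG,
    "low_meg1": Status.LOW_MEG,
    "bial1": Status.BIALLELIC,
    "peg1": Status.PEG,
}


class TestConservationRatios:
    def test_counts_and_percentages(self):
        by_key = {(s.species, s.foreign_status): s for s in conservation_ratios(HOMOLOGS, STATUSES)}
        meg = by_key[("sp1", "MEG")]
        # low-stringency concordance counts low_MEG; high-stringency only MEG
        assert (meg.n_analyzable, meg.n_concordant_low, meg.n_concordant_high) == (3, 2, 1)
        assert meg.pct_low == pytest.approx(100 * 2 / 3)
        peg1 = by_key[("sp1", "PEG")]
        assert (peg1.n_analyzable, peg1.n_concordant_low) == (1, 1)
        peg2 = by_key[("sp2", "PEG")]
        # the homolog absent from the calls is not analyzable
        assert (peg2.n_homologs, peg2.n_analyzable, peg2.n_concordant_low) == (3, 2, 1)

    def test_published_style_arithmetic(self):
        table = pd.DataFrame(
            {
                "species": "At",
                "foreign_gene_id": [f"f{i}" for i in range(191)],
                "foreign_status": "MEG",
                "local_gene_id": ["meg1"] * 31 + ["bial1"] * 160,
            }
        )
        (s,) = conservation_ratios(table, STATUSES)
        assert s.pct_low == pytest.approx(16.2, abs=0.05)

    def test_zero_concordance(self):
        table = HOMOLOGS.assign(local_gene_id="bial1")
        for s in conservation_ratios(table, STATUSES):
            assert s.pct_low == 0.0

    def test_duplicating_rows_preserves_percentages(self):
        once = conservation_ratios(HOMOLOGS, STATUSES)
        twice = conservation_ratios(pd.concat([HOMOLOGS, HOMOLOGS]), STATUSES)
        for a, b in zip(once, twice):
            assert a.pct_low == pytest.approx(b.pct_low, nan_ok=True)
            assert b.n_analyzable == 2 * a.n_analyzable


FPKM = pd.DataFrame(
    {
        "endosperm": [40.0, 40.0, 0.2, 8.0],
        "leaf": [2.0, 39.0, 0.1, 1.0],
        "root": [1.0, 10.0, 0.0, 2.0],
    },
    index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
)


class TestTissueSpecificity:
    def test_fourfold_rule(self):
        labels = tissue_specificity(FPKM, ["a", "b", "c", "d"])
        assert labels["a"] == "endo_specific"   # 40 >= 4 * 2
        assert labels["b"] == "constitutive"    # 40 < 4 * 39
        assert labels["c"] == "constitutive"    # below min FPKM
        assert labels["d"] == "endo_specific"   # 8 >= 4 * 2

    def test_labels_partition_genes_with_data(self):
        labels = tissue_specificity(FPKM, ["a", "b", "missing"])
        assert len(labels) == 2
        assert set(labels.unique()) <= {"endo_specific", "constitutive"}

    def test_missing_endosperm_column_rejected(self):
        with pytest.raises(ValueError):
            tissue_specificity(FPKM.drop(columns="endosperm"), ["a"])


def test_contamination_report_flags_clean_markers():
    report = contamination_report(FPKM, ["c", "a", "unknown"])
    assert bool(report.loc["c", "clean"])       # 0.5 threshold is strict
    assert not report.loc["a", "clean"]
    assert not report.loc["unknown", "clean"]
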