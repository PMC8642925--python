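import numpy as np
import pytest

from imprintscan.genome_clustering import (
    cluster_size_distribution,
    find_clusters,
    spacing_stats,
)
from imprintscan.imprinting_stats import IMPRINTED_STATUSES, Status
from tests.conftest import make_gene


def random_genome(rng, n_genes=50, chrom_span=3_000_000, n_chroms=2):
    """Random gene models with distinct starts plus random statuses."""
    genes, statuses = [], {}
    status_pool = [Status.MEG, Status.PEG, Status.MNC, Status.PNC,
                   Status.BIALLELIC, Status.LOW_MEG, Status.NON_ANALYZED]
    weights = np.array([0.15, 0.2, 0.03, 0.03, 0.25, 0.09, 0.25])
    for c in range(n_chroms):
        k = n_genes // n_chroms
        starts = np.sort(rng.choice(np.arange(1, chrom_span, 1000), size=k, replace=False))
        for i, s in enumerate(starts):
            gid = f"c{c}g{i}"
            genes.append(make_gene(gid, int(s), int(s) + int(rng.integers(200, 900)), chrom=f"Chr{c}"))
            statuses[gid] = status_pool[rng.choice(len(status_pool), p=weights)]
    return genes, statuses


def oracle_clusters(statuses, genes, max_span=1_000_000):
    """Enumerate all maximal valid contiguous member runs per chromosome.

    A run imp[i..j] is valid iff every consecutive start-to-start gap is at
    most max_span and no analyzed non-imprinted gene starts strictly
    between the first and last member. Maximal valid runs of length >= 2
    are the clusters.
    """
    out = []
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        chrom_genes = sorted(chrom_genes, key=lambda g: g.start)
        imp = [g for g in chrom_genes
               if statuses.get(g.gene_id, Status.NON_ANALYZED) in IMPRINTED_STATUSES]
        blockers = [g.start for g in chrom_genes
                    if statuses.get(g.gene_id, Status.NON_ANALYZED) not in IMPRINTED_STATUSES
                    and statuses.get(g.gene_id, Status.NON_ANALYZED) is not Status.NON_ANALYZED]

        def valid(i, j):
            for k in range(i, j):
                if imp[k + 1].start - imp[k].start > max_span:
                    return False
            return not any(imp[i].start < b < imp[j].start for b in blockers)

        n = len(imp)
        for i in range(n):
            for j in range(i + 1, n):
                if valid(i, j) and not (i > 0 and valid(i - 1, j)) and not (
                    j < n - 1 and valid(i, j + 1)
                ):
                    out.append(tuple(g.gene_id for g in imp[i : j + 1]))
    return sorted(out)


class TestFindClusters:
    def test_non_analyzed_genes_do_not_break_chains(self):
        genes = [
            make_gene("p1", 1, 1000),
            make_gene("x1", 10_000, 11_000),
            make_gene("p2", 25_001, 26_000),
            make_gene("x2", 40_000, 41_000),
            make_gene("p3", 50_001, 51_000),
        ]
        statuses = {"p1": Status.PEG, "p2": Status.PEG, "p3": Status.PEG,
                    "x1": Status.NON_ANALYZED, "x2": Status.NON_ANALYZED}
        (cluster,) = find_clusters(statuses, genes)
        assert cluster.members == ("p1", "p2", "p3")
        assert (cluster.start, cluster.end) == (1, 51_000)
        assert cluster.n_peg == 3

    def test_analyzed_biallelic_gene_breaks_chain(self):
        genes = [
            make_gene("p1", 1, 1000),
            make_gene("p2", 25_001, 26_000),
            make_gene("bi", 30_000, 31_000),
            make_gene("p3", 50_001, 51_000),
        ]
        statuses = {"p1": Status.PEG, "p2": Status.PEG, "p3": Status.PEG,
                    "bi": Status.BIALLELIC}
        (cluster,) = find_clusters(statuses, genes)  # the singleton {p3} is not reported
        assert cluster.members == ("p1", "p2")

    def test_gap_over_max_span_breaks_chain(self):
        genes = [make_gene("p1", 1, 1000), make_gene("p2", 1_200_001, 1_201_000)]
        statuses = {"p1": Status.PEG, "p2": Status.PEG}
        assert find_clusters(statuses, genes) == []

    def test_mixed_parental_direction_clusters_allowed(self):
        genes = [make_gene("m", 1, 1000), make_gene("p", 5000, 6000)]
        statuses = {"m": Status.MEG, "p": Status.PEG}
        (cluster,) = find_clusters(statuses, genes)
        assert (cluster.n_meg, cluster.n_peg) == (1, 1)

    def test_unsorted_input_rejected(self):
        genes = [make_gene("a", 5000, 6000), make_gene("b", 1, 1000)]
        with pytest.raises(ValueError, match="sorted"):
            find_clusters({}, genes)

    def test_matches_exhaustive_oracle_on_random_genomes(self, rng):
        for _ in range(30):
            genes, statuses = random_genome(rng)
            found = sorted(c.members for c in find_clusters(statuses, genes))
            assert found == oracle_clusters(statuses, genes)

    def test_clusters_disjoint_and_members_imprinted(self, rng):
        for _ in range(10):
            genes, statuses = random_genome(rng)
            clusters = find_clusters(statuses, genes)
            seen = set()
            for c in clusters:
                assert c.size >= 2
                for m in c.members:
                    assert m not in seen
                    assert statuses[m] in IMPRINTED_STATUSES
                    seen.add(m)

    def test_strict_total_span_caps_chain(self):
        # consecutive gaps of 0.6 Mb chain under the pairwise rule but the
        # strict variant splits once the total span passes 1 Mb
        genes = [make_gene(f"p{i}", 1 + i * 600_000, 1000 + i * 600_000) for i in range(3)]
        statuses = {g.gene_id: Status.PEG for g in genes}
        (chained,) = find_clusters(statuses, genes)
        assert chained.size == 3
        strict = find_clusters(statuses, genes, strict_total_span=True)
        assert [c.size for c in strict] == [2]


class TestSpacingStats:
    def test_two_transcripts(self):
        genes = [make_gene("a", 1_000_000, 1_001_000), make_gene("b", 3_000_000, 3_001_000)]
        statuses = {"a": Status.MEG, "b": Status.PEG}
        mean, distances = spacing_stats(statuses, genes)
        assert mean == pytest.approx(2_000_000)
        assert list(distances) == [2_000_000]

    def test_single_transcript_chromosome_contributes_nothing(self):
        genes = [make_gene("a", 10, 20, chrom="Chr01"), make_gene("b", 10, 20, chrom="Chr02")]
        statuses = {"a": Status.MEG, "b": Status.MEG}
        mean, distances = spacing_stats(statuses, genes)
        assert distances.size == 0 and np.isnan(mean)

    def test_matches_sort_and_diff_oracle(self, rng):
        genes, statuses = random_genome(rng)
        _, distances = spacing_stats(statuses, genes)
        expected = []
        for chrom in sorted({g.chrom for g in genes}):
            starts = sorted(
                g.start for g in genes
                if g.chrom == chrom and statuses[g.gene_id] in IMPRINTED_STATUSES
            )
            expected.extend(np.diff(starts))
        assert sorted(distances) == sorted(expected)


class TestClusterSizeDistribution:
    def test_published_style_composition(self):
        # 65 two-gene, 15 three-gene and 5 four-gene clusters
        sizes = [2] * 65 + [3] * 15 + [4] * 5
        summary = cluster_size_distribution(sizes)
        assert summary.proportions[2] == pytest.approx(0.765, abs=5e-4)
        assert summary.proportions[3] == pytest.approx(0.176, abs=5e-4)
        assert summary.proportions[4] == pytest.approx(0.059, abs=5e-4)
        assert summary.total_members == 195

    def test_single_cluster(self):
        summary = cluster_size_distribution([2])
        assert summary.proportions == {2: 1.0}

    def test_empty(self):
        assert cluster_size_distribution([]).proportions == {}

    def test_member_conservation(self, rng):
        genes, statuses = random_genome(rng)
        clusters = find_clusters(statuses, genes)
        summary = cluster_size_distribution(clusters)
        assert summary.total_members == sum(c.size for c in clusters)
        assert sum(k * v for k, v in summary.counts.items()) == summary.total_members
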