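"""Detection calls, Tanimoto similarity, Venn partitioning, tiers, coverage."""

import random
from itertools import combinations

import pytest
from hypothesis import given, strategies as st

import txconcord as tc
from txconcord import concordance as cc
from txconcord.io_tables import ValidationError

ALPHABET = [f"G{i:02d}" for i in range(20)]

gene_sets = st.frozensets(st.sampled_from(ALPHABET))


class TestDetect:
    @pytest.mark.parametrize(
        "cutoff, comparator, expected",
        [
            (0.0, "strictly_greater", {"G2", "G3"}),
            (0.1, "strictly_greater", {"G3"}),
            (0.05, "greater_or_equal", {"G2", "G3"}),
        ],
    )
    def test_threshold_semantics(self, table_factory, cutoff, comparator, expected):
        t = table_factory({"G1": 0.0, "G2": 0.05, "G3": 2.0})
        assert cc.detect(t, cutoff, comparator).genes == frozenset(expected)

    def test_comparator_boundary(self, table_factory):
        t = table_factory({"G1": 1.0})
        assert cc.detect(t, 1.0, "strictly_greater").genes == frozenset()
        assert cc.detect(t, 1.0, "greater_or_equal").genes == {"G1"}

    def test_absent_gene_counts_as_zero(self, table_factory, universe):
        t = table_factory({"G001": 5.0})
        s = cc.detect(t, 0.0, universe=universe)
        assert s.genes == {"G001"}
        s_ge = cc.detect(t, 0.0, "greater_or_equal", universe=universe)
        assert s_ge.genes == frozenset(universe.genes)  # zeros pass >= 0

    def test_universe_restriction(self, table_factory, universe):
        t = table_factory({"G001": 5.0, "NOT_IN_UNIVERSE": 9.0})
        assert cc.detect(t, 0.0, universe=universe).genes == {"G001"}

    def test_negative_cutoff_rejected(self, table_factory):
        with pytest.raises(ValidationError):
            cc.detect(table_factory({"G1": 1.0}), -0.5)

    def test_ge_at_cutoff_matches_gt_below_gap(self, table_factory):
        """With no value in (c', c), >= at c equals > at c'."""
        t = table_factory({"G1": 0.5, "G2": 1.0, "G3": 3.0})
        ge = cc.detect(t, 1.0, "greater_or_equal").genes
        gt = cc.detect(t, 0.7, "strictly_greater").genes
        assert ge == gt


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"G1", "G2"}, {"G1", "G2"}, 1.0),
            ({"G1", "G2"}, {"G3"}, 0.0),
            ({"G1", "G2", "G3"}, {"G2", "G3", "G4"}, 0.5),
            (set(), {"G1"}, 0.0),
            (set(), set(), 1.0),  # conventional value, flagged downstream
        ],
    )
    def test_known_values(self, a, b, expected):
        assert cc.tanimoto(a, b) == expected

    @given(a=gene_sets, b=gene_sets)
    def test_matches_per_element_enumeration(self, a, b):
        inter = sum(1 for g in ALPHABET if g in a and g in b)
        union = sum(1 for g in ALPHABET if g in a or g in b)
        expected = inter / union if union else 1.0
        assert cc.tanimoto(a, b) == expected

    @given(a=gene_sets, b=gene_sets)
    def test_bounds_and_symmetry(self, a, b):
        t = cc.tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == cc.tanimoto(b, a)
        assert cc.tanimoto(a, a) == 1.0


class TestSimilarityBands:
    @pytest.mark.parametrize(
        "t, band",
        [
            (1.0, "identical"),
            (0.7, "identical"),
            (0.75, "identical"),
            (0.69, "weaker"),
            (0.56, "weaker"),
            (0.55, "considerably_different"),
            (0.51, "considerably_different"),
            (0.43, "considerably_different"),
            (0.0, "considerably_different"),
        ],
    )
    def test_band_table(self, t, band):
        assert cc.classify_similarity(t) == band

    @pytest.mark.parametrize("t", [-0.1, 1.0001, 2.0])
    def test_out_of_domain(self, t):
        with pytest.raises(ValueError):
            cc.classify_similarity(t)


def random_family(rng, k):
    platforms = ["short_read", "long_read", "qpcr", "other"][:k]
    return [
        tc.DetectionSet(
            genes=frozenset(rng.sample(ALPHABET, rng.randint(0, len(ALPHABET)))),
            platform=p, sample="S", batch="b1", cutoff=0.0,
        )
        for p in platforms
    ]


class TestVennPartition:
    def test_two_set_example(self, set_factory):
        a = set_factory({"G1", "G2"}, platform="short_read")
        b = set_factory({"G2", "G3"}, platform="long_read")
        v = cc.venn_partition([a, b])
        assert v.region("short_read") == 1
        assert v.region("long_read") == 1
        assert v.region("short_read", "long_read") == 1
        assert v.union_size == 3

    def test_identical_triple(self, set_factory):
        sets = [set_factory({"G1"}, platform=p) for p in ("short_read", "long_read", "qpcr")]
        v = cc.venn_partition(sets)
        assert v.common_all == 1 and v.union_size == 1
        assert sum(v.region_counts.values()) == 1

    def test_empty_sets(self, set_factory):
        sets = [
            set_factory({"G1"}, platform="short_read"),
            set_factory(set(), platform="long_read"),
            set_factory(set(), platform="qpcr"),
        ]
        v = cc.venn_partition(sets)
        assert v.region("short_read") == 1 and v.union_size == 1 and v.common_all == 0

    def test_duplicate_provenance_rejected(self, set_factory):
        a = set_factory({"G1"})
        b = set_factory({"G2"})
        with pytest.raises(ValidationError, match="provenance"):
            cc.venn_partition([a, b])

    @pytest.mark.parametrize("n", [1, 5])
    def test_arity_limits(self, set_factory, n):
        sets = [set_factory({"G1"}, platform="other", sample=f"S{i}") for i in range(n)]
        with pytest.raises(ValidationError):
            cc.venn_partition(sets)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_conservation_and_pairwise_recovery(self, rng, k):
        for _ in range(100):
            sets = random_family(rng, k)
            v = cc.venn_partition(sets)
            assert sum(v.region_counts.values()) == v.union_size
            assert v.common_all == v.region_counts[frozenset(v.labels)]
            for (la, sa), (lb, sb) in combinations(zip(v.labels, sets), 2):
                from_regions = sum(
                    n for subset, n in v.region_counts.items()
                    if la in subset and lb in subset
                )
                assert from_regions == len(sa.genes & sb.genes)


class TestReliabilityTiers:
    def test_direct_count(self, set_factory):
        sets = [
            set_factory({"G1", "G2"}, platform="short_read"),
            set_factory({"G2"}, platform="long_read"),
            set_factory({"G2"}, platform="qpcr"),
        ]
        assert cc.reliability_tiers(sets) == {"G1": 1, "G2": 3}

    def test_identical_sets_all_top_tier(self, set_factory):
        genes = {"G1", "G2", "G3"}
        sets = [set_factory(genes, platform=p) for p in ("short_read", "long_read", "qpcr")]
        assert set(cc.reliability_tiers(sets).values()) == {3}

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_tier_counts_match_region_sizes_by_subset_size(self, rng, k):
        for _ in range(60):
            sets = random_family(rng, k)
            tiers = cc.reliability_tiers(sets)
            v = cc.venn_partition(sets)
            for level in range(1, k + 1):
                n_tier = sum(1 for t in tiers.values() if t == level)
                n_regions = sum(
                    n for subset, n in v.region_counts.items() if len(subset) == level
                )
                assert n_tier == n_regions


class TestPlatformUniqueAndUndetected:
    def test_unique_lists(self, set_factory):
        a = set_factory({"G1", "G2"}, platform="short_read")
        b = set_factory({"G2", "G3"}, platform="long_read")
        assert cc.platform_unique([a, b]) == {"short_read": ["G1"], "long_read": ["G3"]}

    def test_identical_sets_have_no_unique_genes(self, set_factory):
        sets = [set_factory({"G1", "G2"}, platform=p) for p in ("short_read", "long_read")]
        assert all(v == [] for v in cc.platform_unique(sets).values())

    def test_unique_totals_equal_tier_one(self, rng):
        for k in (2, 3, 4):
            sets = random_family(rng, k)
            uniq = cc.platform_unique(sets)
            tiers = cc.reliability_tiers(sets)
            assert sum(map(len, uniq.values())) == sum(1 for t in tiers.values() if t == 1)

    def test_undetected_in_universe_order(self, set_factory):
        universe = tc.GeneUniverse(genes=("G1", "G2", "G3", "G4"))
        a = set_factory({"G1"}, platform="short_read")
        b = set_factory({"G2"}, platform="long_read")
        assert cc.undetected([a, b], universe) == ["G3", "G4"]
        full = set_factory({"G1", "G2", "G3", "G4"}, platform="qpcr")
        assert cc.undetected([a, b, full], universe) == []


class TestCoverage:
    def test_fraction_of_universe(self, set_factory):
        universe = tc.GeneUniverse(genes=tuple(f"G{i}" for i in range(275)))
        covered = set_factory({f"G{i}" for i in range(273)}, platform="short_read")
        assert cc.coverage([covered], universe) == pytest.approx(273 / 275)

    def test_extremes(self, set_factory, universe):
        empty = set_factory(set(), platform="short_read")
        assert cc.coverage([empty], universe) == 0.0
        full = set_factory(set(universe.genes) | {"EXTRA"}, platform="long_read")
        assert cc.coverage([full], universe) == 1.0


class TestSweep:
    def test_detection_sets_nested_in_cutoff(self, rng, universe):
        values = {g: rng.random() * 12 for g in universe}
        tables = [
            tc.ExpressionTable(platform=p, sample="S", batch="b1", unit="RPKM", values=values)
            for p in ("short_read", "long_read")
        ]
        report = tc.sweep(tables, universe, tc.SweepConfig())
        sizes = [r.venn.union_size for r in report.results]
        covs = [r.coverage for r in report.results]
        assert sizes == sorted(sizes, reverse=True)
        assert covs == sorted(covs, reverse=True)

    def test_duplicated_table_gives_unit_tanimoto(self, universe, rng):
        values = {g: rng.random() * 12 for g in universe}
        tables = [
            tc.ExpressionTable(platform=p, sample="S", batch="b1", unit="RPKM", values=values)
            for p in ("short_read", "qpcr")
        ]
        report = tc.sweep(tables, universe, tc.SweepConfig())
        for res in report.results:
            for pair in res.tanimoto:
                assert pair.value == 1.0

    def test_single_table_rejected(self, table_factory, universe):
        with pytest.raises(ValidationError, match="two tables"):
            tc.sweep([table_factory({"G001": 1.0})], universe)

    def test_duplicate_provenance_rejected(self, table_factory, universe):
        tables = [table_factory({"G001": 1.0}), table_factory({"G002": 2.0})]
        with pytest.raises(ValidationError, match="provenance"):
            tc.sweep(tables, universe)


class TestReplicateConcordance:
    def test_identical_batches_fully_concordant(self, table_factory):
        a = table_factory({"G1": 1.0, "G2": 3.0}, batch="2017")
        b = table_factory({"G1": 1.0, "G2": 3.0}, batch="2020")
        rows = tc.replicate_concordance(a, b, tc.SweepConfig(cutoffs=(0.0, 0.1)))
        assert [r.value for r in rows] == [1.0, 1.0]
        assert all(r.band == "identical" for r in rows)

    def test_scaling_is_invisible_at_cutoff_zero(self, table_factory):
        a = table_factory({"G1": 0.2, "G2": 3.0, "G3": 0.0}, batch="2017")
        b = table_factory({g: 2 * v for g, v in a.values.items()}, batch="2020")
        rows = tc.replicate_concordance(a, b, tc.SweepConfig(cutoffs=(0.0,)))
        assert rows[0].value == 1.0

    def test_mismatched_provenance_rejected(self, table_factory):
        a = table_factory({"G1": 1.0}, platform="short_read", batch="2017")
        b = table_factory({"G1": 1.0}, platform="long_read", batch="2020")
        with pytest.raises(ValidationError, match="same platform"):
            tc.replicate_concordance(a, b)
        c = table_factory({"G1": 1.0}, batch="2017")
        with pytest.raises(ValidationError, match="distinct batches"):
            tc.replicate_concordance(a, c)


class TestSweepConfig:
    @pytest.mark.parametrize("cutoffs", [(1.0, 0.5), (0.0, 0.0), (-1.0, 2.0), ()])
    def test_invalid_ladders_rejected(self, cutoffs):
        with pytest.raises(ValidationError):
            tc.SweepConfig(cutoffs=cutoffs)
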