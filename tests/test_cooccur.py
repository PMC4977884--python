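"""Binary pathway co-occurrence: phi/Pearson equivalence, deduplication,
size classes and error control."""

import numpy as np
import pytest

from conftest import make_profile, random_profiles
from coremetab.cooccur import (
    assign_size_classes,
    consistent_across_classes,
    deduplicate,
    holm_adjust,
    pairwise_cooccurrence,
    summarize,
)
from coremetab.pathways import PATHWAY_NAMES


class TestDeduplicate:
    def test_shared_key_keeps_best_quality(self):
        trio = [
            make_profile("a", [1] * 12, seq_key="k1", quality=0.5),
            make_profile("b", [0] * 12, seq_key="k1", quality=0.9),
            make_profile("c", [1] * 12, seq_key="k1", quality=0.7),
        ]
        kept = deduplicate(trio)
        assert [p.genome_id for p in kept] == ["b"]

    def test_quality_tie_broken_by_genome_id(self):
        pair = [
            make_profile("z", [1] * 12, seq_key="k", quality=0.5),
            make_profile("a", [0] * 12, seq_key="k", quality=0.5),
        ]
        assert [p.genome_id for p in deduplicate(pair)] == ["a"]

    def test_distinct_keys_identity(self):
        profiles = [
            make_profile(f"g{i}", [i % 2] * 12, seq_key=f"k{i}") for i in range(5)
        ]
        assert deduplicate(profiles) == profiles

    def test_missing_key_retained(self):
        profiles = [
            make_profile("a", [1] * 12, seq_key=None),
            make_profile("b", [1] * 12, seq_key=None),
        ]
        assert len(deduplicate(profiles)) == 2

    def test_planted_duplicates_reduce_to_distinct_keys(self):
        rng = np.random.default_rng(3)
        keys = [f"k{rng.integers(0, 40)}" for _ in range(200)]
        profiles = [
            make_profile(f"g{i}", rng.integers(0, 2, 12), seq_key=keys[i])
            for i in range(200)
        ]
        assert len(deduplicate(profiles)) == len(set(keys))


class TestSizeClasses:
    @pytest.mark.parametrize(
        "size,expected",
        [(92, "small"), (93, "medium"), (133, "medium"), (134, "large"),
         (40, "small"), (163, "large")],
    )
    def test_thresholds(self, size, expected):
        [label] = assign_size_classes([make_profile("g", [0] * 12, model_size=size)])
        assert label == expected

    def test_empty_input(self):
        assert assign_size_classes([]) == []

    def test_model_size_range_spans_three_classes(self):
        profiles = [
            make_profile(f"g{s}", [0] * 12, model_size=s) for s in range(40, 164)
        ]
        labels = set(assign_size_classes(profiles))
        assert labels == {"small", "medium", "large"}


class TestPairwise:
    def test_identical_columns_have_unit_r(self):
        rng = np.random.default_rng(0)
        profiles = []
        for i in range(50):
            v = rng.integers(0, 2, 12)
            v[1] = v[0]  # entner_doudoroff copies glycolysis
            profiles.append(make_profile(f"g{i}", v))
        res = pairwise_cooccurrence(profiles)
        row = res.pair(PATHWAY_NAMES[0], PATHWAY_NAMES[1])
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_phi_formula_matches_pearson_on_2x2_counts(self):
        # counts (a, b, c, d) = (30, 10, 10, 30), n = 80
        a = b = c = d = 0
        profiles = []
        for x, y, count in [(1, 1, 30), (1, 0, 10), (0, 1, 10), (0, 0, 30)]:
            for _ in range(count):
                v = [0] * 12
                v[0], v[1] = x, y
                profiles.append(make_profile(f"g{len(profiles)}", v))
        a, b, c, d = 30, 10, 10, 30
        phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        res = pairwise_cooccurrence(profiles)
        row = res.pair(PATHWAY_NAMES[0], PATHWAY_NAMES[1])
        assert row.r == pytest.approx(phi)

    def test_constant_column_flagged_undefined(self):
        rng = np.random.default_rng(1)
        profiles = []
        for i in range(30):
            v = rng.integers(0, 2, 12)
            v[3] = 1  # pentose phosphate in every genome
            profiles.append(make_profile(f"g{i}", v))
        res = pairwise_cooccurrence(profiles)
        sub = res.table[
            (res.table.pathway_a == PATHWAY_NAMES[3]) | (res.table.pathway_b == PATHWAY_NAMES[3])
        ]
        assert not sub.defined.any()
        assert not sub.r.notna().any()

    def test_matrix_symmetric_unit_diagonal_permutation_invariant(self):
        rng = np.random.default_rng(2)
        profiles = random_profiles(rng, 120)
        res = pairwise_cooccurrence(profiles)
        M = res.r_matrix.to_numpy()
        assert np.allclose(M, M.T, equal_nan=True)
        assert np.allclose(np.diag(M), 1.0)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        res2 = pairwise_cooccurrence(shuffled)
        assert np.allclose(M, res2.r_matrix.to_numpy(), equal_nan=True)

    def test_planted_dependence_is_strongest_positive_pair(self):
        rng = np.random.default_rng(5)
        profiles = []
        for i in range(400):
            v = rng.integers(0, 2, 12)
            # butanol tracks butyrate with 10% flips
            i_but = PATHWAY_NAMES.index("butyrate")
            i_bol = PATHWAY_NAMES.index("butanol")
            v[i_bol] = v[i_but] ^ (rng.random() < 0.1)
            profiles.append(make_profile(f"g{i}", v))
        res = pairwise_cooccurrence(profiles)
        top = res.table.loc[res.table.r.idxmax()]
        assert {top.pathway_a, top.pathway_b} == {"butanol", "butyrate"}
        assert top.r > 0.5 and top.significant

    def test_type_one_error_rate_near_alpha(self):
        """Independent Bernoulli pathway columns: the significant-pair rate
        stays within 3 binomial standard errors of alpha = 0.05."""
        rng = np.random.default_rng(12345)
        profiles = random_profiles(rng, 1000)
        res = pairwise_cooccurrence(profiles)
        defined = res.table[res.table.defined]
        rate = defined.significant.mean()
        n_pairs = len(defined)
        se = np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate - 0.05) <= 3 * se


class TestSummaries:
    def test_all_positive_corpus_gives_fraction_one(self):
        rng = np.random.default_rng(8)
        profiles = []
        for i in range(200):
            rich = rng.random() < 0.5  # genome-wide richness couples all pathways
            v = (rng.random(12) < (0.8 if rich else 0.2)).astype(int)
            profiles.append(make_profile(f"g{i}", v))
        res = pairwise_cooccurrence(profiles)
        summary = summarize([res])
        assert summary.fraction_positive.iloc[0] == pytest.approx(1.0)

    def test_planted_negative_pair_lowers_fraction(self):
        rng = np.random.default_rng(9)
        profiles = []
        for i in range(400):
            rich = rng.random() < 0.5
            v = (rng.random(12) < (0.8 if rich else 0.2)).astype(int)
            v[1] = 1 - v[0]  # glycolysis vs ED trade-off
            profiles.append(make_profile(f"g{i}", v))
        res = pairwise_cooccurrence(profiles)
        summary = summarize([res])
        assert summary.fraction_positive.iloc[0] < 1.0

    def test_holm_is_no_less_strict_than_raw(self):
        rng = np.random.default_rng(10)
        profiles = random_profiles(rng, 300)
        res = pairwise_cooccurrence(profiles)
        adjusted = holm_adjust(res)
        assert adjusted.table.significant.sum() <= res.table.significant.sum()

    def test_consistency_across_size_classes(self):
        rng = np.random.default_rng(11)
        sizes = rng.integers(40, 164, size=600)
        profiles = []
        for i in range(600):
            rich = rng.random() < 0.5
            v = (rng.random(12) < (0.8 if rich else 0.2)).astype(int)
            profiles.append(make_profile(f"g{i}", v, model_size=int(sizes[i])))
        by_class = {
            cls: pairwise_cooccurrence(profiles, cls)
            for cls in ("small", "medium", "large")
        }
        table = consistent_across_classes(by_class)
        assert {"pathway_a", "pathway_b", "consistent"} <= set(table.columns)
        assert table.consistent.any()
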