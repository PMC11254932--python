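"""CLR transform, Aitchison PERMANOVA, and relative abundances."""

import numpy as np
import pandas as pd
import pytest

from phyllon.community import (
    AsvTable,
    aitchison_distance,
    clr_transform,
    n_distinct_arrangements,
    permanova,
    relative_abundance,
)
from phyllon.errors import DesignError
from phyllon.synthetic import CountScenario, gen_counts


def small_table():
    counts = pd.DataFrame(
        [[3, 1, 0, 4], [6, 2, 1, 8], [1, 1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    tax = pd.DataFrame(
        {"phylum": ["Proteobacteria", "Proteobacteria", "Cyanobacteria", ""],
         "genus": ["Epibacterium", "", "Schizothrix", ""]},
        index=counts.columns,
    )
    return AsvTable(counts=counts, taxonomy=tax)


class TestClr:
    def test_equal_counts_map_to_zero(self):
        z = clr_transform(pd.DataFrame([[5, 5, 5, 5]]), pseudocount=0.5)
        assert np.allclose(z, 0.0)

    def test_hand_computed_row(self):
        # counts (0,1,3) + 0.5 -> log(0.5,1.5,3.5) centered on its mean
        z = clr_transform(pd.DataFrame([[0, 1, 3]]), pseudocount=0.5)
        logs = np.log([0.5, 1.5, 3.5])
        expected = logs - logs.mean()
        assert np.allclose(z[0], expected)
        assert z[0] == pytest.approx([-1.014841, 0.083771, 0.931069], abs=1e-5)

    def test_rows_sum_to_zero(self):
        table = gen_counts(CountScenario(seed=3))
        z = clr_transform(table)
        assert np.abs(z.sum(axis=1)).max() < 1e-9

    def test_scale_invariance(self):
        row = np.array([[2.0, 7.0, 1.0, 10.0]])
        a = clr_transform(pd.DataFrame(row), pseudocount=1e-12)
        b = clr_transform(pd.DataFrame(17.0 * row), pseudocount=1e-12)
        assert np.allclose(a, b, atol=1e-9)

    def test_rejects_bad_pseudocount_and_empty(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[0, 2]]), pseudocount=0.0)  # zeros need pc > 0
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[1, 2]]), pseudocount=-0.5)
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame())

    def test_exact_scale_invariance_without_pseudocount(self):
        row = np.array([[2.0, 7.0, 1.0, 10.0]])
        a = clr_transform(pd.DataFrame(row), pseudocount=0.0)
        b = clr_transform(pd.DataFrame(123.0 * row), pseudocount=0.0)
        assert np.allclose(a, b, atol=1e-12)


class TestPermanova:
    def separated_points(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1],
                        [10, 10], [10.1, 10], [10, 10.1]])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return d, np.array(["a"] * 3 + ["b"] * 3)

    def test_exact_enumeration_fully_separated(self):
        d, groups = self.separated_points()
        res = permanova(d, groups, method="exact")
        assert res.n_permutations == 20  # C(6,3) labelings
        assert res.p_value == pytest.approx(1.0 / 10.0)  # split + its mirror
        assert res.method == "exact"

    def test_identical_points_not_significant(self):
        d = np.zeros((8, 8))
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 1e-9, (8, 2))
        d = np.sqrt(((jitter[:, None] - jitter[None, :]) ** 2).sum(-1))
        groups = rng.permutation(np.array(["a"] * 4 + ["b"] * 4))
        res = permanova(d, groups, n_perm=199, seed=1, method="sampled")
        assert res.p_value > 0.2

    def test_deterministic_under_seed(self):
        table = gen_counts(CountScenario(seed=11, effect_size=0.5))
        d = aitchison_distance(table)
        g = table.sample_meta["group"].to_numpy()
        r1 = permanova(d, g, n_perm=499, seed=42, method="sampled")
        r2 = permanova(d, g, n_perm=499, seed=42, method="sampled")
        assert (r1.pseudo_f, r1.p_value) == (r2.pseudo_f, r2.p_value)

    def test_matches_skbio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        table = gen_counts(CountScenario(n_samples_per_group=(6, 6), effect_size=1.0, seed=7))
        d = aitchison_distance(table)
        g = table.sample_meta["group"].to_numpy()
        mine = permanova(d, g, n_perm=999, seed=1, method="sampled")
        dm = skbio_distance.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        theirs = skbio_distance.permanova(dm, g, permutations=0)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_sampled_converges_to_exact(self):
        table = gen_counts(CountScenario(n_samples_per_group=(5, 4), effect_size=0.8, seed=2))
        d = aitchison_distance(table)
        g = table.sample_meta["group"].to_numpy()
        exact = permanova(d, g, method="exact")
        sampled = permanova(d, g, n_perm=4999, seed=3, method="sampled")
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4999)
        assert abs(sampled.p_value - exact.p_value) < 3 * se + 1 / 5000

    def test_p_floor_and_single_group_error(self):
        d, groups = self.separated_points()
        res = permanova(d, groups, n_perm=9, seed=0, method="sampled")
        assert res.p_value >= 1.0 / 10.0
        with pytest.raises(DesignError):
            permanova(d, np.array(["a"] * 6))

    def test_arrangement_count(self):
        assert n_distinct_arrangements(["a"] * 3 + ["b"] * 3) == 20
        assert n_distinct_arrangements(["a"] * 4 + ["b"] * 3) == 35


class TestRelativeAbundance:
    def test_single_asv_is_100_percent(self):
        counts = pd.DataFrame([[7]], index=["s1"], columns=["ASV1"])
        tax = pd.DataFrame({"phylum": ["Proteobacteria"]}, index=["ASV1"])
        rel = relative_abundance(AsvTable(counts=counts, taxonomy=tax), "phylum")
        assert rel.loc["s1", "Proteobacteria"] == pytest.approx(100.0)

    def test_three_to_one_split(self):
        counts = pd.DataFrame([[3, 1]], index=["s1"], columns=["ASV1", "ASV2"])
        tax = pd.DataFrame({"phylum": ["P1", "P2"]}, index=counts.columns)
        rel = relative_abundance(AsvTable(counts=counts, taxonomy=tax), "phylum")
        assert rel.loc["s1", "P1"] == pytest.approx(75.0)
        assert rel.loc["s1", "P2"] == pytest.approx(25.0)

    def test_manual_aggregation_and_unclassified_pool(self):
        table = small_table()
        rel = relative_abundance(table, "phylum")
        # s1: Proteobacteria 3+1=4, Cyanobacteria 0, Unclassified 4 of total 8
        assert rel.loc["s1", "Proteobacteria"] == pytest.approx(50.0)
        assert rel.loc["s1", "Unclassified"] == pytest.approx(50.0)
        assert np.allclose(rel.sum(axis=1), 100.0, atol=1e-9)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(small_table(), "kingdom")


class TestAsvTableValidation:
    def test_negative_counts_rejected(self):
        counts = pd.DataFrame([[-1, 2]], index=["s1"], columns=["ASV1", "ASV2"])
        tax = pd.DataFrame({"phylum": ["P", "P"]}, index=counts.columns)
        with pytest.raises(ValueError):
            AsvTable(counts=counts, taxonomy=tax)

    def test_taxonomy_must_cover_asvs(self):
        counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["ASV1", "ASV2"])
        tax = pd.DataFrame({"phylum": ["P"]}, index=["ASV1"])
        with pytest.raises(ValueError):
            AsvTable(counts=counts, taxonomy=tax)
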