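"""Rarefaction, filtering, dissimilarity, ordination and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from contamqc.community import (
    bray_curtis,
    core_taxa,
    filter_low_count,
    pcoa,
    permanova,
    rarefy,
    rda_univariable,
    relativize,
)
from contamqc.feature_table import FeatureTable

from conftest import random_table


class TestRarefy:
    def test_totals_hit_depth_exactly(self, rng):
        t = random_table(rng, 40, 20, max_count=300)
        out, dropped = rarefy(t, depth=500, seed=1)
        assert (out.counts.sum(axis=0) == 500).all()
        shallow = [s for s, tot in t.sample_totals().items() if tot < 500]
        assert dropped == shallow

    def test_counts_never_exceed_originals(self, rng):
        t = random_table(rng, 20, 10, max_count=100)
        out, _ = rarefy(t, depth=100, seed=2)
        orig = t.to_dataframe()[out.sample_ids].to_numpy()
        assert (out.counts <= orig).all()

    def test_depth_equal_to_total_is_identity(self):
        t = FeatureTable(["a", "b"], ["s"], np.array([[6], [2]]))
        out, _ = rarefy(t, depth=8, seed=0)
        assert np.array_equal(out.counts, t.counts)

    def test_seed_reproducibility(self, rng):
        t = random_table(rng, 30, 10, max_count=200)
        a, _ = rarefy(t, 300, seed=9)
        b, _ = rarefy(t, 300, seed=9)
        c, _ = rarefy(t, 300, seed=10)
        assert a == b
        assert a != c

    def test_hypergeometric_mean(self):
        """Sample (6,2) rarefied to 4: mean count of taxon 1 is 3 (3 sigma band)."""
        reps = 10_000
        t = FeatureTable(["a", "b"], [f"s{i}" for i in range(reps)],
                         np.tile([[6], [2]], (1, reps)))
        out, _ = rarefy(t, depth=4, seed=0)
        mean_a = out.counts[0].mean()
        var = 4 * (6 / 8) * (2 / 8) * (8 - 4) / (8 - 1)  # hypergeometric variance
        assert abs(mean_a - 3.0) <= 3 * np.sqrt(var / reps)


class TestFilterLowCount:
    def test_strict_boundary(self):
        t = FeatureTable(["at59", "at60"], ["s1", "s2"],
                         np.array([[30, 29], [30, 30]]))
        out, report = filter_low_count(t, min_total=60)
        assert out.taxon_ids == ["at60"]
        assert report["removed_taxa"] == ["at59"]

    def test_zero_threshold_is_identity(self, rng):
        t = random_table(rng)
        out, _ = filter_low_count(t, min_total=0)
        assert out == t

    def test_matches_brute_force(self, rng):
        t = random_table(rng, 50, 10)
        out, _ = filter_low_count(t, min_total=200)
        expected = [tid for i, tid in enumerate(t.taxon_ids)
                    if t.counts[i].sum() >= 200]
        assert out.taxon_ids == expected


class TestRelativize:
    def test_toy_scaling(self):
        t = FeatureTable(["a", "b"], ["s"], np.array([[1], [1]]))
        out = relativize(t, 8000)
        assert out["s"].tolist() == [4000.0, 4000.0]

    def test_rarefied_column_unchanged(self):
        t = FeatureTable(["a", "b"], ["s"], np.array([[6000], [2000]]))
        out = relativize(t, 8000)
        assert out["s"].tolist() == [6000.0, 2000.0]

    def test_all_columns_hit_total(self, rng):
        t = random_table(rng, 20, 15, max_count=100)
        out = relativize(t, 8000)
        np.testing.assert_allclose(out.sum(axis=0), 8000.0, atol=1e-9)

    def test_zero_total_rejected(self):
        t = FeatureTable(["a"], ["s"], np.array([[0]]))
        with pytest.raises(ValueError):
            relativize(t)


class TestCoreTaxa:
    def test_joint_thresholds(self):
        # t_core everywhere at ~3%; t_prev prevalent but < 1%; t_ab abundant but patchy
        counts = np.array([[3, 3, 3, 3], [1, 1, 1, 1], [97, 0, 97, 0], [0, 97, 0, 97]])
        t = FeatureTable(["t_core", "t_prev", "t_ab1", "t_ab2"],
                         [f"s{i}" for i in range(4)], counts)
        core = core_taxa(t, prevalence_min=0.95, mean_abundance_min=0.01)
        assert core == {"t_core"}

    def test_matches_brute_force(self, rng):
        t = random_table(rng, 40, 25, max_count=10)
        core = core_taxa(t, 0.5, 0.02)
        rel = t.counts / t.counts.sum(axis=0)
        for i, tid in enumerate(t.taxon_ids):
            prev = (t.counts[i] >= 1).mean()
            expected = prev >= 0.5 and rel[i].mean() >= 0.02
            assert (tid in core) == expected


class TestBrayCurtis:
    def test_hand_value(self):
        d = bray_curtis(np.array([[5, 3, 0], [1, 3, 4]]))
        assert d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_identical_and_disjoint_rows(self):
        d = bray_curtis(np.array([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        x = rng.random((12, 8)) * 10
        d = bray_curtis(x)
        for i in range(12):
            for j in range(12):
                expect = 1 - 2 * np.minimum(x[i], x[j]).sum() / (x[i].sum() + x[j].sum())
                assert d[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.all((d >= -1e-15) & (d <= 1 + 1e-15))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1, 1], [0, 0]]))


class TestPcoa:
    def test_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        axis1 = res.coordinates[:, 0]
        np.testing.assert_allclose(sorted(axis1), [-1, 0, 1], atol=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        res = pcoa(d)
        recon = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_eigenvalues_match_skbio(self, rng):
        x = rng.random((15, 10))
        d = bray_curtis(x)
        mine = pcoa(d)
        theirs = skbio_pcoa(DistanceMatrix(d), method="eigh", number_of_dimensions=0)
        n_pos = mine.coordinates.shape[1]
        np.testing.assert_allclose(
            mine.eigenvalues[:n_pos],
            np.sort(theirs.eigvals.to_numpy())[::-1][:n_pos],
            atol=1e-8,
        )

    def test_sample_permutation_equivariance(self, rng):
        x = rng.random((8, 6))
        d = bray_curtis(x)
        perm = rng.permutation(8)
        res = pcoa(d)
        res_p = pcoa(d[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            np.abs(res_p.coordinates[:, 0]), np.abs(res.coordinates[perm, 0]), atol=1e-8
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))


class TestPermanova:
    def test_single_group_rejected(self, rng):
        d = bray_curtis(rng.random((6, 4)))
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 6)

    def test_statistic_matches_skbio(self, rng):
        x = rng.random((20, 8))
        d = bray_curtis(x)
        groups = ["a"] * 10 + ["b"] * 6 + ["c"] * 4
        mine = permanova(d, groups, n_permutations=49, seed=0)
        theirs = skbio_permanova(DistanceMatrix(d), grouping=groups, permutations=49)
        assert mine.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_p_value_convention_and_determinism(self, rng):
        x = rng.random((16, 5))
        d = bray_curtis(x)
        groups = ["a"] * 8 + ["b"] * 8
        r1 = permanova(d, groups, n_permutations=99, seed=5)
        r2 = permanova(d, groups, n_permutations=99, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.p_value * 100 == pytest.approx(round(r1.p_value * 100))
        assert 1 / 100 <= r1.p_value <= 1.0

    def test_separated_groups_detected(self, rng):
        # disjoint supports: every between-group dissimilarity is 1
        a = np.pad(rng.random((10, 3)) + 0.1, ((0, 0), (0, 3)))
        b = np.pad(rng.random((10, 3)) + 0.1, ((0, 0), (3, 0)))
        d = bray_curtis(np.vstack([a, b]))
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_permutations=199, seed=0)
        # a permutation reproducing the partition ties the observed F, so allow 2/200
        assert res.p_value <= 2 / 200
        assert res.r_squared > 0.5


class TestRda:
    def test_perfect_fit(self, rng):
        x = pd.Series(["u"] * 10 + ["v"] * 10)
        y = np.zeros((20, 4))
        y[10:, :] = 3.0  # response is an exact function of x
        res = rda_univariable(y, x, n_permutations=999, seed=1)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_dummy_recoding_invariance(self, rng):
        y = rng.random((24, 6))
        labels = rng.choice(["a", "b", "c"], 24)
        r1 = rda_univariable(y, pd.Series(labels), n_permutations=9, seed=0)
        recoded = pd.Series(pd.Categorical(labels, categories=["c", "a", "b"]))
        r2 = rda_univariable(y, recoded, n_permutations=9, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-10)

    def test_constant_variable_rejected(self, rng):
        with pytest.raises(ValueError):
            rda_univariable(rng.random((10, 3)), pd.Series(["same"] * 10))

    def test_numeric_variable_matches_regression_r2(self, rng):
        xnum = rng.normal(size=30)
        y = np.outer(xnum, [1.0, 2.0]) + rng.normal(size=(30, 2)) * 0.1
        res = rda_univariable(y, xnum, n_permutations=9, seed=0)
        # univariable numeric RDA r2 equals variance-weighted OLS R^2
        yc = y - y.mean(axis=0)
        xc = xnum - xnum.mean()
        fitted = np.outer(xc, (xc @ yc) / (xc @ xc))
        expect = (fitted ** 2).sum() / (yc ** 2).sum()
        assert res.r_squared == pytest.approx(expect, abs=1e-10)
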