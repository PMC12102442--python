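"""Unit tests for community filtering, rarefaction, diversity and ordination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from gyremet import community
from tests.conftest import make_taxonomy


class TestRemoveLineages:
    def test_removes_matching_asvs(self, tiny_table, tiny_tax):
        filtered, report = community.remove_lineages(tiny_table, tiny_tax)
        assert list(filtered.columns) == ["ASV1", "ASV3", "ASV4"]
        assert report["removed"] == ["ASV2"]
        assert list(filtered.index) == list(tiny_table.index)

    def test_identity_when_no_match(self, tiny_table, tiny_tax):
        filtered, _ = community.remove_lineages(tiny_table, tiny_tax, ("Archaea",))
        pd.testing.assert_frame_equal(filtered, tiny_table)

    def test_case_insensitive_substring(self, tiny_table):
        tax = make_taxonomy(
            {a: ("Bacteria", "", "", "chloroplast_like", "", "") for a in tiny_table.columns}
        )
        filtered, _ = community.remove_lineages(tiny_table, tax, ("Chloroplast",))
        assert filtered.shape[1] == 0

    def test_missing_taxonomy_retained_and_reported(self, tiny_table, tiny_tax):
        filtered, report = community.remove_lineages(
            tiny_table, tiny_tax.drop(index="ASV4")
        )
        assert "ASV4" in filtered.columns
        assert report["missing_taxonomy"] == ["ASV4"]


class TestRarefy:
    def test_totals_equal_depth_and_seed_reproducible(self, default_bundle):
        table = default_bundle.asv_table.iloc[:10]
        depth = 40_000
        out1, dropped1 = community.rarefy(table, depth, seed=3)
        out2, _ = community.rarefy(table, depth, seed=3)
        assert (out1.sum(axis=1) == depth).all()
        assert out1.equals(out2)
        assert dropped1 == []

    def test_sample_at_exact_depth_unchanged(self):
        table = pd.DataFrame([[3, 7]], index=["a"], columns=["x", "y"])
        out, _ = community.rarefy(table, 10, seed=0)
        assert out.loc["a"].tolist() == [3, 7]

    def test_shallow_sample_dropped(self):
        table = pd.DataFrame([[3, 7], [1, 1]], index=["a", "b"], columns=["x", "y"])
        out, dropped = community.rarefy(table, 10, seed=0)
        assert dropped == ["b"] and list(out.index) == ["a"]

    def test_depth_one_boundary(self):
        table = pd.DataFrame([[5, 5]], index=["a"], columns=["x", "y"])
        out, _ = community.rarefy(table, 1, seed=0)
        assert out.loc["a"].sum() == 1

    def test_hypergeometric_expectation(self):
        # drawing 100 of (100, 900): E[ASV2] = 90 by the hypergeometric mean
        table = pd.DataFrame([[100, 900]], index=["a"], columns=["x", "y"])
        draws = [community.rarefy(table, 100, seed=s)[0].loc["a", "y"] for s in range(300)]
        se = math.sqrt(100 * 0.9 * 0.1 * (900 / 999) / 300)
        assert np.mean(draws) == pytest.approx(90.0, abs=5 * se)

    def test_invalid_depth(self, tiny_table):
        with pytest.raises(ValueError):
            community.rarefy(tiny_table, 0, seed=0)


class TestDiversity:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 0, 1), 2), ((0, 0, 0), 0), ((1, 1, 1, 1), 4)]
    )
    def test_richness(self, counts, expected):
        assert community.richness(counts) == expected

    @pytest.mark.parametrize(
        "counts,expected",
        [((7, 0, 0), 0.0), ((1, 1, 1, 1), math.log(4)), ((1, 1, 2), 1.0397)],
    )
    def test_shannon(self, counts, expected):
        assert community.shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_shannon_all_zero_errors(self):
        with pytest.raises(ValueError):
            community.shannon([0, 0])

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, deadline=None)
    def test_shannon_bounded_by_log_richness(self, counts):
        h = community.shannon(counts)
        s = community.richness(counts)
        assert -1e-12 <= h <= math.log(s) + 1e-12


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((3, 1), (3, 1), 0.0), ((5, 0), (0, 7), 1.0), ((2, 0), (1, 1), 0.5)],
    )
    def test_examples(self, x, y, expected):
        assert community.bray_curtis(x, y) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            community.bray_curtis([1, 2], [1, 2, 3])

    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=15),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, x, data):
        y = data.draw(st.lists(st.integers(0, 500), min_size=len(x), max_size=len(x)))
        if sum(x) == 0 or sum(y) == 0:
            return
        d_xy = community.bray_curtis(x, y)
        assert 0 <= d_xy <= 1
        assert d_xy == pytest.approx(community.bray_curtis(y, x))
        assert community.bray_curtis(x, x) == 0.0


class TestPCoA:
    def test_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = community.pcoa(d)
        assert res.coordinates.shape[1] == 1
        axis = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert axis == pytest.approx([-1, 0, 1], abs=1e-10)

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
        res = community.pcoa(d)
        assert res.coordinates.iloc[0].to_numpy() == pytest.approx(
            res.coordinates.iloc[1].to_numpy(), abs=1e-10
        )

    def test_euclidean_cloud_reproduces_distances(self, rng):
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        res = community.pcoa(d)
        d_hat = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d_hat - d).max() < 1e-8
        assert res.negative_eigenvalues.size == 0 or (
            np.abs(res.negative_eigenvalues).max() < 1e-8
        )

    def test_matches_reference_eigenvalues(self, rng):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        res = community.pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d), method="eigh")
        k = res.coordinates.shape[1]
        assert res.eigenvalues[:k] == pytest.approx(
            ref.eigvals.to_numpy()[:k], rel=1e-8, abs=1e-10
        )

    def test_asymmetry_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            community.pcoa(d)


class TestPermanova:
    @staticmethod
    def _points(rng, separated):
        pts = rng.normal(size=(12, 3))
        if separated:
            pts[6:] += 4.0
        return squareform(pdist(pts)), np.array(["a"] * 6 + ["b"] * 6)

    def test_separated_duplicated_groups_minimal_p(self, rng):
        pts = np.vstack([np.zeros((6, 2)), np.full((6, 2), 10.0)])
        d = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        f, p = community.permanova(d, labels, n_perm=999, seed=0)
        assert p < 0.01

    def test_seed_reproducibility(self, rng):
        d, labels = self._points(rng, separated=True)
        r1 = community.permanova(d, labels, n_perm=199, seed=5)
        r2 = community.permanova(d, labels, n_perm=199, seed=5)
        assert r1 == r2

    def test_exact_enumeration_matches_brute_force(self, rng):
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = squareform(pdist(pts))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f_obs, p_exact = community.permanova(d, labels, exact=True)

        # independent brute force: direct within-group sums over all relabelings
        def brute_f(lab):
            n = len(lab)
            sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for g in set(lab):
                idx = [i for i in range(n) if lab[i] == g]
                ssw += sum(
                    d[i, j] ** 2 for i in idx for j in idx if i < j
                ) / len(idx)
            return ((sst - ssw) / 1) / (ssw / 4)

        fs = [brute_f(np.array(labels)[list(perm)]) for perm in itertools.permutations(range(6))]
        p_brute = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert f_obs == pytest.approx(brute_f(labels), rel=1e-10)
        assert p_exact == pytest.approx(p_brute, abs=1e-12)

    def test_degenerate_grouping_rejected(self, rng):
        d, _ = self._points(rng, separated=False)
        with pytest.raises(ValueError):
            community.permanova(d, ["a"] * 11 + ["b"], n_perm=99)


class TestWilcoxon:
    def test_identical_samples(self):
        _, p = community.wilcoxon_ranksum([1, 2, 3, 4, 5] * 2, [1, 2, 3, 4, 5] * 2)
        assert p > 0.9

    def test_complete_separation(self):
        x = np.arange(10.0)
        y = np.arange(100.0, 110.0)
        _, p = community.wilcoxon_ranksum(x, y)
        assert p < 0.001

    def test_exact_matches_enumeration(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        y = np.array([2.0, 4.0, 6.0, 20.0])
        _, p = community.wilcoxon_ranksum(x, y)
        pooled = np.concatenate([x, y])
        us = []
        for comb in itertools.combinations(range(8), 4):
            xs = pooled[list(comb)]
            ys = np.delete(pooled, list(comb))
            us.append(sum((xi > ys).sum() for xi in xs))
        us = np.asarray(us)
        u_obs = sum((xi > y).sum() for xi in x)
        p_enum = min(2 * min((us <= u_obs).mean(), (us >= u_obs).mean()), 1.0)
        assert p == pytest.approx(p_enum, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            community.wilcoxon_ranksum([], [1.0])


class TestAggregateTaxa:
    def test_single_class_single_column(self, tiny_table):
        tax = make_taxonomy(
            {a: ("Bacteria", "P", "OnlyClass", "", "", "") for a in tiny_table.columns}
        )
        rel = community.aggregate_taxa(tiny_table, tax, "class")
        assert list(rel.columns) == ["OnlyClass"]
        assert rel["OnlyClass"].to_numpy() == pytest.approx(np.ones(5))

    def test_additivity_within_order(self, tiny_tax):
        table = pd.DataFrame(
            [[10, 10, 20, 0]], index=["s"], columns=["ASV1", "ASV2", "ASV3", "ASV4"]
        )
        rel = community.aggregate_taxa(table, tiny_tax, "order")
        assert rel.loc["s", "SAR11_clade"] == pytest.approx(0.25)
        assert rel.loc["s", "Chloroplast"] == pytest.approx(0.25)

    def test_survey_scale_shares(self):
        # 40.7/28.7/16.0/14.6 reads per 100 -> identical proportions
        table = pd.DataFrame([[407, 287, 160, 146]], index=["s"], columns=list("abcd"))
        tax = make_taxonomy(
            {
                "a": ("B", "", "Alphaproteobacteria", "", "", ""),
                "b": ("B", "", "Cyanobacteriia", "", "", ""),
                "c": ("B", "", "Gammaproteobacteria", "", "", ""),
                "d": ("B", "", "Other", "", "", ""),
            }
        )
        rel = community.aggregate_taxa(table, tax, "class")
        assert rel.loc["s", "Alphaproteobacteria"] == pytest.approx(0.407)
        assert rel.loc["s", "Cyanobacteriia"] == pytest.approx(0.287)
        assert rel.loc["s", "Gammaproteobacteria"] == pytest.approx(0.160)
        assert rel.sum(axis=1).to_numpy() == pytest.approx([1.0], abs=1e-12)

    def test_unassigned_pooling_and_unknown_rank(self, tiny_table, tiny_tax):
        tax = tiny_tax.copy()
        tax.loc["ASV1", "genus"] = ""
        rel = community.aggregate_taxa(tiny_table, tax, "genus")
        assert "Unassigned" in rel.columns
        with pytest.raises(ValueError):
            community.aggregate_taxa(tiny_table, tiny_tax, "species")
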