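"""Rarefaction, diversity, filters, CSS, distances, PERMANOVA, FDR stage."""

import numpy as np
import pandas as pd
import pytest

from skinpah import (
    abundance_filter,
    bh_adjust,
    css_normalize,
    distance,
    fit_associations,
    goods_coverage,
    kruskal_wallis,
    mann_whitney,
    permanova,
    rarefy,
    shannon,
)
from skinpah.errors import EmptyTableError
from skinpah.stats import DistanceMatrix
from skinpah.tables import TaxonTable


def make_table(counts):
    counts = np.asarray(counts)
    df = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(counts.shape[0])],
        columns=[f"T{i}" for i in range(counts.shape[1])],
    )
    return TaxonTable(df, pd.Series("bacteria", index=df.columns))


class TestRarefy:
    def test_library_at_exact_depth_unchanged(self):
        t = make_table([[3, 4, 3]])
        out = rarefy(t, 10, seed=0)
        assert list(out.counts.iloc[0]) == [3, 4, 3]

    def test_all_libraries_equal_depth(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 60, (10, 30)))
        out = rarefy(t, 200, seed=1)
        assert (out.library_sizes() == 200).all()

    def test_shallow_samples_dropped(self):
        t = make_table([[100, 100], [1, 1]])
        out = rarefy(t, 50, seed=0)
        assert out.n_samples == 1

    def test_depth_unreachable_raises(self):
        with pytest.raises(EmptyTableError):
            rarefy(make_table([[1, 1]]), 100, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean rarefied count tracks depth x original proportion."""
        t = make_table([[600, 300, 100]])
        depth = 100
        draws = np.array(
            [rarefy(t, depth, seed=s).counts.iloc[0].to_numpy() for s in range(1000)]
        )
        expected = depth * np.array([0.6, 0.3, 0.1])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 2 * se + 1e-9)


class TestDiversity:
    def test_single_taxon_zero_entropy(self):
        assert shannon([10]) == pytest.approx(0.0)

    def test_uniform_entropy_is_log_k(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_hand_computed_entropy(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.03972, abs=1e-5)

    def test_goods_no_singletons(self):
        assert goods_coverage([2, 3, 5]) == pytest.approx(1.0)

    def test_goods_two_singletons_of_ten_reads(self):
        assert goods_coverage([1, 1, 8]) == pytest.approx(0.8)

    def test_goods_all_singletons(self):
        assert goods_coverage([1, 1, 1]) == pytest.approx(0.0)


class TestAbundanceFilter:
    def test_boundary_taxon_retained(self):
        t = make_table([[999, 1], [8000, 9], [989, 2]])  # T1: 12/10000
        out = abundance_filter(t, 12 / 10000)
        assert "T1" in out.taxon_ids

    def test_engineered_pass_count(self):
        """Exactly 74 of 300 taxa sit above the 0.1% overall threshold."""
        rng = np.random.default_rng(5)
        grand = 100_000
        n_pass, n_total = 74, 300
        high = rng.integers(150, 500, n_pass)  # >= 0.15% each
        low = rng.integers(1, 80, n_total - n_pass)  # < 0.08% each
        counts = np.concatenate([high, low])
        pad = grand - counts.sum()
        counts[0] += max(pad, 0)
        t = make_table(counts[None, :])
        out = abundance_filter(t, 0.001)
        assert out.n_taxa == n_pass

    def test_idempotent(self, random_table):
        once = abundance_filter(random_table, 0.005)
        twice = abundance_filter(once, 0.005)
        assert list(once.taxon_ids) == list(twice.taxon_ids)


class TestCss:
    def test_identical_samples_identical_rows(self):
        t = make_table([[5, 1, 9, 0]] * 4)
        out = css_normalize(t).to_numpy()
        assert np.allclose(out, out[0])

    def test_depth_equivariance(self):
        base = np.array([12, 0, 7, 30, 1, 5])
        t = make_table(np.vstack([base, base * 10]))
        out = css_normalize(t, percentile=0.5).to_numpy()
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_percentile_one_is_total_sum_scaling(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, (5, 20))
        t = make_table(counts)
        out = css_normalize(t, percentile=1.0).to_numpy()
        expected = counts / counts.sum(axis=1, keepdims=True) * 1000
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestDistance:
    def test_identical_samples_zero(self):
        t = make_table([[1, 2, 3], [1, 2, 3]])
        for metric in ("bray_curtis", "binary_jaccard"):
            assert distance(t, metric).matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        t = make_table([[5, 0], [0, 9]])
        for metric in ("bray_curtis", "binary_jaccard"):
            assert distance(t, metric).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        t = make_table([[1, 1, 0], [0, 1, 1]])
        assert distance(t, "bray_curtis").matrix[0, 1] == pytest.approx(0.5)
        assert distance(t, "binary_jaccard").matrix[0, 1] == pytest.approx(
            2 / 3, abs=1e-9
        )

    def test_symmetry_zero_diagonal_and_range(self, random_table):
        for metric in ("bray_curtis", "binary_jaccard"):
            D = distance(random_table, metric).matrix
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)
            assert D.min() >= 0 and D.max() <= 1


class TestPermanova:
    def test_maximal_separation_minimal_p(self):
        # unbalanced groups so no label permutation reproduces the split
        a = np.zeros((5, 3))
        b = np.ones((6, 3)) * 10
        D = distance(
            pd.DataFrame(np.vstack([a + [1, 0, 0], b])), "bray_curtis"
        )
        res = permanova(D, ["g1"] * 5 + ["g2"] * 6, n_perm=99, seed=0)
        assert res.p == pytest.approx(1 / 100)
        assert res.pseudo_F > 10

    def test_equivariant_under_matched_permutation(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 6))
        labels = np.array(["a", "b"] * 6)
        D = distance(pd.DataFrame(X), "bray_curtis")
        perm = rng.permutation(12)
        D2 = DistanceMatrix(D.sample_ids[perm], D.matrix[np.ix_(perm, perm)],
                            "bray_curtis")
        f1 = permanova(D, labels, n_perm=9, seed=0).pseudo_F
        f2 = permanova(D2, labels[perm], n_perm=9, seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-10)

    def test_agrees_with_skbio_pseudo_f(self):
        """Independent oracle: scikit-bio's PERMANOVA statistic."""
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        X = rng.random((16, 5))
        labels = ["a"] * 8 + ["b"] * 8
        D = distance(pd.DataFrame(X), "bray_curtis")
        ours = permanova(D, labels, n_perm=9, seed=0).pseudo_F
        dm = skbio_dist.DistanceMatrix(D.matrix, [str(i) for i in range(16)])
        theirs = skbio_dist.permanova(dm, labels, permutations=9)["test statistic"]
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_degenerate_grouping_raises(self):
        D = distance(pd.DataFrame(np.eye(4)), "bray_curtis")
        with pytest.raises(ValueError):
            permanova(D, ["a", "a", "a", "b"], n_perm=9)


class TestAssociations:
    @staticmethod
    def null_features(rng, n=60, p=30):
        raw = rng.gamma(1.0, size=(n, p))
        ra = raw / raw.sum(axis=1, keepdims=True)
        feats = pd.DataFrame(ra, index=[f"S{i}" for i in range(n)])
        feats.columns = [f"F{i}" for i in range(p)]
        meta = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "grp": rng.choice(["u", "v"], n),
            },
            index=feats.index,
        )
        return feats, meta

    def test_perfect_signal_detected(self):
        rng = np.random.default_rng(0)
        feats, meta = self.null_features(rng)
        # arcsin(sqrt(sin^2(t))) = t for t in [0, pi/2]: the transformed
        # feature is exactly linear in x
        t = 0.1 + 0.2 * (meta["x"] - meta["x"].min())
        feats["F0"] = np.sin(np.clip(t, 0, np.pi / 2)) ** 2
        res = fit_associations(feats, meta, ["x", "grp"])
        hit = res[(res.feature_id == "F0") & (res.covariate == "x")]
        assert float(hit["p"].iloc[0]) < 1e-10
        assert bool(hit["significant"].iloc[0])

    def test_orthogonal_covariate_leaves_estimates(self):
        rng = np.random.default_rng(1)
        feats, meta = self.null_features(rng)
        meta = meta.copy()
        base = fit_associations(feats, meta, ["x"], transform="none")
        # orthogonalise a new covariate against [1, x]
        z = rng.normal(size=len(meta))
        X = np.column_stack([np.ones(len(meta)), meta["x"]])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        meta["z"] = z
        both = fit_associations(feats, meta, ["x", "z"], transform="none")
        b0 = base[base.covariate == "x"].set_index("feature_id")["coefficient"]
        b1 = both[both.covariate == "x"].set_index("feature_id")["coefficient"]
        np.testing.assert_allclose(b0, b1.loc[b0.index], atol=1e-8)

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(2)
        feats, meta = self.null_features(rng)
        meta = meta.copy()
        meta["x2"] = 2 * meta["x"]
        res = fit_associations(feats, meta, ["x", "x2"])
        assert "x2" not in set(res.covariate)

    def test_bh_matches_reference_step_up(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        # reference BH step-up
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            running = min(running, p[order[rank - 1]] * n / rank)
            adj[order[rank - 1]] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


def test_group_tests_match_scipy_conventions():
    x, y = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
    u, p = mann_whitney(x, y)
    assert u == 0.0 and p < 0.05
    h, p = kruskal_wallis(x, y, [20.0, 21.0, 22.0])
    assert h > 0 and p < 0.05
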