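from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import oracles
from srnadisc import explore


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(
        rng.integers(0, 300, size=(50, 8)),
        index=[f"m{i:03d}" for i in range(50)],
        columns=[f"s{j}" for j in range(8)],
    )
    rpm = raw / raw.sum(axis=0) * 1e6
    return raw, rpm


class TestDistinctCounts:
    def test_strictly_greater_semantics(self):
        raw = pd.DataFrame({"s": [0, 5, 11, 10]})
        table = explore.distinct_counts(raw)
        assert table.loc["s", "above_0"] == 3   # 10 counts, 10 is not > 10
        assert table.loc["s", "above_10"] == 1

    def test_all_zero_sample(self):
        raw = pd.DataFrame({"s": [0, 0, 0]})
        table = explore.distinct_counts(raw)
        assert table.loc["s", "above_0"] == 0 and table.loc["s", "above_10"] == 0

    def test_matches_brute_force_recount(self, random_matrix):
        raw, _ = random_matrix
        table = explore.distinct_counts(raw)
        for s in raw.columns:
            assert table.loc[s, "above_0"] == sum(1 for v in raw[s] if v > 0)
            assert table.loc[s, "above_10"] == sum(1 for v in raw[s] if v > 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            explore.distinct_counts(pd.DataFrame({"s": [-1, 2]}))


class TestTopCV:
    def test_ordering_matches_direct_recomputation(self, random_matrix):
        _, rpm = random_matrix
        top = explore.top_cv_features(rpm, k=200)
        direct = {}
        for f in rpm.index:
            vals = rpm.loc[f].to_numpy(dtype=float)
            if vals.mean() > 0:
                direct[f] = vals.std(ddof=1) / vals.mean()
        assert list(top.index) == sorted(
            direct, key=lambda f: (-direct[f], f)
        )
        for f in top.index:
            assert top[f] == pytest.approx(direct[f])

    def test_constant_feature_cv_zero_ranked_last(self):
        rpm = pd.DataFrame(
            [[10.0, 10.0, 10.0], [5.0, 9.0, 1.0], [7.0, 7.0, 7.0]],
            index=["constant", "varied", "constant2"],
            columns=["s1", "s2", "s3"],
        )
        top = explore.top_cv_features(rpm, k=10)
        assert list(top.index)[0] == "varied"
        assert top["constant"] == 0.0

    def test_k_larger_than_available_returns_all(self):
        rpm = pd.DataFrame(np.ones((3, 4)) * [[1.0], [2.0], [0.0]],
                           index=["a", "b", "zero"])
        rpm.loc["a", 0] = 2.0
        top = explore.top_cv_features(rpm, k=50)
        assert len(top) == 2  # the zero-mean feature is excluded


class TestScaleAndCluster:
    def test_scaled_rows_unit_variance(self, random_matrix):
        _, rpm = random_matrix
        result = explore.scale_and_cluster(rpm, list(rpm.index[:20]))
        sd = result.scaled.std(axis=1, ddof=1)
        assert np.allclose(sd, 1.0)
        assert np.allclose(result.scaled.mean(axis=1), 0.0, atol=1e-12)

    def test_constant_feature_scales_to_zeros(self):
        rpm = pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["const", "var"],
            columns=["s1", "s2", "s3"],
        )
        result = explore.scale_and_cluster(rpm, ["const", "var"])
        assert (result.scaled.loc["const"] == 0.0).all()
        assert not result.scaled.isna().any().any()

    def test_linkage_heights_match_cubic_oracle(self, random_matrix):
        _, rpm = random_matrix
        subset = list(rpm.index[:12])
        result = explore.scale_and_cluster(rpm, subset)
        expected = oracles.complete_linkage_heights(
            result.scaled.to_numpy()
        )
        assert np.allclose(sorted(result.feature_linkage[:, 2]), sorted(expected))
        expected_s = oracles.complete_linkage_heights(result.scaled.T.to_numpy())
        assert np.allclose(sorted(result.sample_linkage[:, 2]), sorted(expected_s))

    def test_identical_samples_merged_first(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 100, size=10)
        rpm = pd.DataFrame(
            {"twin1": base, "twin2": base, "other": base * rng.uniform(0.1, 3, 10)},
            index=[f"m{i}" for i in range(10)],
        )
        result = explore.scale_and_cluster(rpm, list(rpm.index))
        first_merge = result.sample_linkage[0]
        assert first_merge[2] == pytest.approx(0.0)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_single_sample_skips_clustering(self, caplog):
        import logging

        rpm = pd.DataFrame({"only": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with caplog.at_level(logging.WARNING, logger="srnadisc.explore"):
            result = explore.scale_and_cluster(rpm, ["a", "b", "c"])
        assert result.sample_linkage is None
        assert result.sample_order == ["only"]

    def test_empty_subset_rejected(self, random_matrix):
        _, rpm = random_matrix
        with pytest.raises(ValueError):
            explore.scale_and_cluster(rpm, [])


class TestOrdination:
    def test_pca_matches_eigendecomposition_oracle(self, random_matrix):
        _, rpm = random_matrix
        result = explore.ordination(rpm, seed=0)
        x = np.log2(rpm.to_numpy(dtype=float).T + 1.0)
        expected, evr = oracles.pca_scores_eig(x, 2)
        got = result.pca_scores.to_numpy()
        for j in range(2):  # compare up to sign
            col, exp = got[:, j], expected[:, j]
            assert np.allclose(col, exp, atol=1e-8) or np.allclose(col, -exp, atol=1e-8)
        assert np.allclose(result.explained_variance_ratio, evr[:2], atol=1e-10)

    def test_explained_variance_non_increasing(self, random_matrix):
        _, rpm = random_matrix
        result = explore.ordination(rpm, seed=0)
        evr = result.explained_variance_ratio
        assert evr[0] >= evr[1] and evr.sum() <= 1.0 + 1e-12

    def test_duplicated_sample_identical_scores(self, random_matrix):
        _, rpm = random_matrix
        dup = rpm.copy()
        dup["s_dup"] = dup["s0"]
        result = explore.ordination(dup, seed=0)
        assert np.allclose(result.pca_scores.loc["s0"],
                           result.pca_scores.loc["s_dup"], atol=1e-8)

    def test_separated_groups_split_on_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(100, 1000, size=40)
        cols = {}
        for j in range(4):
            cols[f"a{j}"] = base * np.exp(rng.normal(0, 0.05, 40))
        shifted = base.copy()
        shifted[:20] *= 16.0  # strong mean shift on half the features
        for j in range(4):
            cols[f"b{j}"] = shifted * np.exp(rng.normal(0, 0.05, 40))
        rpm = pd.DataFrame(cols)
        rpm = rpm / rpm.sum(axis=0) * 1e6
        result = explore.ordination(rpm, seed=0)
        pc1 = result.pca_scores["PC1"]
        a = pc1[[f"a{j}" for j in range(4)]]
        b = pc1[[f"b{j}" for j in range(4)]]
        assert a.max() < b.min() or b.max() < a.min()

    def test_tsne_deterministic_at_fixed_seed(self, random_matrix):
        _, rpm = random_matrix
        r1 = explore.ordination(rpm, seed=7)
        r2 = explore.ordination(rpm, seed=7)
        pd.testing.assert_frame_equal(r1.tsne, r2.tsne)
        assert r1.perplexity == pytest.approx(min(5.0, 7 / 3))

    def test_too_few_samples_skips_sections(self, caplog):
        import logging

        rpm = pd.DataFrame(np.ones((5, 2)), columns=["s1", "s2"])
        with caplog.at_level(logging.WARNING, logger="srnadisc.explore"):
            result = explore.ordination(rpm, seed=0)
        assert result.pca_scores is None and result.tsne is None

    def test_sample_permutation_permutes_scores(self, random_matrix):
        _, rpm = random_matrix
        perm = list(rpm.columns[::-1])
        r1 = explore.ordination(rpm, seed=0)
        r2 = explore.ordination(rpm[perm], seed=0)
        pd.testing.assert_frame_equal(
            r1.pca_scores.loc[perm], r2.pca_scores, atol=1e-8, rtol=0,
        )


def test_explore_bundle_assembles(random_matrix):
    raw, rpm = random_matrix
    bundle = explore.explore_matrix(raw, rpm, seed=3, k=20)
    assert len(bundle.top_cv) == 20
    assert bundle.heatmap_top.scaled.shape[0] == 20
    detected = (raw > 0).all(axis=1).sum()
    if detected:
        assert bundle.heatmap_all_detected.scaled.shape[0] == detected
    assert bundle.ordination.tsne is not None
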