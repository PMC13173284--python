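from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import oracles
from srnadisc import de, indfilter, synth


class TestBH:
    def test_matches_closed_form_on_random_vector(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert np.allclose(indfilter.bh_adjust(p), oracles.bh_closed_form(p))

    def test_all_equal_pvalues_unchanged(self):
        p = np.full(50, 0.03)
        assert np.allclose(indfilter.bh_adjust(p), 0.03)

    def test_nan_preserved(self):
        p = np.array([0.01, np.nan, 0.5])
        adj = indfilter.bh_adjust(p)
        assert np.isnan(adj[1]) and not np.isnan(adj[[0, 2]]).any()


@pytest.fixture(scope="module")
def constructed_instance():
    """1000 features: 100 high-abundance with tiny p, 900 low-abundance
    uniform nulls — the canonical case where filtering helps."""
    rng = np.random.default_rng(1)
    p = np.concatenate([
        np.full(100, 1e-8),
        rng.uniform(size=900),
    ])
    abundance = np.concatenate([
        np.full(100, 1000.0),
        rng.uniform(0.5, 9.5, size=900),
    ])
    return p, abundance


class TestScan:
    def test_all_p_one_gives_zero_counts(self):
        res = indfilter.scan_quantiles(np.ones(100), np.arange(100.0), alpha=0.05)
        assert set(res.counts) == {0}
        assert res.theta_star == 0.0

    def test_alpha_zero_gives_zero_counts(self, constructed_instance):
        p, a = constructed_instance
        res = indfilter.scan_quantiles(p, a, alpha=0.0)
        assert set(res.counts) == {0}

    def test_counts_match_exhaustive_oracle(self, constructed_instance):
        grid = tuple(np.round(np.arange(0.0, 0.9501, 0.05), 2))
        p, a = constructed_instance
        res = indfilter.scan_quantiles(p, a, alpha=0.05, grid=grid)
        expected = oracles.quantile_scan_counts(p, a, 0.05, grid)
        assert list(res.counts) == expected
        assert res.best_count >= res.count_at_zero
        assert res.best_count == res.counts[res.grid.index(res.theta_star)]

    def test_ties_resolve_to_smallest_theta(self):
        p = np.full(100, 1e-9)  # every theta gives the same count shape
        a = np.arange(100.0)
        res = indfilter.scan_quantiles(p, a, alpha=0.05)
        assert res.theta_star == 0.0

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            indfilter.scan_quantiles([], [], alpha=0.05)


def _design(samples, groups):
    return de.DesignSpec(samples=samples,
                         group=dict(zip(samples, groups)),
                         contrast=("GroupA", "GroupB"))


class TestFallbackRule:
    @pytest.fixture
    def straddle_setup(self):
        """Library sizes 0.5M and 2M -> T = 20 RPM; smaller group n = 4."""
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(6)]
        groups = ["GroupA"] * 4 + ["GroupB"] * 6
        lib = pd.Series([500_000] + [2_000_000] * 9, index=samples, dtype=float)
        rng = np.random.default_rng(2)
        rpm = pd.DataFrame(
            rng.uniform(0, 40, size=(50, 10)),
            index=[f"m{i}" for i in range(50)], columns=samples,
        )
        return rpm, _design(samples, groups), lib

    def test_mask_equals_hand_enumeration(self, straddle_setup):
        rpm, design, lib = straddle_setup
        mask = indfilter.fallback_prefilter(rpm, design, lib_sizes=lib)
        T = 10.0 / 0.5  # = 20 RPM
        small = [s for s in rpm.columns if s.startswith("A")]
        for feature in rpm.index:
            n_below = sum(rpm.loc[feature, s] < T for s in small)
            assert mask[feature] == (n_below < 2), feature  # ceil(4/2) = 2

    def test_all_zero_feature_dropped(self, straddle_setup):
        rpm, design, lib = straddle_setup
        rpm.loc["m0"] = 0.0
        assert not indfilter.fallback_prefilter(rpm, design, lib_sizes=lib)["m0"]

    def test_feature_above_threshold_everywhere_kept(self, straddle_setup):
        rpm, design, lib = straddle_setup
        rpm.loc["m1"] = 100.0
        assert indfilter.fallback_prefilter(rpm, design, lib_sizes=lib)["m1"]

    def test_zero_library_size_rejected(self, straddle_setup):
        rpm, design, lib = straddle_setup
        lib.iloc[0] = 0.0
        with pytest.raises(ValueError, match="library size"):
            indfilter.fallback_prefilter(rpm, design, lib_sizes=lib)

    def test_mask_invariant_under_label_permutation(self, straddle_setup):
        """The filter statistic must not depend on which side is which when
        group sizes are equal."""
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        rng = np.random.default_rng(3)
        rpm = pd.DataFrame(rng.uniform(0, 40, size=(30, 8)),
                           index=[f"m{i}" for i in range(30)], columns=samples)
        lib = pd.Series(1_000_000.0, index=samples)
        d1 = _design(samples, ["GroupA"] * 4 + ["GroupB"] * 4)
        # swapping sides swaps which group is "smaller" (tie -> side A);
        # with equal sizes the rule must inspect the same sample set
        d2 = de.DesignSpec(samples=samples,
                           group=d1.group,
                           contrast=("GroupB", "GroupA"))
        m1 = indfilter.fallback_prefilter(rpm, d1, lib_sizes=lib)
        m2 = indfilter.fallback_prefilter(rpm, d2, lib_sizes=lib)
        assert (m1 == m2).all()


class TestFilteredDE:
    def test_pure_null_uses_fallback_and_matches_mask(self):
        design = synth.SyntheticDesign(
            seed=41, n_samples_per_group=5, n_mirnas=2000, n_de=0,
            mean_count=100, dispersion=0.1, low_fraction=0.3,
        )
        counts, groups, _ = synth.make_count_matrix(design)
        spec = de.DesignSpec(samples=list(counts.columns),
                             group=groups["group"].to_dict(),
                             contrast=("GroupA", "GroupB"))
        res = indfilter.filtered_de(counts, spec, alpha=0.05)
        assert res.scan.fallback_used
        lib = counts.sum(axis=0).astype(float)
        rpm = counts / lib * 1e6
        mask = indfilter.fallback_prefilter(rpm, spec, lib_sizes=lib)
        fit = de.fit_test(counts, spec)
        expected_kept = mask & fit["PValue"].notna()
        assert (res.table["filtered"] == ~expected_kept).all()

    def test_recovery_with_filtering_beats_unfiltered(self):
        design = synth.SyntheticDesign(
            seed=42, n_samples_per_group=8, n_mirnas=2000, n_de=50,
            mean_count=200, dispersion=0.1, logfc=2.0,
            low_fraction=1500 / 1950,
        )
        counts, groups, truth = synth.make_count_matrix(design)
        spec = de.DesignSpec(samples=list(counts.columns),
                             group=groups["group"].to_dict(),
                             contrast=("GroupB", "GroupA"))
        res = indfilter.filtered_de(counts, spec, alpha=0.05)
        planted = set(truth.index[truth != 0])
        sig = set(res.table.index[res.table["FDR"] <= 0.05])
        assert len(planted & sig) / len(planted) >= 0.9
        assert res.scan.best_count >= res.scan.count_at_zero

    def test_alpha_one_everything_significant_theta_zero(self):
        design = synth.SyntheticDesign(
            seed=43, n_samples_per_group=3, n_mirnas=200, n_de=0,
            low_fraction=0.0,
        )
        counts, groups, _ = synth.make_count_matrix(design)
        spec = de.DesignSpec(samples=list(counts.columns),
                             group=groups["group"].to_dict(),
                             contrast=("GroupA", "GroupB"))
        res = indfilter.filtered_de(counts, spec, alpha=1.0)
        assert res.scan.theta_star == 0.0
        testable = res.table["PValue"].notna()
        assert (res.table.loc[testable, "FDR"] <= 1.0).all()
        assert res.scan.count_at_zero == int(testable.sum())
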