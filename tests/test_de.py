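from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from srnadisc import de, synth


def two_group_design(counts, groups, contrast=("GroupA", "GroupB"), blocking=None):
    return de.DesignSpec(
        samples=list(counts.columns),
        group=groups["group"].to_dict(),
        contrast=contrast,
        blocking=blocking,
    )


@pytest.fixture(scope="module")
def nb_dataset():
    design = synth.SyntheticDesign(
        seed=21, n_samples_per_group=4, n_mirnas=300, n_de=20,
        mean_count=150, dispersion=0.15, low_fraction=0.3,
    )
    return synth.make_count_matrix(design)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        factors = de.tmm_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({"a": base, "b": 3 * base})
        factors = de.tmm_factors(counts)
        assert np.allclose(factors, 1.0, atol=1e-8)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 300, size=(150, 6)))
        factors = de.tmm_factors(counts)
        assert np.prod(factors) ** (1 / 6) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(de.DesignError, match="b"):
            de.tmm_factors(counts)


class TestFitBasics:
    def test_identical_groups_logfc_zero(self):
        col = [50, 100, 10, 200, 5, 80] * 5
        counts = pd.DataFrame({f"s{i}": col for i in range(6)})
        groups = pd.DataFrame({"group": ["GroupA"] * 3 + ["GroupB"] * 3},
                              index=counts.columns)
        fit = de.fit_test(counts, two_group_design(counts, groups))
        assert np.allclose(fit["logFC"], 0.0, atol=1e-6)

    def test_contrast_swap_negates_logfc_keeps_p(self, nb_dataset):
        counts, groups, _ = nb_dataset
        f1 = de.fit_test(counts, two_group_design(counts, groups, ("GroupA", "GroupB")))
        f2 = de.fit_test(counts, two_group_design(counts, groups, ("GroupB", "GroupA")))
        ok = f1["logFC"].notna()
        assert np.allclose(f1.loc[ok, "logFC"], -f2.loc[ok, "logFC"], atol=1e-4)
        assert np.allclose(f1.loc[ok, "PValue"], f2.loc[ok, "PValue"], atol=1e-6)

    def test_constant_blocking_equals_no_blocking(self, nb_dataset):
        counts, groups, _ = nb_dataset
        plain = de.fit_test(counts, two_group_design(counts, groups))
        blocked = de.fit_test(
            counts,
            two_group_design(counts, groups,
                             blocking={s: "x" for s in counts.columns}),
        )
        ok = plain["PValue"].notna()
        assert np.allclose(plain.loc[ok, "PValue"], blocked.loc[ok, "PValue"],
                           atol=1e-6)

    def test_depth_scaling_leaves_p_invariant(self, nb_dataset):
        """Multiplying one sample's counts by a constant is absorbed by the
        offsets (library size x TMM factor)."""
        counts, groups, _ = nb_dataset
        scaled = counts.copy()
        scaled["A1"] = scaled["A1"] * 4
        f1 = de.fit_test(counts, two_group_design(counts, groups))
        f2 = de.fit_test(scaled, two_group_design(scaled, groups))
        ok = f1["PValue"].notna() & f2["PValue"].notna()
        # offsets absorb depth exactly only up to the TMM trimming; demand
        # close agreement rather than equality
        assert np.corrcoef(np.log10(f1.loc[ok, "PValue"] + 1e-300),
                           np.log10(f2.loc[ok, "PValue"] + 1e-300))[0, 1] > 0.99

    def test_all_zero_feature_gets_na(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(10, 100, size=(20, 6)),
                              index=[f"m{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(6)])
        counts.loc["m0"] = 0
        groups = pd.DataFrame({"group": ["GroupA"] * 3 + ["GroupB"] * 3},
                              index=counts.columns)
        fit = de.fit_test(counts, two_group_design(counts, groups))
        assert np.isnan(fit.loc["m0", "PValue"])
        assert np.isnan(fit.loc["m0", "logFC"])

    def test_confounded_blocking_rejected(self):
        counts = pd.DataFrame(np.ones((5, 4), dtype=int) * 50,
                              columns=["a", "b", "c", "d"])
        groups = pd.DataFrame({"group": ["GroupA", "GroupA", "GroupB", "GroupB"]},
                              index=counts.columns)
        blocking = {"a": "x", "b": "x", "c": "y", "d": "y"}  # == group
        with pytest.raises(de.DesignError, match="rank"):
            de.fit_test(counts, two_group_design(counts, groups, blocking=blocking))

    def test_too_few_samples_per_side_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3), dtype=int), columns=["a", "b", "c"])
        groups = pd.DataFrame({"group": ["GroupA", "GroupB", "GroupB"]},
                              index=counts.columns)
        with pytest.raises(de.DesignError, match="need >= 2"):
            de.fit_test(counts, two_group_design(counts, groups))


class TestCalibrationAndRecovery:
    def test_null_type_one_error_calibrated(self):
        design = synth.SyntheticDesign(
            seed=31, n_samples_per_group=5, n_mirnas=2000, n_de=0,
            mean_count=100, dispersion=0.1, low_fraction=0.0,
        )
        counts, groups, _ = synth.make_count_matrix(design)
        fit = de.fit_test(counts, two_group_design(counts, groups))
        p = fit["PValue"].dropna()
        assert 0.025 <= (p <= 0.05).mean() <= 0.075

    def test_planted_logfc_recovered(self):
        design = synth.SyntheticDesign(
            seed=32, n_samples_per_group=8, n_mirnas=600, n_de=100,
            mean_count=200, dispersion=0.1, logfc=2.0, low_fraction=0.0,
        )
        counts, groups, truth = synth.make_count_matrix(design)
        fit = de.fit_test(counts, two_group_design(counts, groups,
                                                   ("GroupB", "GroupA")))
        planted = truth.index[truth != 0]
        med = fit.loc[planted, "logFC"].median()
        assert med == pytest.approx(2.0, abs=0.3)

    def test_block_effect_needs_blocking_factor(self):
        """A 2x multiplier on half the samples (balanced across groups) only
        keeps the null calibrated when modeled as an additive block."""
        rng = np.random.default_rng(33)
        G, n = 1500, 4
        samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        groups = pd.DataFrame({"group": ["GroupA"] * n + ["GroupB"] * n},
                              index=samples)
        # block 'hi' = first half of each group
        block = {s: ("hi" if int(s[1:]) < n // 2 else "lo") for s in samples}
        base = rng.uniform(50, 400, size=G)
        cols = {}
        for s in samples:
            mu = base * (2.0 if block[s] == "hi" else 1.0)
            cols[s] = synth.nb_counts(rng, mu, 0.05)
        counts = pd.DataFrame(cols)
        # blocking included: calibrated
        fit_b = de.fit_test(counts, two_group_design(counts, groups, blocking=block))
        p_b = fit_b["PValue"].dropna()
        assert 0.01 <= (p_b <= 0.05).mean() <= 0.09

    def test_dispersion_recovery_order_of_magnitude(self):
        design = synth.SyntheticDesign(
            seed=34, n_samples_per_group=10, n_mirnas=800, n_de=0,
            mean_count=200, dispersion=0.2, low_fraction=0.0,
        )
        counts, groups, _ = synth.make_count_matrix(design)
        f = de.tmm_factors(counts)
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        X, _ = de.build_design_matrix(
            two_group_design(counts, groups), list(counts.columns)
        )
        y = counts.to_numpy(dtype=float)
        _, mu, _ = de._fit_glm(y, X, np.log(lib * f.to_numpy()), np.full(len(y), 0.2))
        phi = de._pearson_dispersion(y, mu, len(counts.columns) - X.shape[1])
        assert np.median(phi) == pytest.approx(0.2, rel=0.3)


@pytest.fixture(scope="module")
def cross(tmp_path_factory, nb_dataset):
    """edgeR (glmQLFit) as an independent implementation of the same model
    family, run through Rscript on the shared simulated dataset."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    counts, groups, _ = nb_dataset
    d = tmp_path_factory.mktemp("edger")
    counts.to_csv(d / "counts.csv")
    groups.to_csv(d / "groups.csv")
    script = d / "ql.R"
    script.write_text(
        'suppressMessages(library(edgeR))\n'
        f'counts <- read.csv("{d}/counts.csv", row.names=1)\n'
        f'groups <- read.csv("{d}/groups.csv", row.names=1)\n'
        'y <- DGEList(counts=counts, group=groups$group)\n'
        'y <- calcNormFactors(y)\n'
        'write.csv(data.frame(tmm=y$samples$norm.factors),'
        f' "{d}/tmm.csv", row.names=FALSE)\n'
        'design <- model.matrix(~group, data=groups)\n'
        'y <- estimateDisp(y, design)\n'
        'fit <- glmQLFit(y, design)\n'
        'res <- glmQLFTest(fit, coef=2)\n'
        'tab <- topTags(res, n=Inf, sort.by="none")$table\n'
        f'write.csv(tab, "{d}/fit.csv")\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    fit_py = de.fit_test(
        counts,
        de.DesignSpec(samples=list(counts.columns),
                      group=groups["group"].to_dict(),
                      contrast=("GroupB", "GroupA")),
    )
    return {
        "tmm_py": de.tmm_factors(counts).to_numpy(),
        "tmm_r": pd.read_csv(d / "tmm.csv")["tmm"].to_numpy(),
        "fit_py": fit_py.dropna(),
        "fit_r": pd.read_csv(d / "fit.csv", index_col=0),
    }


class TestEdgeRCrossCheck:
    """Normalization factors must agree with edgeR to near machine
    precision; inference must agree closely (not bit-identically)."""

    def test_tmm_matches_edger(self, cross):
        assert np.allclose(cross["tmm_py"], cross["tmm_r"], atol=1e-10)

    def test_logfc_agrees(self, cross):
        fr = cross["fit_r"].loc[cross["fit_py"].index]
        diff = (cross["fit_py"]["logFC"] - fr["logFC"]).abs()
        assert diff.median() < 0.01

    def test_pvalues_strongly_correlated(self, cross):
        from scipy.stats import spearmanr

        fr = cross["fit_r"].loc[cross["fit_py"].index]
        rho = spearmanr(cross["fit_py"]["PValue"], fr["PValue"]).statistic
        assert rho > 0.95
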