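"""Phenotype model, Wald screening, group clustering and Welch test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from ewescan.phenotypes import (
    aggregate_per_ewe,
    assign_groups,
    dendrogram_newick,
    fit_final_model,
    screen_covariates,
    welch_t_test,
)
from ewescan.simulate import SimulationConfig, simulate_population


def pheno_frame(bc, fec, **extra):
    n = len(bc)
    base = dict(
        ewe_id=[f"e{i}" for i in range(n)], year=2021,
        age=4.0, body_condition=bc, hours_to_estrus=24.0, n_births=3,
        fecundity=fec)
    base.update(extra)
    return pd.DataFrame(base)


class TestFinalModel:
    def test_hand_derived_least_squares(self):
        """Normal equations on (2,1),(3,1),(4,2),(5,2): slope 0.4, intercept 0.1."""
        table = pheno_frame([2, 3, 4, 5], [1, 1, 2, 2])
        fit = fit_final_model(table)
        assert fit.params["body_condition"] == pytest.approx(0.4, abs=1e-12)
        assert fit.params["const"] == pytest.approx(0.1, abs=1e-12)

    def test_constant_body_condition_gives_mean(self):
        table = pheno_frame([3, 3, 3, 3], [0, 1, 1, 2])
        fit = fit_final_model(table)
        assert fit.params["const"] == pytest.approx(1.0)
        assert "body_condition" in fit.dropped

    def test_accuracy_approaches_one_as_noise_vanishes(self):
        """Under the bare liability model (no calibrated group offsets),
        vanishing noise makes the outcome a deterministic function of body
        condition and the rounded fit classifies perfectly."""
        cfg = SimulationConfig(noise_sd=1e-4, calibrate_means=False,
                               n_chrom=1, snps_per_chrom=20,
                               planted_roh=[], planted_diff_snps=[],
                               n_low_maf_snps=0, n_hwe_violating_snps=0,
                               n_low_call_snps=0, seed=3)
        _, _, pheno, _ = simulate_population(cfg)
        fit = fit_final_model(aggregate_per_ewe(pheno))
        assert fit.accuracy == 1.0

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        bc = rng.integers(1, 6, 40)
        fec = np.clip(np.rint(0.2 + 0.3 * bc + rng.normal(0, 0.4, 40)), 0, 2)
        table = pheno_frame(bc, fec.astype(int))
        fit = fit_final_model(table)
        resid = table["fecundity"].to_numpy() - fit.fitted.to_numpy()
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * bc).sum()) < 1e-8


class TestScreening:
    def test_constant_covariate_excluded_with_warning(self):
        table = pheno_frame([2, 3, 4, 5], [1, 1, 2, 2])  # year/age/hours constant
        with pytest.warns(UserWarning, match="constant"):
            fit = screen_covariates(table)
        assert "year" not in fit.params.index

    def test_retains_true_signal_and_controls_false_positives(self):
        """Only body condition drives the outcome: screening always keeps
        it, while each pure-noise covariate is retained at about the nominal
        alpha = 0.05 false-positive rate."""
        n_rep = 40
        bc_kept = 0
        noise_kept = 0
        for s in range(n_rep):
            rng = np.random.default_rng(100 + s)
            n = 200
            bc = rng.integers(1, 6, n)
            fec = np.clip(np.rint(0.1 + 0.35 * bc + rng.normal(0, 0.3, n)), 0, 2)
            table = pheno_frame(
                bc, fec.astype(int),
                year=rng.integers(2019, 2022, n),
                age=rng.normal(4.5, 1.2, n).round(2),
                hours_to_estrus=rng.normal(24, 6, n).round(1),
                n_births=rng.integers(1, 7, n))
            fit = screen_covariates(table)
            bc_kept += "body_condition" in fit.retained
            noise_kept += len(set(fit.retained) - {"body_condition"})
        assert bc_kept == n_rep
        # 4 noise covariates x 40 replicates at alpha=0.05 -> ~8 expected
        assert noise_kept / (4 * n_rep) < 0.12

    def test_wald_p_equals_squared_z_identity(self):
        rng = np.random.default_rng(7)
        n = 60
        bc = rng.integers(1, 6, n)
        fec = np.clip(np.rint(0.3 * bc + rng.normal(0, 0.5, n)), 0, 2)
        fit = screen_covariates(pheno_frame(bc, fec.astype(int),
                                            age=rng.normal(4, 1, n)))
        for name in fit.wald.index:
            z = np.sqrt(fit.wald[name])
            assert fit.wald_p[name] == pytest.approx(2 * st.norm.sf(z), rel=1e-10)


class TestGroups:
    def test_separated_values_split_exactly(self):
        adj = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        groups = assign_groups(adj)
        assert groups.labels.tolist() == ["low", "low", "high", "high"]
        assert groups.group_means == {"high": 2.0, "low": 1.0}

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(1.0, 0.05, 10), rng.normal(2.0, 0.05, 10)])
        ids = [f"e{i}" for i in range(20)]
        adj = pd.Series(vals, index=ids)
        perm = rng.permutation(20)
        shuffled = adj.iloc[perm]
        g1 = assign_groups(adj).labels.sort_index()
        g2 = assign_groups(shuffled).labels.sort_index()
        assert g1.equals(g2)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            assign_groups(pd.Series([1.0, 1.0, 1.0], index=list("abc")))

    def test_recovers_generator_groups(self, default_sim):
        matrix, _, pheno, truth = default_sim
        fit = fit_final_model(aggregate_per_ewe(pheno))
        groups = assign_groups(fit.fitted)
        true = pd.Series(truth.true_groups)
        agree = (groups.labels.sort_index() == true.sort_index()).mean()
        assert max(agree, 1 - agree) >= 0.90  # best label permutation

    def test_dendrogram_newick_contains_all_leaves(self):
        adj = pd.Series([1.0, 1.2, 2.0, 2.1], index=list("abcd"))
        groups = assign_groups(adj)
        nwk = dendrogram_newick(groups, list(adj.index))
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk


class TestWelch:
    def test_hand_computation_with_zero_variance_group(self):
        t, df, p = welch_t_test(np.array([1, 1, 2]), np.array([1, 1, 1]))
        assert t == pytest.approx(1.0)
        assert df == pytest.approx(2.0)

    def test_identical_groups(self):
        t, df, p = welch_t_test(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert (t, p) == (0.0, 1.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            t, df, p = welch_t_test(a, b)
            ref = st.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestStudyConditions:
    def test_group_means_and_welch_power_at_n48(self):
        """Generator defaults: observed group fecundity means within 3 SE of
        the configured 1.3/1.1, and the Welch test on adjusted phenotypes
        rejects at alpha=0.05 with power >= 0.8 over 500 replicates."""
        n_rep = 500
        rejections = 0
        mean_ok = 0
        for s in range(n_rep):
            cfg = SimulationConfig(n_chrom=1, snps_per_chrom=15, planted_roh=[],
                                   planted_diff_snps=[], n_low_maf_snps=0,
                                   n_hwe_violating_snps=0, n_low_call_snps=0,
                                   seed=20_000 + s)
            _, _, pheno, truth = simulate_population(cfg)
            fit = fit_final_model(aggregate_per_ewe(pheno))
            groups = assign_groups(fit.fitted)
            if groups.p_value < 0.05:
                rejections += 1
            true = pd.Series(truth.true_groups)
            raw = pheno.merge(true.rename("g"), left_on="ewe_id", right_index=True)
            ok = True
            for g, target in (("high", 1.3), ("low", 1.1)):
                vals = raw.loc[raw["g"] == g, "fecundity"]
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                ok &= abs(vals.mean() - target) <= 3 * se
            mean_ok += ok
        assert rejections / n_rep >= 0.8
        assert mean_ok / n_rep >= 0.9  # 3-SE window should almost always hold
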