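"""z-scoring, training filters, model fitting/importance, triage, and screen
dropout metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from guidesmith.training import (apply_training_filters, fit_feature_model,
                                 lmg_importance, median_diff_vs_prevalence,
                                 screen_dropout_metrics, zscore_by_group,
                                 _group_design_columns)


def _records(lfcs_by_group):
    rows = []
    for (exp, gene), lfcs in lfcs_by_group.items():
        for i, lfc in enumerate(lfcs):
            rows.append({"experiment_id": exp, "gene_id": gene,
                         "guide_id": f"{exp}_{gene}_{i}", "lfc": lfc})
    return pd.DataFrame(rows)


class TestZscore:
    def test_two_member_group_hand_arithmetic(self):
        df = zscore_by_group(_records({("e", "g"): [-2.0, 0.0]}))
        # sample sd of {-2, 0} is sqrt(2); z = -/+ 1/sqrt(2)
        assert sorted(df["z"]) == pytest.approx([-0.7071067811865475,
                                                 0.7071067811865475])

    def test_groups_standardised(self):
        rng = np.random.default_rng(4)
        df = zscore_by_group(_records({
            ("e1", "g1"): rng.normal(-2, 1, 8).tolist(),
            ("e1", "g2"): rng.normal(3, 5, 5).tolist(),
            ("e2", "g1"): rng.normal(0, 0.2, 6).tolist()}))
        for _, grp in df.groupby(["experiment_id", "gene_id"]):
            assert grp["z"].mean() == pytest.approx(0, abs=1e-12)
            assert grp["z"].std() == pytest.approx(1)

    def test_degenerate_groups_dropped(self):
        df = zscore_by_group(_records({("e", "solo"): [-1.0],
                                       ("e", "flat"): [2.0, 2.0, 2.0],
                                       ("e", "ok"): [0.0, 1.0]}))
        assert set(df["gene_id"]) == {"ok"}

    def test_affine_invariance_within_group(self):
        lfcs = [-3.0, -1.0, 0.5, 2.0]
        a = zscore_by_group(_records({("e", "g"): lfcs}))
        b = zscore_by_group(_records({("e", "g"): [4 * x + 7 for x in lfcs]}))
        assert a["z"].tolist() == pytest.approx(b["z"].tolist())


class TestTrainingFilters:
    def test_close_offtargets_removed(self):
        df = pd.DataFrame({
            "specificity": [0.9] * 100,
            "close_offtargets": [1] * 10 + [0] * 90,
            "in_cds": [True] * 100})
        assert len(apply_training_filters(df)) == 90

    def test_non_cds_removed(self):
        df = pd.DataFrame({"specificity": [0.9, 0.9],
                           "close_offtargets": [0, 0],
                           "in_cds": [False, True]})
        assert len(apply_training_filters(df)) == 1

    def test_specificity_boundary_strict(self):
        df = pd.DataFrame({"specificity": [0.50, 0.51],
                           "close_offtargets": [0, 0],
                           "in_cds": [True, True]})
        out = apply_training_filters(df)
        assert out["specificity"].tolist() == [0.51]

    def test_all_pass_identity(self):
        df = pd.DataFrame({"specificity": [0.8, 0.7],
                           "close_offtargets": [0, 0],
                           "in_cds": [True, True], "z": [0.1, -0.2]})
        assert apply_training_filters(df).equals(df)


def lmg_oracle(df, terms, formula_lhs="z"):
    """Exhaustive average of incremental R^2 over all term orderings,
    via independent statsmodels fits."""
    shares = {t: 0.0 for t in terms}
    perms = list(itertools.permutations(terms))
    for perm in perms:
        included = []
        prev = 0.0
        for t in perm:
            included.append(t)
            r2 = smf.ols(f"{formula_lhs} ~ {' + '.join(included)}", df).fit().rsquared
            shares[t] += r2 - prev
            prev = r2
    return {t: v / len(perms) for t, v in shares.items()}


class TestModelFit:
    def _sim(self, seed=0, n=2000, rho=0.0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rho * x1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        x3 = rng.normal(size=n)
        z = 0.5 * x1 - 0.3 * x2 + 0.0 * x3 + rng.normal(size=n)
        return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "z": z})

    def test_orthogonal_predictors_importance_is_marginal_r2(self):
        df = self._sim(seed=1, n=20000, rho=0.0)
        res = fit_feature_model(df, "z ~ x1 + x2")
        m1 = smf.ols("z ~ x1", df).fit().rsquared
        m2 = smf.ols("z ~ x2", df).fit().rsquared
        assert res.shares["x1"] == pytest.approx(m1, abs=0.01)
        assert res.shares["x2"] == pytest.approx(m2, abs=0.01)

    def test_shares_sum_to_r_squared(self):
        df = self._sim(seed=2, rho=0.6)
        res = fit_feature_model(df, "z ~ x1 + x2 + x3")
        assert sum(res.shares.values()) == pytest.approx(res.r_squared, abs=1e-9)
        assert all(v >= -1e-9 for v in res.shares.values())

    def test_matches_exhaustive_ordering_oracle(self):
        df = self._sim(seed=3, n=500, rho=0.7)
        res = fit_feature_model(df, "z ~ x1 + x2 + x3")
        oracle = lmg_oracle(df, ["x1", "x2", "x3"])
        for t in oracle:
            assert res.shares[t] == pytest.approx(oracle[t], abs=1e-9)

    def test_monte_carlo_close_to_exact_for_many_groups(self):
        rng = np.random.default_rng(9)
        n, p = 800, 4
        X = rng.normal(size=(n, p))
        z = X @ np.array([0.5, 0.3, -0.2, 0.1]) + rng.normal(size=n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        df["z"] = z
        formula = "z ~ " + " + ".join(df.columns[:-1])
        y, Xd, groups = _group_design_columns(df, formula)
        exact = lmg_importance(y, Xd, groups, exact_limit=15)
        mc = lmg_importance(y, Xd, groups, exact_limit=0, n_orders=2000, seed=1)
        for t in exact:
            assert mc[t] == pytest.approx(exact[t], abs=0.01)

    def test_constant_predictor_dropped_with_warning(self, caplog):
        df = self._sim(seed=4)
        df["flat"] = 1.0
        with caplog.at_level("WARNING"):
            res = fit_feature_model(df, "z ~ x1 + flat")
        assert "flat" not in res.shares
        assert any("flat" in r.message for r in caplog.records)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(6)
        n = 5000
        df = pd.DataFrame({"efficacy": rng.uniform(0, 1, n),
                           "conservation": rng.normal(5, 4, n),
                           "tm": rng.normal(60, 5, n)})
        betas = {"efficacy": -1.2, "conservation": -0.08, "tm": 0.0}
        df["z"] = sum(b * df[k] for k, b in betas.items()) + rng.normal(size=n)
        fit = smf.ols("z ~ efficacy + conservation + tm", df).fit()
        for k, b in betas.items():
            assert abs(fit.params[k] - b) < 3 * fit.bse[k]
        res = fit_feature_model(df, "z ~ efficacy + conservation + tm")
        ranked = sorted(res.shares, key=res.shares.get, reverse=True)
        assert set(ranked[:2]) == {"efficacy", "conservation"}


class TestMedianDiff:
    def test_null_feature_near_zero(self):
        rng = np.random.default_rng(12)
        n = 4000
        df = pd.DataFrame({"z": rng.normal(size=n),
                           "feat": rng.random(n) < 0.3})
        out = median_diff_vs_prevalence(df, ["feat"])
        # bootstrap-free bound: 3 * approximate SE of a median difference
        assert abs(out.loc["feat", "median_diff"]) < 3 * 1.25 / np.sqrt(n * 0.3)
        assert out.loc["feat", "prevalence"] == pytest.approx(0.3, abs=0.03)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(13)
        n = 10000
        feat = rng.random(n) < 0.2
        z = rng.normal(size=n) - 0.5 * feat
        df = pd.DataFrame({"z": z, "feat": feat})
        out = median_diff_vs_prevalence(df, ["feat"])
        assert out.loc["feat", "median_diff"] == pytest.approx(-0.5, abs=0.06)
        assert out.loc["feat", "prevalence"] == pytest.approx(0.2, abs=0.02)

    def test_universal_feature_reported_missing(self):
        df = pd.DataFrame({"z": [0.1, -0.2, 0.3], "feat": [True] * 3})
        out = median_diff_vs_prevalence(df, ["feat"])
        assert np.isnan(out.loc["feat", "median_diff"])

    def test_prevalence_from_reference_universe(self):
        train = pd.DataFrame({"z": [0.0, 1.0], "feat": [True, False]})
        universe = pd.DataFrame({"feat": [True] * 9 + [False]})
        out = median_diff_vs_prevalence(train, ["feat"], universe=universe)
        assert out.loc["feat", "prevalence"] == pytest.approx(0.9)


def _screen():
    counts = pd.DataFrame({
        "ref1": [1000, 1000, 500, 500, 250, 250],
        "end1": [250, 250, 125, 125, 250, 250],
    }, index=[f"gd{i}" for i in range(6)])
    gene_map = pd.Series(["ESS", "ESS", "ESS", "ESS", "NEG", "NEG"],
                         index=counts.index)
    design = pd.DataFrame({"role": ["reference", "endpoint"]},
                          index=["ref1", "end1"])
    return counts, design, gene_map


class TestScreenMetrics:
    def test_global_scaling_invariance(self):
        counts, design, gene_map = _screen()
        a = screen_dropout_metrics(counts, design, gene_map, ["NEG"])
        b = screen_dropout_metrics(counts * 2, design, gene_map, ["NEG"])
        assert a.guide_lfc.tolist() == pytest.approx(b.guide_lfc.tolist())

    def test_negative_control_mass_equalised_exactly(self):
        counts, design, gene_map = _screen()
        m = screen_dropout_metrics(counts, design, gene_map, ["NEG"])
        neg = gene_map[gene_map == "NEG"].index
        masses = m.rpm.loc[neg].sum(axis=0)
        assert masses.iloc[0] == pytest.approx(masses.iloc[1], rel=0, abs=1e-9)

    def test_uniform_dropout_gene_is_hit_with_zero_cv(self):
        rpm_scale = 1.0
        counts = pd.DataFrame({
            "r": [4000, 4000, 1000, 1000],
            "e": [1000, 1000, 1000, 1000]},
            index=["a1", "a2", "n1", "n2"])
        gene_map = pd.Series(["A", "A", "NEG", "NEG"], index=counts.index)
        design = pd.DataFrame({"role": ["reference", "endpoint"]},
                              index=["r", "e"])
        m = screen_dropout_metrics(counts, design, gene_map, ["NEG"],
                                   pseudocount_rpm=0.0)
        assert m.gene_lfc["A"] == pytest.approx(-2.0)
        assert m.gene_cv["A"] == pytest.approx(0.0, abs=1e-12)
        assert bool(m.hits["A"]) is True
        assert bool(m.hits["NEG"]) is False

    def test_signed_cv_convention(self):
        # three guides with LFCs -1, -2, -3: mean -2, sd 1, CV reported 0.5
        lfcs = np.array([-1.0, -2.0, -3.0])
        ref = np.array([1000.0, 1000, 1000, 3000])
        end = np.concatenate([1000 * 2.0 ** lfcs, [3000]])
        counts = pd.DataFrame({"r": ref, "e": end},
                              index=["g1", "g2", "g3", "n1"])
        gene_map = pd.Series(["A", "A", "A", "NEG"], index=counts.index)
        design = pd.DataFrame({"role": ["reference", "endpoint"]},
                              index=["r", "e"])
        m = screen_dropout_metrics(counts, design, gene_map, ["NEG"],
                                   pseudocount_rpm=0.0)
        assert m.gene_lfc["A"] == pytest.approx(-2.0)
        assert m.gene_cv["A"] == pytest.approx(0.5)

    def test_replicates_averaged_within_role(self):
        counts = pd.DataFrame({
            "r1": [800, 200], "r2": [1200, 200],
            "e1": [500, 200], "e2": [500, 200]},
            index=["g", "n"])
        gene_map = pd.Series(["A", "NEG"], index=counts.index)
        design = pd.DataFrame(
            {"role": ["reference", "reference", "endpoint", "endpoint"]},
            index=counts.columns)
        m = screen_dropout_metrics(counts, design, gene_map, ["NEG"],
                                   pseudocount_rpm=0.0)
        assert np.isfinite(m.gene_lfc["A"])
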