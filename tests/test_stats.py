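"""Tests of the discrimination statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hookmorph.errors import AnalysisError
from hookmorph.stats import (classify_loo, equality_of_group_means,
                             fit_canonical, format_summary, kw_posthoc,
                             stepwise_select, summarize)
from hookmorph.synthetic import generate_measurements, species_presets
from hookmorph.variables import VARIABLE_NAMES


def _frame(groups: dict[str, np.ndarray], var: str = "HL") -> pd.DataFrame:
    rows = [{"species": sp, var: v} for sp, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


def _noise_frame(seed: int, sizes=(8, 4, 5)) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(sum(sizes), 14)), columns=VARIABLE_NAMES)
    df.insert(0, "species", ["a"] * sizes[0] + ["b"] * sizes[1] + ["c"] * sizes[2])
    return df


class TestSummarize:
    def test_hand_computable_triplet(self):
        s = summarize(_frame({"x": np.array([1.0, 2.0, 3.0])}))
        row = s.iloc[0]
        assert (row["mean"], row["sd"], row["low"], row["high"], row["n"]) == \
            (2.0, 1.0, 1.0, 3.0, 3)
        assert row["formatted"] == "2.00 ± 1.00 (1.00–3.00)"

    def test_published_formatting_convention(self):
        assert format_summary(18.53, 0.39, 17.77, 19.35) == \
            "18.53 ± 0.39 (17.77–19.35)"

    def test_matches_direct_formulas_on_random_data(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(10, 2, size=37)
        row = summarize(_frame({"x": vals})).iloc[0]
        assert row["mean"] == pytest.approx(vals.mean(), rel=1e-12)
        assert row["sd"] == pytest.approx(np.std(vals, ddof=1), rel=1e-12)
        assert (row["low"], row["high"]) == (vals.min(), vals.max())

    def test_single_observation_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning, match="single observation"):
            row = summarize(_frame({"x": np.array([5.0])})).iloc[0]
        assert row["sd"] == 0.0

    def test_available_cases_per_variable(self):
        df = generate_measurements(seed=5)
        df.loc[df.index[:2], "HNL"] = np.nan
        s = summarize(df)
        hl_n = s.set_index(["species", "variable"]).loc[("P. vaalense", "HL"), "n"]
        hnl_n = s.set_index(["species", "variable"]).loc[("P. vaalense", "HNL"), "n"]
        assert hl_n == 8 and hnl_n == 6


class TestKruskalWallis:
    def test_hand_computed_h_three_groups_of_two(self):
        df = _frame({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0]),
                     "c": np.array([5.0, 6.0])})
        r = kw_posthoc(df, "HL")
        assert r.H == pytest.approx(32.0 / 7.0, rel=1e-12)

    def test_identical_observations_give_zero_h_no_significance(self):
        df = _frame({"a": np.full(4, 2.5), "b": np.full(3, 2.5), "c": np.full(5, 2.5)})
        r = kw_posthoc(df, "HL")
        assert r.H == 0.0
        assert not r.significant_pairs

    def test_complete_separation_is_significant(self):
        rng = np.random.default_rng(0)
        df = _frame({"a": rng.normal(0, 1, 8), "b": rng.normal(1000, 1, 4)})
        r = kw_posthoc(df, "HL")
        assert r.pairwise[("a", "b")] < 0.05

    def test_exact_p_matches_full_enumeration_oracle(self):
        groups = {"a": np.array([3.0, 1.0, 4.0]), "b": np.array([1.5, 5.0]),
                  "c": np.array([9.0, 2.0])}
        r = kw_posthoc(_frame(groups), "HL", p_method="exact")
        # independent enumeration over all distinct orderings of the pooled
        # values into the group-size pattern
        pooled = np.concatenate(list(groups.values()))
        sizes = [len(g) for g in groups.values()]

        def h_of(parts):
            n = sum(len(p) for p in parts)
            ranks = sps.rankdata(np.concatenate(parts))
            out, start = 0.0, 0
            for p in parts:
                out += ranks[start:start + len(p)].sum() ** 2 / len(p)
                start += len(p)
            out = 12 / (n * (n + 1)) * out - 3 * (n + 1)
            _, cts = np.unique(np.concatenate(parts), return_counts=True)
            tie = 1 - (cts ** 3 - cts).sum() / (n ** 3 - n)
            return out / tie
        h_obs = h_of(list(groups.values()))
        assert r.H == pytest.approx(h_obs, rel=1e-12)
        count = total = 0
        for perm in itertools.permutations(range(len(pooled))):
            parts, start = [], 0
            for s in sizes:
                parts.append(pooled[list(perm[start:start + s])])
                start += s
            total += 1
            if h_of(parts) >= h_obs - 1e-9:
                count += 1
        assert r.p_global == pytest.approx(count / total, abs=1e-12)

    def test_dunn_variant_agrees_on_extreme_pair(self):
        rng = np.random.default_rng(1)
        df = _frame({"a": rng.normal(0, 1, 8), "b": rng.normal(50, 1, 4),
                     "c": rng.normal(100, 1, 5)})
        r = kw_posthoc(df, "HL", method="dunn")
        assert r.pairwise[("a", "c")] < 0.05  # bottom vs top ranks

    def test_empty_group_rejected(self):
        df = _frame({"a": np.array([1.0]), "b": np.array([])})
        with pytest.raises(AnalysisError):
            kw_posthoc(df, "HL")

    def test_published_separation_pattern_across_seeds(self):
        # variables whose smallest pairwise mean gap exceeds ~4.4 pooled SD
        # separate every species pair in >= 95% of seeds; DSW and OCL
        # (2.1-2.4 SD for the D. paradoxum / P. ichthyoxanthon pair) cannot
        strong = ["HL", "HNL", "PL", "ISL", "OSL", "AD", "DPL", "ICL"]
        hits = {v: 0 for v in strong}
        n_seeds = 100
        for seed in range(n_seeds):
            df = generate_measurements(seed=30_000 + seed)
            for var in strong:
                r = kw_posthoc(df, var)
                if len(r.significant_pairs) == 3:
                    hits[var] += 1
        for var in strong:
            assert hits[var] >= 0.95 * n_seeds, (var, hits[var])


class TestEqualityOfGroupMeans:
    def test_identical_means_give_unit_lambda_zero_f(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 5)
        df = _frame({sp: base.copy() for sp in "abc"})
        row = equality_of_group_means(df, ["HL"]).iloc[0]
        assert row["wilks_lambda"] == pytest.approx(1.0, rel=1e-12)
        assert row["F"] == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_for_published_group_sizes(self, preset_table):
        table = equality_of_group_means(preset_table)
        assert (table["df1"] == 2).all()
        assert (table["df2"] == 14).all()
        assert len(table) == 14

    def test_f_matches_one_way_anova_oracle(self):
        df = _noise_frame(9)
        table = equality_of_group_means(df).set_index("variable")
        for var in VARIABLE_NAMES:
            groups = [df.loc[df["species"] == sp, var] for sp in "abc"]
            f_ref, p_ref = sps.f_oneway(*groups)
            assert table.loc[var, "F"] == pytest.approx(f_ref, rel=1e-10)
            assert table.loc[var, "p"] == pytest.approx(p_ref, rel=1e-8)

    def test_lambda_f_identity_holds_exactly(self, preset_table):
        table = equality_of_group_means(preset_table)
        lam, f = table["wilks_lambda"].to_numpy(), table["F"].to_numpy()
        np.testing.assert_allclose(f, (1 - lam) / lam * (14 / 2), rtol=1e-12)

    def test_zero_variance_variable_rejected(self):
        df = _noise_frame(3)
        df["HL"] = 1.0
        with pytest.raises(AnalysisError, match="HL"):
            equality_of_group_means(df)


class TestStepwiseSelection:
    def test_dominant_variable_enters_first(self):
        df = _noise_frame(1)
        shift = {"a": 0.0, "b": 50.0, "c": 100.0}
        df["PL"] = df["PL"] + df["species"].map(shift)
        result = stepwise_select(df)
        assert result.selected[0] == "PL"
        assert result.steps.iloc[0]["action"] == "enter"

    def test_pure_noise_selects_nothing_most_often(self):
        sizes = [len(stepwise_select(_noise_frame(1000 + s)).selected)
                 for s in range(80)]
        counts = pd.Series(sizes).value_counts()
        assert counts.index[0] == 0  # empty selection is the modal outcome

    def test_first_entry_equals_largest_univariate_f(self, preset_table):
        table = equality_of_group_means(preset_table)
        best = table.sort_values("F", ascending=False).iloc[0]["variable"]
        result = stepwise_select(preset_table)
        assert result.selected[0] == best

    def test_collinear_candidate_skipped_with_warning(self, preset_table):
        df = preset_table.copy()
        df["HNL"] = 2.0 * df["HL"]  # exact within-group collinearity
        result = stepwise_select(df)
        assert not {"HL", "HNL"} <= set(result.selected)
        assert any("tolerance" in w for w in result.warnings)

    def test_f_thresholds_are_respected(self, preset_table):
        greedy = stepwise_select(preset_table, f_enter=0.0)
        strict = stepwise_select(preset_table, f_enter=1e6)
        assert len(strict.selected) == 0
        assert len(greedy.selected) >= len(stepwise_select(preset_table).selected)


class TestCanonicalFunctions:
    def test_three_groups_give_two_functions(self, preset_table):
        sw = stepwise_select(preset_table)
        model = fit_canonical(preset_table, sw.selected)
        assert model.n_functions == 2
        assert model.coefficients.shape == (len(sw.selected), 2)

    def test_two_group_direction_matches_fisher_closed_form(self):
        rng = np.random.default_rng(8)
        df = _noise_frame(8)[lambda d: d["species"] != "c"].copy()
        df["HL"] += df["species"].map({"a": 0.0, "b": 3.0})
        df["AD"] += df["species"].map({"a": 0.0, "b": -2.0})
        selected = ["HL", "AD", "PL"]
        model = fit_canonical(df, selected)
        assert model.n_functions == 1
        x = df[selected].to_numpy()
        ma = x[(df["species"] == "a").to_numpy()].mean(axis=0)
        mb = x[(df["species"] == "b").to_numpy()].mean(axis=0)
        fisher = np.linalg.solve(model.pooled_within_cov, ma - mb)
        v = model.coefficients[:, 0]
        cos = abs(fisher @ v) / (np.linalg.norm(fisher) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_scores_have_unit_pooled_within_variance(self, preset_table):
        sw = stepwise_select(preset_table)
        model = fit_canonical(preset_table, sw.selected)
        scores = model.scores(preset_table)
        ssw = 0.0
        for sp in model.species:
            s = scores[(preset_table["species"] == sp).to_numpy()]
            ssw += ((s - s.mean(axis=0)) ** 2).sum(axis=0)
        within_var = ssw / (len(preset_table) - len(model.species))
        np.testing.assert_allclose(within_var, 1.0, rtol=1e-9)

    def test_structure_matrix_entries_are_correlations(self, preset_table):
        sw = stepwise_select(preset_table)
        model = fit_canonical(preset_table, sw.selected)
        assert model.structure_matrix.shape == (14, 2)
        assert (model.structure_matrix.abs() <= 1.0 + 1e-12).all().all()

    def test_matches_sklearn_two_group_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        df = _noise_frame(12)[lambda d: d["species"] != "c"].copy()
        df["OSL"] += df["species"].map({"a": 0.0, "b": 4.0})
        selected = ["OSL", "ICL", "OCL"]
        model = fit_canonical(df, selected)
        lda = LinearDiscriminantAnalysis(solver="eigen")
        lda.fit(df[selected], df["species"])
        v, w = model.coefficients[:, 0], lda.coef_[0]
        cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-8)


class TestClassification:
    def test_widely_separated_clouds_classify_perfectly(self):
        rng = np.random.default_rng(21)
        df = _noise_frame(21)
        for var, shift in (("HL", 100.0), ("AD", -60.0)):
            df[var] += df["species"].map({"a": 0.0, "b": shift, "c": 2 * shift})
        table, scores = classify_loo(df, ["HL", "AD"])
        assert table.overall_original == 100.0
        assert table.overall_cv == 100.0
        assert int(np.trace(table.counts_original)) == len(df)

    def test_loo_assignment_equals_manual_refit_oracle(self, preset_table):
        selected = ["HL", "DSW"]
        table, per = classify_loo(preset_table, selected)
        x = preset_table[selected].to_numpy()
        labels = preset_table["species"].to_numpy()
        species = list(dict.fromkeys(labels))
        for i in (0, 5, 9, 13, 16):
            keep = np.ones(len(x), bool)
            keep[i] = False
            xs, ls = x[keep], labels[keep]
            means = {sp: xs[ls == sp].mean(axis=0) for sp in species}
            pooled = np.zeros((2, 2))
            for sp in species:
                c = xs[ls == sp] - means[sp]
                pooled += c.T @ c
            pooled /= len(xs) - len(species)
            inv = np.linalg.inv(pooled)
            d2 = {sp: (x[i] - means[sp]) @ inv @ (x[i] - means[sp])
                  for sp in species}
            expected = min(d2, key=d2.get)
            assert per.iloc[i]["predicted_cv"] == expected

    def test_assignments_invariant_under_variable_rescaling(self, preset_table):
        selected = ["HL", "PL", "DSW"]
        _, per0 = classify_loo(preset_table, selected)
        rescaled = preset_table.copy()
        rescaled["PL"] = rescaled["PL"] * 1000.0 - 77.0
        _, per1 = classify_loo(rescaled, selected)
        assert (per0["predicted"] == per1["predicted"]).all()
        assert (per0["predicted_cv"] == per1["predicted_cv"]).all()

    def test_matches_sklearn_assignments(self, preset_table):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        selected = ["HL", "DSW", "PCA"]
        _, per = classify_loo(preset_table, selected)
        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        lda.fit(preset_table[selected], preset_table["species"])
        ref = lda.predict(preset_table[selected])
        assert (per["predicted"].to_numpy() == ref).all()

    def test_tiny_group_fold_skipped_with_flag(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "species": ["a"] * 5 + ["b"] * 2,
            "HL": np.r_[rng.normal(0, 1, 5), rng.normal(30, 1, 2)],
            "PL": np.r_[rng.normal(0, 1, 5), rng.normal(-30, 1, 2)],
        })
        table, _ = classify_loo(df, ["HL", "PL"])
        assert len(table.skipped_folds) == 2  # each b-specimen's fold


class TestParameterRecovery:
    def test_summaries_recover_preset_means_at_n200(self):
        n = 200
        data = generate_measurements(n_per_species=n, seed=0)
        summary = summarize(data).set_index(["species", "variable"])
        checked = 0
        for sp, params in species_presets().items():
            for name, vp in params.variables.items():
                got = summary.loc[(sp, name), "mean"]
                se = vp.sd / np.sqrt(n)
                assert abs(got - vp.mean) < 3 * se, (sp, name)
                checked += 1
        assert checked == 42
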