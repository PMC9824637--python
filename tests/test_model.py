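"""Predictor screening, OLS fitting, LOOCV and field rank validation."""

import numpy as np
import pandas as pd
import pytest

from understory import (fit_linear_model, loocv_evaluate, normalized_rmse,
                        screen_predictors, spearman_validation)
from understory.model import load_model_json, save_model_json


def random_metric_table(rng, n=24, names=("HM_1_3", "SD_1_3", "HMEAN", "PTN")):
    data = {name: rng.uniform(0, 10, n) for name in names}
    return pd.DataFrame(data, index=[f"plot{i:02d}" for i in range(n)])


class TestScreening:
    def test_identical_metric_selected_with_r_one(self, rng):
        table = random_metric_table(rng)
        response = table["HM_1_3"].rename("LU")
        sel = screen_predictors(table, response)
        assert sel[0] == "HM_1_3"

    def test_negative_correlation_also_selected(self, rng):
        table = random_metric_table(rng)
        response = (-table["HM_1_3"]).rename("LU")
        assert "HM_1_3" in screen_predictors(table, response)

    def test_pearson_values_match_textbook_formula(self, rng):
        """Hand 5-plot table: selection agrees with a direct r computation."""
        table = pd.DataFrame({
            "A": [1.0, 2.0, 3.0, 4.0, 5.0],
            "B": [2.0, 1.0, 4.0, 3.0, 5.0],
            "C": [5.0, 1.0, 4.0, 2.0, 3.0],
        }, index=list("vwxyz"))
        y = pd.Series([1.1, 2.0, 3.2, 3.9, 5.1], index=list("vwxyz"))

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / np.sqrt((a ** 2).sum() * (b ** 2).sum())

        rs = {c: pearson(table[c].to_numpy(), y.to_numpy()) for c in table}
        # threshold 0.7 with alpha loose enough that |r| is the binding rule
        sel = screen_predictors(table, y, r_threshold=0.7, alpha=0.5)
        expect = sorted((c for c, r in rs.items() if abs(r) > 0.7),
                        key=lambda c: -abs(rs[c]))
        assert sel == expect

    def test_constant_column_skipped_with_warning(self, rng):
        table = random_metric_table(rng)
        table["FLAT"] = 1.0
        y = table["HM_1_3"].rename("LU")
        with pytest.warns(UserWarning, match="FLAT"):
            sel = screen_predictors(table, y)
        assert "FLAT" not in sel

    def test_white_noise_rarely_passes(self):
        """Independent noise at n=24 essentially never reaches |r| > 0.7."""
        hits = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            table = random_metric_table(rng)
            y = pd.Series(rng.normal(size=24), index=table.index)
            hits += bool(screen_predictors(table, y))
        assert hits / reps < 0.02

    def test_too_few_plots_rejected(self, rng):
        table = random_metric_table(rng, n=2)
        y = pd.Series([0.1, 0.2], index=table.index)
        with pytest.raises(ValueError, match="3 plots"):
            screen_predictors(table, y)


class TestFitLinearModel:
    def test_exact_linear_response_recovered(self, rng):
        table = random_metric_table(rng)
        y = (0.03 * table["HM_1_3"] + 0.1).rename("UU")
        fm = fit_linear_model(table, y, ["HM_1_3"])
        assert fm.coefficients["HM_1_3"] == pytest.approx(0.03, abs=1e-10)
        assert fm.coefficients["const"] == pytest.approx(0.1, abs=1e-10)
        assert fm.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Fixed 6-row dataset against an explicit (X'X)^-1 X'y solve."""
        table = pd.DataFrame({
            "HM_1_3": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "SD_1_3": [0.5, 1.5, 1.0, 2.5, 2.0, 3.0],
        }, index=list("abcdef"))
        y = pd.Series([0.12, 0.25, 0.31, 0.50, 0.46, 0.68], index=table.index,
                      name="LU")
        fm = fit_linear_model(table, y, ["HM_1_3", "SD_1_3"])
        X = np.column_stack([np.ones(6), table["HM_1_3"], table["SD_1_3"]])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y.to_numpy()
        np.testing.assert_allclose(fm.coefficients.to_numpy(), beta, atol=1e-12)
        resid = y.to_numpy() - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fm.standard_errors.to_numpy(), se, rtol=1e-10)
        np.testing.assert_allclose(fm.t_values.to_numpy(), beta / se, rtol=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        table = random_metric_table(rng)
        table["COPY"] = table["HM_1_3"]
        y = pd.Series(rng.normal(size=len(table)), index=table.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_model(table, y, ["HM_1_3", "COPY"])

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            table = random_metric_table(r)
            y = pd.Series(0.1 * table["HM_1_3"] + r.normal(0, 2, 24),
                          index=table.index)
            fm = fit_linear_model(table, y, ["HM_1_3", "SD_1_3"])
            assert fm.adjusted_r2 <= fm.r2 + 1e-12


class TestLoocv:
    @pytest.mark.parametrize("n_predictors", [1, 2, 3])
    def test_matches_naive_refits(self, n_predictors):
        """Hat-matrix shortcut equals n explicit refits to 1e-10."""
        rng = np.random.default_rng(n_predictors)
        names = ["HM_1_3", "SD_1_3", "HMEAN"][:n_predictors]
        table = random_metric_table(rng)
        y = pd.Series(0.05 * table["HM_1_3"] + rng.normal(0, 0.3, 24),
                      index=table.index, name="UU")
        fm = loocv_evaluate(table, y, names)
        naive = []
        for held in table.index:
            keep = table.index != held
            sub = fit_linear_model(table.loc[keep], y.loc[keep], names)
            naive.append(sub.predict(table.loc[[held]]).iloc[0])
        np.testing.assert_allclose(fm.loocv_predictions.to_numpy(),
                                   np.array(naive), atol=1e-10)
        rmse = np.sqrt(np.mean((y.to_numpy() - np.array(naive)) ** 2))
        assert fm.rmse == pytest.approx(rmse, abs=1e-10)
        assert fm.nrmse == pytest.approx(rmse / (y.max() - y.min()), abs=1e-10)

    def test_perfect_predictions_give_zero_error(self, rng):
        table = random_metric_table(rng)
        y = (0.02 * table["HM_1_3"] + 0.05).rename("UU")
        fm = loocv_evaluate(table, y, ["HM_1_3"])
        assert fm.rmse == pytest.approx(0.0, abs=1e-10)
        assert fm.nrmse == pytest.approx(0.0, abs=1e-10)

    def test_too_few_plots_rejected(self, rng):
        table = random_metric_table(rng, n=3)
        y = pd.Series([0.1, 0.3, 0.2], index=table.index)
        with pytest.raises(ValueError, match="LOOCV"):
            loocv_evaluate(table, y, ["HM_1_3"])


class TestNormalizedRmse:
    def test_half_range_example(self):
        assert normalized_rmse([0.0, 1.0], [0.5, 0.5]) == 0.5

    def test_perfect_prediction(self):
        assert normalized_rmse([0.1, 0.6, 0.3], [0.1, 0.6, 0.3]) == 0.0

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            normalized_rmse([0.5, 0.5], [0.4, 0.6])


def make_profiles(pdi_lu, pdi_uu):
    rows = []
    for i, (lu, uu) in enumerate(zip(pdi_lu, pdi_uu)):
        pid = f"plot{i:02d}"
        for stratum, val in (("FF", 0.0), ("Sh", 0.0), ("LU", lu),
                             ("UU", uu), ("Sc", 0.1)):
            rows.append({"plot_id": pid, "stratum": stratum, "z_low": 0,
                         "z_high": 1, "pdi": val})
    return pd.DataFrame(rows)


def make_trees(small_counts, mid_counts):
    rows = []
    for i, (ns, nm) in enumerate(zip(small_counts, mid_counts)):
        pid = f"plot{i:02d}"
        rows += [{"plot_id": pid, "dbh_cm": 5.0}] * ns
        rows += [{"plot_id": pid, "dbh_cm": 15.0}] * nm
        rows.append({"plot_id": pid, "dbh_cm": 40.0})  # canopy tree, neither class
    return pd.DataFrame(rows)


class TestSpearmanValidation:
    def test_identical_ranks_give_rho_one(self):
        lu = [0.1, 0.2, 0.3, 0.4, 0.5]
        uu = [0.5, 0.4, 0.3, 0.2, 0.1]
        prof = make_profiles(lu, uu)
        trees = make_trees([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        out = spearman_validation(prof, trees).set_index("stratum")
        assert out.loc["LU", "spearman_rho"] == pytest.approx(1.0)
        assert out.loc["UU", "spearman_rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        prof = make_profiles([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        trees = make_trees([9, 7, 5, 3], [20, 15, 10, 5])
        out = spearman_validation(prof, trees).set_index("stratum")
        assert out.loc["LU", "spearman_rho"] == pytest.approx(-1.0)
        assert out.loc["UU", "spearman_rho"] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        """10-plot table with ties against brute-force rank correlation."""
        lu = [0.1, 0.1, 0.3, 0.3, 0.5, 0.2, 0.4, 0.6, 0.15, 0.35]
        uu = [0.2] * 5 + [0.4] * 5
        small = [2, 2, 6, 6, 9, 4, 7, 12, 3, 6]
        mid = [5, 5, 5, 8, 8, 8, 11, 11, 11, 14]
        out = spearman_validation(make_profiles(lu, uu),
                                  make_trees(small, mid)).set_index("stratum")

        def rank_with_ties(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        def rho(a, b):
            ra, rb = rank_with_ties(a), rank_with_ties(b)
            ra, rb = ra - ra.mean(), rb - rb.mean()
            return (ra * rb).sum() / np.sqrt((ra ** 2).sum() * (rb ** 2).sum())

        assert out.loc["LU", "spearman_rho"] == pytest.approx(rho(lu, small), abs=1e-12)
        assert out.loc["UU", "spearman_rho"] == pytest.approx(rho(uu, mid), abs=1e-12)

    def test_unmatched_plot_excluded_with_warning(self):
        prof = make_profiles([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        trees = make_trees([1, 2, 3], [3, 2, 1])  # one plot missing
        with pytest.warns(UserWarning, match="plot03"):
            out = spearman_validation(prof, trees)
        assert (out["n_plots"] == 3).all()


class TestModelPersistence:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        table = random_metric_table(rng)
        y = pd.Series(0.05 * table["HM_1_3"] + rng.normal(0, 0.1, 24),
                      index=table.index, name="UU")
        fm = loocv_evaluate(table, y, ["HM_1_3", "SD_1_3"])
        save_model_json(fm, tmp_path / "m.json")
        back = load_model_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(table).to_numpy(),
                                   fm.predict(table).to_numpy(), atol=1e-12)
        assert back.nrmse == pytest.approx(fm.nrmse)
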