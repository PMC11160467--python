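"""Downstream readouts: accuracy, sex verdicts, age, weight, groups, breeds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylspan as ms
from _oracles import wilcoxon_exact_oracle


def _pred_frame(rows):
    df = pd.DataFrame(rows)
    df.index = [f"s{i}" for i in range(len(df))]
    return df


class TestAccuracyMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = ms.accuracy_metrics(y, y)
        assert out["r"] == pytest.approx(1.0)
        assert out["mae"] == 0.0

    def test_anti_correlation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = ms.accuracy_metrics(y, -y)
        assert out["r"] == pytest.approx(-1.0)

    def test_five_point_product_moment(self):
        obs = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        pred = np.array([2.0, 2.5, 2.0, 4.0, 5.0])
        # product-moment formula written out long-hand
        n = 5
        num = n * (obs * pred).sum() - obs.sum() * pred.sum()
        den = np.sqrt(n * (obs**2).sum() - obs.sum() ** 2) * np.sqrt(
            n * (pred**2).sum() - pred.sum() ** 2
        )
        out = ms.accuracy_metrics(obs, pred)
        assert out["r"] == pytest.approx(num / den, abs=1e-12)
        assert out["mae"] == pytest.approx(np.median(np.abs(obs - pred)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ms.UndefinedCorrelationError):
            ms.accuracy_metrics(np.ones(5), np.arange(5.0))


class TestWilcoxon:
    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (6, 6), (8, 8)])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert ms.wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_exact_oracle(x, y), abs=1e-12
            )


class TestSexVerdict:
    def test_exhaustive_truth_table(self):
        """All sign/significance patterns over up to 3 tissues agree
        with direct enumeration of the consistency rule."""
        cases = [(0.005, 0.1), (0.005, -0.1), (0.5, 0.1), (0.5, -0.1)]
        for n_tissues in (1, 2, 3):
            for combo in itertools.product(cases, repeat=n_tissues):
                ps = [p for p, _ in combo]
                ds = [d for _, d in combo]
                n_sig_pos = sum(p <= 0.01 and d > 0 for p, d in combo)
                n_sig_neg = sum(p <= 0.01 and d < 0 for p, d in combo)
                if n_sig_pos and not n_sig_neg:
                    expected = "+"
                elif n_sig_neg and not n_sig_pos:
                    expected = "-"
                else:
                    expected = "."
                assert ms.sex_verdict(ps, ds) == expected, combo

    def test_no_tissues_is_undecided(self):
        assert ms.sex_verdict([], []) == "."


class TestSexDifference:
    @staticmethod
    def _species_rows(species, tissue, f_vals, m_vals):
        rows = []
        for v in f_vals:
            rows.append({"species": species, "tissue": tissue,
                         "sex": "female", "predicted": v, "age_years": 1.0})
        for v in m_vals:
            rows.append({"species": species, "tissue": tissue,
                         "sex": "male", "predicted": v, "age_years": 1.0})
        return rows

    def test_consistent_female_advantage(self):
        # full separation at 6v6 gives exact p = 0.0022 <= 0.01
        rows = []
        for tissue in ("blood", "liver"):
            rows += self._species_rows("sp", tissue,
                                       [2.0, 2.1, 2.2, 2.3, 2.4, 2.5],
                                       [1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
        out = ms.sex_difference(_pred_frame(rows))
        assert out.verdicts["sp"] == "+"
        assert (out.tissues["p"] <= 0.01).all()

    def test_opposite_directions_undecided(self):
        rows = self._species_rows("sp", "blood",
                                  [2.0, 2.1, 2.2, 2.3, 2.4, 2.5],
                                  [1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
        rows += self._species_rows("sp", "liver",
                                   [1.0, 1.1, 1.2, 1.3, 1.4, 1.5],
                                   [2.0, 2.1, 2.2, 2.3, 2.4, 2.5])
        out = ms.sex_difference(_pred_frame(rows))
        assert out.verdicts["sp"] == "."

    def test_marginal_significance_undecided(self):
        # full separation at 4v4 gives exact p = 0.029 > 0.01
        rows = self._species_rows("sp", "blood",
                                  [2.0, 2.1, 2.2, 2.3],
                                  [1.0, 1.1, 1.2, 1.3])
        out = ms.sex_difference(_pred_frame(rows))
        assert out.verdicts["sp"] == "."

    def test_undersized_cells_skipped(self):
        rows = self._species_rows("sp", "blood", [2.0], [1.0, 1.1])
        out = ms.sex_difference(_pred_frame(rows), min_n=2)
        assert out.tissues.empty
        assert out.verdicts["sp"] == "."


class TestAgeAssociation:
    def test_small_strata_skipped(self):
        rows = [
            {"species": "sp", "tissue": "blood", "sex": "female",
             "predicted": v, "age_years": a}
            for v, a in [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        ]
        out = ms.age_association(_pred_frame(rows), min_n=4)
        assert out.empty

    def test_planted_trend_detected(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 10, 20)
        rows = [
            {"species": "sp", "tissue": "blood", "sex": "female",
             "predicted": 0.2 * a + rng.normal(0, 0.1), "age_years": a}
            for a in ages
        ]
        out = ms.age_association(_pred_frame(rows))
        assert len(out) == 1
        assert out.iloc[0]["r"] > 0 and out.iloc[0]["p"] < 0.05

    def test_constant_age_stratum_skipped(self):
        rows = [
            {"species": "sp", "tissue": "blood", "sex": "female",
             "predicted": float(i), "age_years": 2.0}
            for i in range(6)
        ]
        assert ms.age_association(_pred_frame(rows)).empty


class TestWeightAdjusted:
    def test_independent_weight_leaves_r_unchanged(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(0, 1, 400)
        obs = pred + rng.normal(0, 0.5, 400)
        weight = rng.normal(0, 1, 400)  # independent of both
        out = ms.weight_adjusted_analysis(obs, pred, weight)
        raw_r = stats.pearsonr(obs, pred)[0]
        assert out["adjusted_r"] == pytest.approx(raw_r, abs=0.05)

    def test_fully_mediated_signal_vanishes(self):
        rng = np.random.default_rng(1)
        weight = rng.normal(0, 1, 200)
        pred = 2.0 * weight + 1.0  # prediction is a function of weight
        obs = weight + rng.normal(0, 0.5, 200)
        out = ms.weight_adjusted_analysis(obs, pred, weight)
        assert abs(out["adjusted_r"]) < 0.15
        assert out["collinear"]

    def test_partial_correlation_matches_residual_oracle(self):
        rng = np.random.default_rng(2)
        weight = rng.normal(0, 1, 12)
        pred = 0.5 * weight + rng.normal(0, 1, 12)
        obs = 0.8 * pred + 0.3 * weight + rng.normal(0, 1, 12)
        out = ms.weight_adjusted_analysis(obs, pred, weight)
        # two-stage residual computation with explicit least squares
        b_obs = np.polyfit(weight, obs, 1)
        b_pred = np.polyfit(weight, pred, 1)
        r_obs = obs - np.polyval(b_obs, weight)
        r_pred = pred - np.polyval(b_pred, weight)
        expected = stats.pearsonr(r_obs, r_pred)[0]
        assert out["adjusted_r"] == pytest.approx(expected, abs=1e-9)


class TestGroupComparison:
    @staticmethod
    def _stratum(tissue, t_vals, c_vals):
        rows = []
        for v in t_vals:
            rows.append({"tissue": tissue, "group": "treat", "predicted": v})
        for v in c_vals:
            rows.append({"tissue": tissue, "group": "ctrl", "predicted": v})
        return rows

    def test_exchangeable_null_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 40)
        out = ms.group_comparison(
            _pred_frame(self._stratum("liver", vals[:20], vals[20:])),
            "treat", "ctrl",
        )
        # same distribution in both arms: |Z| small on average
        assert abs(out.iloc[0]["z"]) < 2.5

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(2.0, 0.3, 20)
        treat = rng.normal(2.5, 0.3, 20)
        out = ms.group_comparison(
            _pred_frame(self._stratum("liver", treat, ctrl)),
            "treat", "ctrl", expected_sign=1,
        )
        row = out.iloc[0]
        assert row["significant"] and row["z"] > 0 and row["sign_concordant"]

    def test_single_group_stratum_skipped(self):
        rows = self._stratum("liver", [1.0, 2.0], [])
        out = ms.group_comparison(_pred_frame(rows), "treat", "ctrl")
        assert out.empty


class TestAgeAccel:
    def test_residuals_orthogonal_to_age(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 20, 50)
        pred = 0.1 * ages + rng.normal(0, 1, 50)
        resid = ms.ageaccel(pred, ages)
        assert abs(resid.mean()) < 1e-9
        assert abs(stats.pearsonr(resid, ages)[0]) < 1e-9

    def test_exact_linear_fit_gives_zero_residuals(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        pred = 2 * ages + 1
        assert np.allclose(ms.ageaccel(pred, ages), 0.0, atol=1e-12)

    def test_age_independent_predictions_just_centred(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([5.0, -5.0, -5.0, 5.0])  # orthogonal to age
        assert np.allclose(ms.ageaccel(pred, ages), pred - pred.mean())

    def test_constant_age_rejected(self):
        with pytest.raises(ms.InvalidArgumentError):
            ms.ageaccel(np.arange(4.0), np.ones(4))


class TestBreedAnalysis:
    @pytest.mark.parametrize(
        "median, expected_max",
        [(6.3, 8.379), (14.6, 19.418)],
    )
    def test_derived_maximum_from_median(self, median, expected_max):
        rows = [{"breed": "b1", "predicted": 2.0},
                {"breed": "b1", "predicted": 2.2}]
        meta = pd.DataFrame(
            {"median_lifespan_years": [median], "avg_weight_g": [10_000.0]},
            index=pd.Index(["b1"], name="breed"),
        )
        table, _ = ms.breed_analysis(_pred_frame(rows), meta)
        assert table.loc["b1", "derived_max_lifespan_years"] == pytest.approx(
            expected_max, abs=1e-9
        )
        assert table.loc["b1", "n"] == 2
        assert table.loc["b1", "mean_predicted_log_lifespan"] == pytest.approx(2.1)

    def test_constant_predictions_give_null_correlation(self):
        rng = np.random.default_rng(0)
        breeds = [f"b{i}" for i in range(10)]
        rows = [{"breed": b, "predicted": 2.0} for b in breeds for _ in range(3)]
        meta = pd.DataFrame(
            {
                "median_lifespan_years": rng.uniform(6, 15, 10),
                "avg_weight_g": rng.uniform(2e3, 6e4, 10),
            },
            index=pd.Index(breeds, name="breed"),
        )
        _, corrs = ms.breed_analysis(_pred_frame(rows), meta)
        assert corrs["r_lifespan"] == 0.0

    def test_unlabelled_samples_rejected(self):
        rows = [{"breed": "", "predicted": 2.0}]
        meta = pd.DataFrame(
            {"median_lifespan_years": [8.0], "avg_weight_g": [1e4]},
            index=pd.Index(["b1"], name="breed"),
        )
        with pytest.raises(ms.InvalidArgumentError):
            ms.breed_analysis(_pred_frame(rows), meta)
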