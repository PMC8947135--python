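import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clutterflight.analysis import (ModelSpec, candidate_altitude_models,
                                    candidate_variance_models, effect_summary,
                                    first_last_paired_test, fit_lmm,
                                    levene_test, marginal_contrasts,
                                    transform_response)
from clutterflight.synthetic import BehaviorConfig, simulate_experiment


def truth_metrics(seed, n_bees=20):
    exp = simulate_experiment(BehaviorConfig(n_bees=n_bees, seed=seed),
                              observe=False)
    df = exp.truth_table()
    df["speed_change"] = 0.0
    return df


class TestTransforms:
    @pytest.mark.parametrize("metric,value,expected", [
        ("altitude_floor", 4.0, 16.0),
        ("altitude_range", 100.0, 2.0),
        ("ground_speed", 1000.0, 3.0),
        ("lateral_excursion", 27.0, 3.0),
    ])
    def test_values(self, metric, value, expected):
        assert transform_response([value], metric)[0] == pytest.approx(expected)

    def test_nonpositive_log_names_offender(self):
        with pytest.raises(ValueError, match="row 1"):
            transform_response([5.0, -1.0], "ground_speed")

    def test_unknown_metric_identity(self):
        assert transform_response([3.0], "speed_change")[0] == 3.0


class TestLevene:
    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            levene_test(np.concatenate([rng.normal(0, 1, 50),
                                        rng.normal(5, 1, 50)]),
                        np.repeat([0, 1], 50))[1] < 0.05
            for _ in range(100))
        assert rejections <= 10

    def test_alternative_usually_rejects(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            levene_test(np.concatenate([rng.normal(0, 1, 50),
                                        rng.normal(0, 3, 50)]),
                        np.repeat([0, 1], 50))[1] < 0.05
            for _ in range(100))
        assert rejections >= 90

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 2.0, 3.0], [0, 0, 0])


class TestVarianceModelSearch:
    def test_eight_models_ranked_by_reml_aic(self):
        df = truth_metrics(5)
        fits, failures = candidate_variance_models(df, "altitude_floor",
                                                   fixed="wind * direction")
        assert len(fits) + len(failures) == 8
        aics = [f.aic for _, f in fits]
        assert aics == sorted(aics)

    def test_heteroskedastic_by_height_detected(self):
        """Residual spread scaled 3x for the two tallest fields should
        pull a field_height stratification to the top."""
        rng = np.random.default_rng(7)
        df = truth_metrics(7, n_bees=40)
        scale = np.where(df.field_height >= 98, 3.0, 1.0)
        df["lateral_excursion"] = np.abs(
            10 + rng.normal(0, scale, len(df))) + 1.0
        fits, _ = candidate_variance_models(df, "lateral_excursion",
                                            fixed="wind * direction")
        best_spec, _ = fits[0]
        assert best_spec.variance_strata is not None
        assert "field_height" in best_spec.variance_strata

    def test_homoskedastic_data_prefers_parsimony(self):
        """Under homoskedastic truth the base model stays within 2 AIC of
        the winner in most replicates."""
        hits = 0
        reps = 8
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            df = truth_metrics(100 + seed)
            df["lateral_excursion"] = np.abs(10 + rng.normal(0, 1, len(df)))
            fits, _ = candidate_variance_models(df, "lateral_excursion",
                                                fixed="wind * direction")
            best_aic = fits[0][1].aic
            base_aic = next(f.aic for s, f in fits if s.variance_strata is None)
            hits += base_aic <= best_aic + 2.0
        assert hits >= int(0.8 * reps)


class TestAltitudeModelSelection:
    def test_three_fits_ranked(self):
        df = truth_metrics(11)
        ranked = candidate_altitude_models(df, "ground_speed")
        assert len(ranked) == 3
        aics = [fit.aic for _, _, fit in ranked]
        assert aics == sorted(aics)

    def test_linear_altitude_generator_prefers_continuous(self):
        """Converse recovery: speed linear in altitude with no route step
        should rank a continuous definition over the categorical one."""
        rng = np.random.default_rng(13)
        df = truth_metrics(13, n_bees=40)
        df["ground_speed"] = 200.0 + 1.5 * df["altitude_floor"] \
            + rng.normal(0, 10, len(df))
        ranked = candidate_altitude_models(df, "ground_speed")
        assert ranked[0][0] in ("floor_x_height", "obstacle")


class TestMarginalContrasts:
    def one_factor_fixture(self, rng, means=(0.0, 1.0, 3.0), n=15):
        k = len(means)
        y = np.concatenate([rng.normal(m, 1.0, n) for m in means])
        return pd.DataFrame({
            "y": y,
            "f": np.repeat([f"lv{i}" for i in range(k)], n),
            "bee_id": [f"u{i}" for i in range(k * n)],  # singleton groups
        })

    def test_matches_scipy_tukey_hsd(self, rng):
        """Balanced one-factor fixture against the textbook studentized-
        range computation (scipy.stats.tukey_hsd)."""
        df = self.one_factor_fixture(rng)
        fit = fit_lmm(df.rename(columns={"y": "speed_change"}),
                      ModelSpec("speed_change", "f", None, transform=False))
        table = marginal_contrasts(fit, "f").set_index("contrast")
        groups = [df.y[df.f == lv].to_numpy() for lv in ("lv0", "lv1", "lv2")]
        ref = stats.tukey_hsd(*groups)
        for (i, j), row in zip([(0, 1), (0, 2), (1, 2)], table.itertuples()):
            assert row.estimate == pytest.approx(
                groups[i].mean() - groups[j].mean(), abs=1e-6)
            assert row.p_adjusted == pytest.approx(ref.pvalue[i, j], abs=2e-3)

    def test_identical_means_near_zero_estimates(self, rng):
        df = self.one_factor_fixture(rng, means=(2.0, 2.0, 2.0), n=40)
        fit = fit_lmm(df.rename(columns={"y": "speed_change"}),
                      ModelSpec("speed_change", "f", None, transform=False))
        table = marginal_contrasts(fit, "f")
        assert np.all(np.abs(table.estimate) < 0.8)
        assert np.all(table.p_adjusted > 0.2)

    def test_five_levels_give_ten_rows(self, rng):
        df = self.one_factor_fixture(rng, means=(0, 1, 2, 3, 4), n=8)
        fit = fit_lmm(df.rename(columns={"y": "speed_change"}),
                      ModelSpec("speed_change", "f", None, transform=False))
        assert len(marginal_contrasts(fit, "f")) == 10

    def test_absent_factor_rejected(self, rng):
        df = self.one_factor_fixture(rng)
        fit = fit_lmm(df.rename(columns={"y": "speed_change"}),
                      ModelSpec("speed_change", "f", None, transform=False))
        with pytest.raises(ValueError):
            marginal_contrasts(fit, "nonexistent")


class TestFirstLastPairedTests:
    def make_table(self, firsts, lasts, wind="still"):
        rows = []
        for b, (f0, f1) in enumerate(zip(firsts, lasts)):
            for fl_num, v in ((1, f0), (9, f1)):
                rows.append({"bee_id": f"b{b}", "flight_number": fl_num,
                             "wind": wind, "altitude_floor": v,
                             "ground_speed": v, "lateral_excursion": v})
        return pd.DataFrame(rows)

    def test_identical_first_last(self):
        table = first_last_paired_test(self.make_table([1, 2, 3], [1, 2, 3]))
        assert np.allclose(table.t, 0.0)
        assert np.allclose(table.p, 1.0)

    def test_hand_computed_t(self):
        # differences (last - first) = [1, 2, 3] -> t = 2*sqrt(3), df 2
        table = first_last_paired_test(
            self.make_table([0, 0, 0], [1, 2, 3]),
            metric_names=("ground_speed",))
        row = table.iloc[0]
        assert row.t == pytest.approx(2 * np.sqrt(3))
        assert row.df == 2

    def test_single_bee_skipped(self):
        table = first_last_paired_test(self.make_table([0], [1]),
                                       metric_names=("ground_speed",))
        assert table.iloc[0].note.startswith("skipped")
        assert np.isnan(table.iloc[0].t)


class TestQualitativeStructure:
    def test_route_and_wind_terms_significant_on_default_truth(self):
        """The generator's injected structure shows up in the fitted
        route-definition models: route affects speed and excursion, wind
        affects excursion."""
        df = truth_metrics(2, n_bees=58)
        speed_fit = fit_lmm(df, ModelSpec("ground_speed",
                                          "route * wind * direction"))
        exc_fit = fit_lmm(df, ModelSpec("lateral_excursion",
                                        "route * wind * direction"))
        sp = speed_fit.anova().set_index("term")
        ex = exc_fit.anova().set_index("term")
        assert sp.loc["route", "p"] < 0.05
        assert ex.loc["route", "p"] < 0.05
        assert ex.loc["wind", "p"] < 0.05

    def test_effect_summary_keys_and_signs(self):
        df = truth_metrics(3, n_bees=30)
        summary = effect_summary(df)
        assert summary["speed_above_vs_within_pct"] > 0
        assert summary["excursion_above_vs_within_pct"] > 0
        assert 0.2 < summary["still_air_ground_speed_m_s"] < 0.45
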