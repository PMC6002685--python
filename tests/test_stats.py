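"""Composites, OLS machinery, the three models, and the r-to-t conversion."""

import numpy as np
import pandas as pd
import pytest

from soaekit import stats
from soaekit.calibration import reduced_cohort_config
from soaekit.synth import simulate_measurements
from soaekit.types import TASK_COLUMNS


class TestZscore:
    def test_closed_form(self):
        assert np.allclose(stats.zscore([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_unit_sample_sd(self, rng):
        z = stats.zscore(rng.normal(10, 3, size=40))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_constant_vector_names_task(self):
        with pytest.raises(ValueError, match="flanker"):
            stats.zscore([2.0, 2.0, 2.0], name="flanker")


def z_frame(**overrides):
    base = {task: [0.0] for task in TASK_COLUMNS}
    base.update({k: [v] for k, v in overrides.items()})
    return pd.DataFrame(base, index=["S1"])


class TestComposites:
    def test_zero_scores_give_zero_composites(self):
        out = stats.composite_scores(z_frame())
        assert out.loc["S1", "control"] == 0.0
        assert out.loc["S1", "working_memory"] == 0.0

    def test_unit_vectors_reproduce_loadings(self):
        out = stats.composite_scores(z_frame(flanker=1.0))
        assert out.loc["S1", "control"] == pytest.approx(0.922)
        assert out.loc["S1", "working_memory"] == 0.0
        out = stats.composite_scores(z_frame(working_memory=1.0))
        assert out.loc["S1", "working_memory"] == pytest.approx(0.999)
        assert out.loc["S1", "control"] == 0.0

    def test_cross_loadings_enter_working_memory(self):
        out = stats.composite_scores(z_frame(card_sort=1.0))
        assert out.loc["S1", "control"] == pytest.approx(0.509)
        assert out.loc["S1", "working_memory"] == pytest.approx(-0.119)

    def test_linearity(self, rng):
        z1 = pd.DataFrame(rng.normal(size=(5, 5)), columns=TASK_COLUMNS)
        z2 = pd.DataFrame(rng.normal(size=(5, 5)), columns=TASK_COLUMNS)
        combo = stats.composite_scores(2.0 * z1 + 3.0 * z2)
        parts = (2.0 * stats.composite_scores(z1)
                 + 3.0 * stats.composite_scores(z2))
        assert np.allclose(combo, parts)

    def test_salient_only_drops_small_cross_loadings(self):
        out = stats.composite_scores(z_frame(card_sort=1.0), salient_only=True)
        assert out.loc["S1", "working_memory"] == 0.0
        assert out.loc["S1", "control"] == pytest.approx(0.509)

    def test_missing_task_rejected(self):
        z = z_frame().drop(columns=["flanker"])
        with pytest.raises(ValueError, match="flanker"):
            stats.composite_scores(z)


class TestOLS:
    def test_exact_line_has_zero_residuals(self):
        x = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        fit = stats.fit_linear_model([2.0, 4.0, 6.0], x)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.se["x"] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.resid, 0.0, atol=1e-10)

    def test_intercept_only_is_mean(self):
        fit = stats.fit_linear_model([1.0, 2.0, 6.0],
                                     pd.DataFrame(index=range(3)))
        assert fit.params["intercept"] == pytest.approx(3.0)

    def test_matches_pseudoinverse_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        fit = stats.fit_linear_model(y, X)
        design = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.pinv(design) @ y
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        # residuals orthogonal to every design column
        assert np.max(np.abs(design.T @ fit.resid)) < 1e-6

    def test_t_equals_beta_over_se(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(size=25)
        fit = stats.fit_linear_model(y, X)
        assert np.allclose(fit.tvalues, fit.params / fit.se)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                          "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="collinear"):
            stats.fit_linear_model([1.0, 2.0, 3.0, 4.0], X)


@pytest.fixture(scope="module")
def sim():
    return simulate_measurements(reduced_cohort_config(seed=7), seed=7)


class TestModels:
    def test_cognitive_model_recovers_signs(self, sim):
        fit = stats.cognitive_model(sim["measurements"], sim["composites"])
        assert fit.params["control"] < 0
        assert fit.params["working_memory"] > 0
        assert np.isfinite(fit.pvalues).all()

    def test_group_model_recovers_bilingual_suppression(self, sim):
        fit = stats.group_model(sim["measurements"], sim["metadata"])
        assert fit.params["bilingual"] < 0

    def test_ear_covariate_keeps_group_sign(self, sim):
        base = stats.group_model(sim["measurements"], sim["metadata"])
        with_ear = stats.group_model(sim["measurements"], sim["metadata"],
                                     include_ear=True)
        assert np.sign(with_ear.params["bilingual"]) \
            == np.sign(base.params["bilingual"])

    def test_aoa_model_runs_within_bilinguals(self, sim):
        fit = stats.aoa_within_bilinguals_model(sim["measurements"],
                                                sim["metadata"])
        assert np.isfinite(fit.params["english_aoa"])
        assert np.isfinite(fit.pvalues["english_aoa"])
        mono_only = sim["metadata"][sim["metadata"]["group"] == "mono"]
        with pytest.raises(ValueError, match="bilingual"):
            stats.aoa_within_bilinguals_model(sim["measurements"], mono_only)

    def test_single_group_rejected(self, sim):
        meta = sim["metadata"].copy()
        meta["group"] = "mono"
        with pytest.raises(ValueError, match="two language groups"):
            stats.group_model(sim["measurements"], meta)

    def test_null_effects_yield_zero_slopes(self):
        config = reduced_cohort_config(
            seed=8, b_control=0, b_wm=0, b_interaction=0, b_group=0,
            b_baseline_level=0, residual_sd=0.0, trial_noise_sd=0.0)
        sim = simulate_measurements(config, seed=8)
        fit = stats.cognitive_model(sim["measurements"], sim["composites"])
        for term in ("control", "working_memory", "control:working_memory"):
            assert fit.params[term] == pytest.approx(0.0, abs=1e-9)

    def test_residualized_group_zero_when_fully_mediated(self):
        # all group-linked variation flows through the composites
        config = reduced_cohort_config(seed=9, b_group=0.0, residual_sd=0.0,
                                       trial_noise_sd=0.0)
        sim = simulate_measurements(config, seed=9)
        cog = stats.cognitive_model(sim["measurements"], sim["composites"])
        fit = stats.residualized_group_model(cog, sim["measurements"],
                                             sim["metadata"])
        assert abs(fit.params["bilingual"]) < 0.05

    def test_residualized_group_survives_independent_group_effect(self):
        config = reduced_cohort_config(seed=10)
        sim = simulate_measurements(config, seed=10)
        cog = stats.cognitive_model(sim["measurements"], sim["composites"])
        fit = stats.residualized_group_model(cog, sim["measurements"],
                                             sim["metadata"])
        assert fit.params["bilingual"] < 0

    def test_permuted_labels_center_group_coefficient_on_zero(self):
        config = reduced_cohort_config(seed=12)
        rng = np.random.default_rng(12)
        coefs = []
        for _ in range(30):
            sim = simulate_measurements(config, seed=int(rng.integers(2**31)))
            meta = sim["metadata"].copy()
            meta["group"] = rng.permutation(meta["group"].to_numpy())
            fit = stats.group_model(sim["measurements"], meta,
                                    aggregate="subject")
            coefs.append(fit.params["bilingual"])
        assert abs(np.mean(coefs)) < 0.15

    def test_subject_aggregation_preserves_coefficients(self, sim):
        trial = stats.group_model(sim["measurements"], sim["metadata"])
        subject = stats.group_model(sim["measurements"], sim["metadata"],
                                    aggregate="subject")
        # same estimand; estimates agree to sampling noise
        assert np.sign(trial.params["bilingual"]) \
            == np.sign(subject.params["bilingual"])
        assert subject.n == sim["metadata"]["subject_id"].nunique() \
            - (~sim["metadata"]["subject_id"]
               .isin(sim["measurements"]["subject_id"])).sum()


class TestCorrelationT:
    def test_zero_correlation_gives_zero_t(self):
        t, df = stats.correlation_t(0.0, 20)
        assert t == 0.0 and df == 18

    def test_closed_form_value(self):
        t, df = stats.correlation_t(0.5, 11)
        assert t == pytest.approx(1.7321, abs=1e-4)
        assert df == 9

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            stats.correlation_t(1.0, 10)
        with pytest.raises(ValueError):
            stats.correlation_t(0.2, 2)
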