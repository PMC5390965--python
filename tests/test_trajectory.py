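"""Spline trajectories, GLM effect sizes, reliability, windowed correlation."""

import numpy as np
import pandas as pd
import pytest

from rigc.cohort import sample_cohort
from rigc.scoring import score_cohort
from rigc.trajectory import (
    age_window_correlation,
    fit_glm,
    fit_trajectory,
    reliability_alpha,
    speed_accuracy_path,
)


def _df(ages, values, name="v"):
    return pd.DataFrame({"age": ages, name: values})


class TestSpline:
    def test_recovers_parabola_peak(self):
        ages = np.repeat(np.arange(4, 92), 3).astype(float)
        fit = fit_trajectory(_df(ages, -((ages - 25.0) ** 2)), "v", bootstrap_reps=0)
        assert abs(fit.peak_age - 25.0) <= 0.5
        assert not fit.no_unique_peak

    def test_constant_data_has_no_unique_peak(self):
        ages = np.arange(4, 92).astype(float)
        fit = fit_trajectory(_df(ages, np.ones_like(ages)), "v", bootstrap_reps=0)
        assert fit.no_unique_peak and np.isnan(fit.peak_age)

    def test_df2_limit_is_least_squares_line(self):
        """At df = 2 the smoothing spline must coincide with the
        least-squares straight line (here: exactly linear data)."""
        ages = np.arange(4, 92).astype(float)
        vals = 0.31 * ages - 2.0
        fit = fit_trajectory(_df(ages, vals), "v", spline_df=2, bootstrap_reps=0)
        line = np.polyval(np.polyfit(ages, vals, 1), fit.age_grid)
        assert np.allclose(fit.fitted, line, atol=1e-6)

    def test_insufficient_age_spread_rejected(self):
        with pytest.raises(ValueError, match="age spread"):
            fit_trajectory(_df([20.0] * 50, np.arange(50.0)), "v")

    def test_band_contains_fit(self, scored_cohort):
        fit = fit_trajectory(scored_cohort, "mean_z", bootstrap_reps=30, seed=0)
        assert (fit.ci_lower <= fit.fitted + 1e-12).all()
        assert (fit.ci_upper >= fit.fitted - 1e-12).all()

    def test_seeded_bootstrap_is_reproducible(self, scored_cohort):
        a = fit_trajectory(scored_cohort, "mean_z", bootstrap_reps=20, seed=7)
        b = fit_trajectory(scored_cohort, "mean_z", bootstrap_reps=20, seed=7)
        assert np.array_equal(a.ci_lower, b.ci_lower)


class TestPeakRecovery:
    def test_peak_age_recovered_over_ten_generator_seeds(self, task_tables):
        """With the default lifespan curve (true peak 25), the df=7 spline
        peak of mean complexity: median over seeds 1-10 in [23, 27], every
        single estimate in [20, 30]."""
        peaks = []
        for seed in range(1, 11):
            cohort = sample_cohort(3429, seed=seed)
            scores = score_cohort(cohort.table, task_tables)
            peaks.append(
                fit_trajectory(scores, "mean_z", bootstrap_reps=0, seed=seed).peak_age
            )
        assert 23 <= np.median(peaks) <= 27, peaks
        assert all(20 <= p <= 30 for p in peaks), peaks

    def test_bootstrap_band_covers_generator_truth_at_age_40(self, task_tables):
        """95% bands from case resampling should cover the generator's true
        mean complexity at age 40 in >= 90% of 50 replicate cohorts."""
        from rigc.cohort import (
            BiasProfile,
            CovariateEffects,
            LifespanCurve,
            generate_response,
        )
        from rigc.scoring import mean_complexity, score_response
        from rigc.tasks import TASKS

        curve, effects = LifespanCurve(), CovariateEffects()
        rng = np.random.default_rng(2024)
        truth_samples = []
        for _ in range(4000):
            ability = float(
                np.clip(curve.expected_ability(40.0) + rng.standard_normal() * curve.noise_sd, 0, 1)
            )
            belief = int(rng.integers(1, 7))
            zs = []
            for tid, spec in TASKS.items():
                ab = ability
                if tid == "grid":
                    ab = max(0.0, ab - effects.belief_grid_ability * belief)
                r = generate_response(spec, BiasProfile(ability=ab), rng)
                if tid == "grid":
                    r = r[0]
                zs.append(score_response(r, spec, task_tables[tid]).z)
            truth_samples.append(mean_complexity(zs)[0])
        truth = float(np.mean(truth_samples))

        covered = 0
        for rep in range(50):
            cohort = sample_cohort(400, seed=3000 + rep)
            scores = score_cohort(cohort.table, task_tables)
            fit = fit_trajectory(scores, "mean_z", bootstrap_reps=200, seed=rep)
            j = int(np.argmin(np.abs(fit.age_grid - 40.0)))
            if fit.ci_lower[j] <= truth <= fit.ci_upper[j]:
                covered += 1
        assert covered >= 45, (covered, truth)


class TestSpeedAccuracyPath:
    def test_path_matches_grid(self, scored_cohort):
        zf = fit_trajectory(scored_cohort, "mean_z", bootstrap_reps=0)
        cf = fit_trajectory(scored_cohort, "total_ct", bootstrap_reps=0)
        path = speed_accuracy_path(cf, zf)
        assert len(path) == len(zf.age_grid)
        assert path["age"].iloc[0] == zf.age_grid[0]
        assert path["age"].iloc[-1] == zf.age_grid[-1]

    def test_grid_mismatch_rejected(self, scored_cohort):
        zf = fit_trajectory(scored_cohort, "mean_z", bootstrap_reps=0)
        cf = fit_trajectory(scored_cohort, "total_ct", bootstrap_reps=0)
        cf.age_grid = cf.age_grid[:-1]
        cf.fitted = cf.fitted[:-1]
        with pytest.raises(ValueError, match="grid"):
            speed_accuracy_path(cf, zf)


class TestGlm:
    def test_perfectly_explained_dv(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "age": rng.integers(16, 80, n).astype(float),
                "education": rng.integers(1, 8, n).astype(float),
                "y": 0.0,
            }
        )
        df["y"] = 2.0 * df["education"] + 1e-8 * rng.standard_normal(n)
        res = fit_glm(df, "y", ivs=("education",))
        assert res.term("education").partial_eta_sq > 0.99

    def test_hand_computed_one_way_eta_squared(self):
        # male: five 1s, five 2s, five 3s (mean 2); female: five 3s, 4s, 5s
        # (mean 4).  SS_between = 15+15 = 30, SS_within = 10+10 = 20,
        # partial eta^2 = 30/50 = 0.6 exactly.
        male = [1.0] * 5 + [2.0] * 5 + [3.0] * 5
        female = [3.0] * 5 + [4.0] * 5 + [5.0] * 5
        df = pd.DataFrame(
            {
                "y": male + female,
                "sex": ["male"] * 15 + ["female"] * 15,
                "age": [30.0] * 30,
            }
        )
        res = fit_glm(df, "y", ivs=("sex",))
        assert res.term("C(sex)").partial_eta_sq == pytest.approx(0.6, abs=1e-9)

    def test_null_simulation_has_tiny_effect_sizes(self):
        """DV independent of every IV: all partial eta^2 below 0.01
        (n = 3000, seeds 0-4)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 3000
            df = pd.DataFrame(
                {
                    "age": rng.integers(16, 85, n).astype(float),
                    "sex": rng.choice(["male", "female"], n),
                    "education": rng.integers(1, 8, n).astype(float),
                    "field": rng.choice(["humanities", "science", "other"], n),
                    "paranormal_belief": rng.integers(1, 7, n).astype(float),
                    "y": rng.standard_normal(n),
                }
            )
            res = fit_glm(df, "y")
            assert all(t.partial_eta_sq < 0.01 for t in res.terms)

    def test_rank_deficiency_names_aliased_terms(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "age": rng.integers(16, 80, n).astype(float),
                "education": rng.integers(1, 8, n).astype(float),
                "y": rng.standard_normal(n),
            }
        )
        df["shadow"] = df["education"]
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(df, "y", ivs=("education", "shadow"))

    def test_too_few_cases_rejected(self, rng):
        df = pd.DataFrame(
            {"age": np.arange(16, 28).astype(float), "y": rng.standard_normal(12)}
        )
        with pytest.raises(ValueError, match="complete cases"):
            fit_glm(df, "y", ivs=("age",))


class TestReliability:
    def test_identical_items_alpha_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x, "c": x})
        assert reliability_alpha(df, ["a", "b", "c"]).alpha == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self, rng):
        df = pd.DataFrame(rng.standard_normal((10_000, 4)), columns=list("abcd"))
        assert abs(reliability_alpha(df, list("abcd")).alpha) < 0.05

    def test_two_item_hand_value(self):
        # var(x) = var(y) = 2.5, var(x+y) = 9 -> alpha = 2(1 - 5/9) = 8/9
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 5]})
        assert reliability_alpha(df, ["x", "y"]).alpha == pytest.approx(
            2 * (1 - 5 / 9), abs=1e-9
        )

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        base = rng.standard_normal(500)
        df = pd.DataFrame(
            {f"i{j}": base + rng.standard_normal(500) for j in range(4)}
        )
        ours = reliability_alpha(df, list(df.columns)).alpha
        theirs = pg.cronbach_alpha(data=df)[0]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="variance"):
            reliability_alpha(df, ["a", "b"])
        with pytest.raises(ValueError, match="two variables"):
            reliability_alpha(df, ["a"])


class TestAgeWindowCorrelation:
    def test_perfect_linear_pair(self):
        df = pd.DataFrame({"age": np.arange(25, 65).astype(float)})
        df["a"] = np.arange(40.0)
        df["b"] = 3 * df["a"] + 1
        r, p = age_window_correlation(df, ("a", "b"), (25, 60))
        assert r == pytest.approx(1.0)

    def test_independent_pair_near_zero(self, rng):
        n = 3000
        df = pd.DataFrame(
            {
                "age": rng.uniform(25, 60, n),
                "a": rng.standard_normal(n),
                "b": rng.standard_normal(n),
            }
        )
        r, _ = age_window_correlation(df, ("a", "b"), (25, 60))
        assert abs(r) < 0.05

    def test_empty_window_rejected(self, rng):
        df = pd.DataFrame(
            {"age": np.full(50, 70.0), "a": rng.standard_normal(50), "b": rng.standard_normal(50)}
        )
        with pytest.raises(ValueError, match="window"):
            age_window_correlation(df, ("a", "b"), (25, 60))
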