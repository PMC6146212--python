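"""Mixed-model fitting, Satterthwaite ANOVA, LS-means, and power."""

import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from balancegait.inference import (
    LmmSpec,
    anova_fixed,
    fit_lmm,
    lsmeans_ci,
    power_simulation,
    required_sample_size,
    simulate_outcomes,
)

SPEC = LmmSpec(outcome="y")


def _without_subject_effects(df):
    """Center each subject's outcomes so the fitted subject variance is
    exactly on the zero boundary (the closed-form OLS oracle applies)."""
    out = df.copy()
    out["y"] = df.y - df.groupby("subject").y.transform("mean") + df.y.mean()
    return out


def quiet_fit(df):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_lmm(df, SPEC)


class TestFitLmm:
    def test_zero_subject_variance_collapses_to_ols(self):
        df = simulate_outcomes(8, 5, direction_effect=2.0, subject_sd=0.0, resid_sd=1.0, rng=1)
        fit = quiet_fit(df)
        assert fit.singular
        cells = df.groupby(["trigger_foot", "direction"]).y.mean()
        b = dict(zip(fit.columns, fit.params))
        # sum-coded parameters reproduce every cell mean exactly
        for foot, fc in (("left", 1), ("right", -1)):
            for direction, dc in (("away", 1), ("toward", -1)):
                model_mean = (
                    b["intercept"]
                    + fc * b["trigger_foot"]
                    + dc * b["direction"]
                    + fc * dc * b["trigger_foot:direction"]
                )
                assert model_mean == pytest.approx(cells[(foot, direction)], rel=1e-9)

    def test_satterthwaite_df_matches_ols_residual_df_without_subject_variance(self):
        df = _without_subject_effects(simulate_outcomes(8, 5, subject_sd=0.0, resid_sd=1.0, rng=2))
        fit = quiet_fit(df)
        assert fit.singular
        table = anova_fixed(fit)
        assert table["den_df"].to_numpy() == pytest.approx(np.full(3, len(df) - 4), rel=1e-6)

    def test_variance_components_recovered_in_simulation(self):
        rng = np.random.default_rng(3)
        su, se = [], []
        for _ in range(40):
            df = simulate_outcomes(12, 6, subject_sd=3.0, resid_sd=5.0, rng=rng)
            fit = quiet_fit(df)
            su.append(fit.sigma_u2)
            se.append(fit.sigma_e2)
        assert np.mean(su) == pytest.approx(9.0, abs=1.5)
        assert np.mean(se) == pytest.approx(25.0, abs=1.5)

    def test_constant_outcome_rejected(self):
        df = simulate_outcomes(4, 3, rng=0)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(df, SPEC)

    def test_single_subject_rejected(self):
        df = simulate_outcomes(1, 5, rng=0)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_lmm(df, SPEC)


class TestAnovaAndLsmeans:
    def test_dominant_injected_direction_effect_has_largest_f(self):
        df = simulate_outcomes(
            10, 5, direction_effect=10.0, foot_effect=0.3, subject_sd=1.0, resid_sd=1.0, rng=4
        )
        table = anova_fixed(quiet_fit(df)).set_index("effect")
        assert table.loc["direction", "F"] == table["F"].max()
        assert table.loc["direction", "p"] < 1e-6

    def test_lsmean_ci_equals_classical_t_interval_when_variance_collapses(self):
        df = _without_subject_effects(
            simulate_outcomes(6, 8, direction_effect=3.0, subject_sd=0.0, resid_sd=2.0, rng=5)
        )
        fit = quiet_fit(df)
        assert fit.singular
        ls = lsmeans_ci(fit, "direction").set_index("level")
        resid_df = len(df) - 4
        for level in ("away", "toward"):
            sub = df[df.direction == level].y
            # classical interval with the pooled (full-model) residual variance
            fitted = df.groupby(["trigger_foot", "direction"]).y.transform("mean")
            s2 = np.sum((df.y - fitted) ** 2) / resid_df
            se = np.sqrt(s2 / len(sub))
            q = t_dist.ppf(0.975, resid_df)
            assert ls.loc[level, "mean"] == pytest.approx(sub.mean(), rel=1e-9)
            assert ls.loc[level, "upper"] - ls.loc[level, "mean"] == pytest.approx(q * se, rel=1e-6)

    def test_shift_equivariance(self):
        df = simulate_outcomes(6, 5, direction_effect=1.0, subject_sd=2.0, resid_sd=3.0, rng=6)
        ls0 = lsmeans_ci(quiet_fit(df), "direction")
        shifted = df.assign(y=df.y + 7.5)
        ls1 = lsmeans_ci(quiet_fit(shifted), "direction")
        assert ls1["mean"].to_numpy() == pytest.approx(ls0["mean"].to_numpy() + 7.5, abs=1e-6)
        w0 = (ls0["upper"] - ls0["lower"]).to_numpy()
        w1 = (ls1["upper"] - ls1["lower"]).to_numpy()
        # widths agree to the optimizer's variance-ratio tolerance
        assert w1 == pytest.approx(w0, rel=1e-5)

    def test_significance_flag_iff_ci_excludes_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            df = simulate_outcomes(
                5, 4, direction_effect=rng.uniform(0, 4), grand_mean=rng.uniform(-2, 2),
                subject_sd=1.0, resid_sd=2.0, rng=rng,
            )
            for _, row in lsmeans_ci(quiet_fit(df), "direction").iterrows():
                assert row["significant"] == (row["lower"] > 0 or row["upper"] < 0)
                assert row["lower"] <= row["mean"] <= row["upper"]


class TestAgainstR:
    def test_matches_lmertest_and_emmeans(self, tmp_path):
        """Variance components, Type-III F with Satterthwaite df, and
        LS-mean CIs agree with R's lmerTest/emmeans on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not found on PATH")
        df = simulate_outcomes(6, 4, direction_effect=2.0, foot_effect=0.5,
                               subject_sd=2.0, resid_sd=3.0, rng=42)
        data_csv = tmp_path / "data.csv"
        out_csv = tmp_path / "r_out.csv"
        df.to_csv(data_csv, index=False)
        rcode = f"""
        suppressMessages({{library(lmerTest); library(emmeans)}})
        d <- read.csv("{data_csv}")
        d$trigger_foot <- factor(d$trigger_foot); d$direction <- factor(d$direction)
        contrasts(d$trigger_foot) <- contr.sum(2); contrasts(d$direction) <- contr.sum(2)
        m <- lmer(y ~ trigger_foot * direction + (1|subject), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        a <- anova(m, type=3)
        em <- summary(emmeans(m, ~direction, lmer.df="satterthwaite"))
        out <- data.frame(
          sigma_u2 = vc$vcov[1], sigma_e2 = vc$vcov[2],
          F_dir = a["direction", "F value"], df_dir = a["direction", "DenDF"],
          em_away = em$emmean[em$direction=="away"],
          em_away_lo = em$lower.CL[em$direction=="away"],
          em_away_hi = em$upper.CL[em$direction=="away"],
          em_df = em$df[em$direction=="away"])
        write.csv(out, "{out_csv}", row.names=FALSE)
        """
        script = tmp_path / "check.R"
        script.write_text(rcode)
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=120)
        r = pd.read_csv(out_csv).iloc[0]

        fit = quiet_fit(df)
        assert fit.sigma_u2 == pytest.approx(r.sigma_u2, rel=1e-4)
        assert fit.sigma_e2 == pytest.approx(r.sigma_e2, rel=1e-4)
        table = anova_fixed(fit).set_index("effect")
        assert table.loc["direction", "F"] == pytest.approx(r.F_dir, rel=1e-4)
        assert table.loc["direction", "den_df"] == pytest.approx(r.df_dir, rel=1e-3)
        ls = lsmeans_ci(fit, "direction").set_index("level")
        assert ls.loc["away", "mean"] == pytest.approx(r.em_away, rel=1e-5)
        assert ls.loc["away", "lower"] == pytest.approx(r.em_away_lo, rel=1e-3)
        assert ls.loc["away", "upper"] == pytest.approx(r.em_away_hi, rel=1e-3)
        assert ls.loc["away", "df"] == pytest.approx(r.em_df, rel=1e-2)


class TestPower:
    def test_null_effect_power_near_alpha(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = power_simulation(0.0, n_subjects=8, n_per_cell=5, n_sims=200, seed=0)
        # binomial 99% band around 5% with n=200
        assert pw / 100 == pytest.approx(0.05, abs=2.58 * np.sqrt(0.05 * 0.95 / 200))

    def test_huge_effect_saturates_power(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = power_simulation(
                20 * np.sqrt(3.0**2 + 5.0**2), n_subjects=5, n_per_cell=4, n_sims=30, seed=1
            )
        assert pw == 100.0

    def test_power_monotone_in_subjects_with_paired_seeds(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            powers = [
                power_simulation(3.5, n, n_per_cell=4, subject_sd=2.0, resid_sd=5.0,
                                 n_sims=60, seed=11)
                for n in (3, 6, 12)
            ]
        assert powers[0] <= powers[1] + 5 and powers[1] <= powers[2] + 5
        assert powers[2] > powers[0]

    def test_required_sample_size_scans_upward(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n = required_sample_size(
                6.0, target_power=80.0, n_per_cell=4, subject_sd=1.0, resid_sd=4.0,
                n_sims=40, seed=2, n_max=20,
            )
        assert n is not None and 2 <= n <= 20

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(-1.0, 5)
        with pytest.raises(ValueError):
            required_sample_size(0.0)
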