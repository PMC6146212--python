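"""Mixed-effects statistics on outcome tables and simulation-based power.

The model is a linear mixed model with two two-level fixed factors
(*trigger foot* and *perturbation direction*), their interaction, and a
random intercept per subject, fitted by REML.  Factors use sum-to-zero
(+1/-1) coding, so each fixed effect has one numerator degree of freedom
and the F tests are Type III.  Denominator degrees of freedom use the
Satterthwaite approximation, computed from the closed-form REML
likelihood of the random-intercept model; the Kenward-Roger and
Satterthwaite approximations agree on the near-balanced designs this
package produces, and the approximation used is recorded in the result
metadata.  Least-squares means are reported with 95% confidence
intervals; an effect is flagged significant when its CI excludes zero.
p-values are reported but de-emphasized: with mixed models they rest on
approximate reference distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_lmm",
    "anova_fixed",
    "lsmeans_ci",
    "simulate_outcomes",
    "power_simulation",
    "required_sample_size",
]


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: outcome column, the two fixed factors, their
    interaction, and a random subject intercept."""

    outcome: str
    foot_factor: str = "trigger_foot"
    direction_factor: str = "direction"
    interaction: bool = True
    group: str = "subject"


@dataclass
class LmmFit:
    """A fitted random-intercept LMM with the pieces inference needs."""

    spec: LmmSpec
    params: np.ndarray  # beta for [intercept, foot, direction, interaction]
    cov_params: np.ndarray
    sigma_u2: float  # subject-intercept variance
    sigma_e2: float  # residual variance
    columns: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    levels: dict[str, tuple[str, str]]  # factor -> (level coded +1, level coded -1)
    converged: bool
    singular: bool
    df_approximation: str = "satterthwaite"

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def residual_df(self) -> float:
        return self.n_obs - self.X.shape[1]


def _design(df: pd.DataFrame, spec: LmmSpec):
    """Sum-to-zero coded design matrix for intercept + foot + direction
    (+ interaction)."""
    levels = {}
    codes = {}
    for factor in (spec.foot_factor, spec.direction_factor):
        vals = sorted(df[factor].astype(str).unique())
        if len(vals) != 2:
            raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {vals}")
        levels[factor] = (vals[0], vals[1])
        codes[factor] = np.where(df[factor].astype(str) == vals[0], 1.0, -1.0)
    cols = [np.ones(len(df)), codes[spec.foot_factor], codes[spec.direction_factor]]
    names = ["intercept", spec.foot_factor, spec.direction_factor]
    if spec.interaction:
        cols.append(codes[spec.foot_factor] * codes[spec.direction_factor])
        names.append(f"{spec.foot_factor}:{spec.direction_factor}")
    return np.column_stack(cols), names, levels


def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    blocks = []
    for g in pd.unique(groups):
        sel = groups == g
        blocks.append((X[sel], y[sel]))
    return blocks


def _reml_pieces(theta, blocks):
    """Sufficient statistics of the random-intercept REML likelihood.

    theta = (sigma_u^2, sigma_e^2).  Returns (XtVinvX, XtVinvy, quad_fun,
    logdetV) where quad_fun(beta) gives the GLS residual quadratic form.
    """
    su2, se2 = theta
    p = blocks[0][0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdetV = 0.0
    yty = 0.0
    parts = []
    for Xi, yi in blocks:
        ni = len(yi)
        lam = su2 / (se2 + ni * su2)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtVX += (Xi.T @ Xi - lam * np.outer(sx, sx)) / se2
        XtVy += (Xi.T @ yi - lam * sx * sy) / se2
        yty += (yi @ yi - lam * sy * sy) / se2
        logdetV += (ni - 1) * np.log(se2) + np.log(se2 + ni * su2)
        parts.append((sx, sy))
    return XtVX, XtVy, yty, logdetV


def _reml_loglik(theta, blocks) -> float:
    su2, se2 = theta
    if se2 <= 0 or su2 < 0:
        return -np.inf
    XtVX, XtVy, yty, logdetV = _reml_pieces(theta, blocks)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
        sign, logdetXVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
    except np.linalg.LinAlgError:
        return -np.inf
    quad = yty - XtVy @ beta
    n = sum(len(yi) for _, yi in blocks)
    p = blocks[0][0].shape[1]
    return -0.5 * (logdetV + logdetXVX + quad + (n - p) * np.log(2 * np.pi))


def _beta_cov(theta, blocks):
    XtVX, XtVy, _, _ = _reml_pieces(theta, blocks)
    C = np.linalg.inv(XtVX)
    return C @ XtVy, C


def _profile_reml(blocks):
    """Maximize the REML likelihood over the variance ratio.

    With V = sigma_e^2 (I + rho Z Z'), the residual variance profiles out
    analytically, leaving a 1-D optimization in rho = sigma_u^2/sigma_e^2
    that is robust on and off the rho=0 boundary.
    """
    n = sum(len(yi) for _, yi in blocks)
    p = blocks[0][0].shape[1]

    def profiled(rho):
        XtWX, XtWy, yty, logdetW = _reml_pieces((rho, 1.0), blocks)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
            sign, logdetXWX = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return np.inf, None
        except np.linalg.LinAlgError:
            return np.inf, None
        quad = max(yty - XtWy @ beta, 1e-300)
        se2 = quad / (n - p)
        # negative profiled REML log-likelihood (constants dropped)
        nll = 0.5 * (logdetW + logdetXWX + (n - p) * (1.0 + np.log(se2)))
        return nll, se2

    def objective(log_rho):
        return profiled(np.exp(log_rho))[0]

    res = minimize_scalar(objective, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(np.exp(res.x))
    nll_opt, se2_opt = profiled(rho)
    nll_zero, se2_zero = profiled(0.0)
    if nll_zero <= nll_opt:
        rho, se2 = 0.0, se2_zero
    else:
        se2 = se2_opt
    return rho * se2, se2


def fit_lmm(df: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """REML fit of the random-intercept model.

    The variance components are estimated by maximizing the closed-form
    profiled REML likelihood of the random-intercept model (a 1-D
    optimization in the variance ratio, well-behaved on the zero-variance
    boundary); the fixed-effect estimates and covariance follow by GLS at
    those estimates.  A singular (zero) subject variance is reported with
    a warning and the fit retained.
    """
    for col in (spec.outcome, spec.foot_factor, spec.direction_factor, spec.group):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    data = df.dropna(subset=[spec.outcome]).reset_index(drop=True)
    y = data[spec.outcome].to_numpy(dtype=float)
    if len(data[spec.group].unique()) < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; the model is degenerate")
    X, names, levels = _design(data, spec)
    groups = data[spec.group].to_numpy()

    blocks = _group_blocks(X, y, groups)
    sigma_u2, sigma_e2 = _profile_reml(blocks)
    converged = np.isfinite(sigma_e2) and sigma_e2 > 0
    singular = sigma_u2 < 1e-8 * max(sigma_e2, 1e-12)
    if singular:
        warnings.warn("subject-intercept variance is (near) zero; fit retained", stacklevel=2)

    beta, cov = _beta_cov((max(sigma_u2, 0.0), sigma_e2), blocks)
    return LmmFit(
        spec=spec,
        params=beta,
        cov_params=cov,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        columns=names,
        X=X,
        y=y,
        groups=groups,
        levels=levels,
        converged=converged,
        singular=singular,
    )


def satterthwaite_df(fit: LmmFit, contrast) -> float:
    """Satterthwaite denominator df for the variance of a contrast c'beta.

    df = 2 f(theta)^2 / Var(f(theta)), f(theta) = c' C(theta) c, with the
    variance of the REML variance-component estimates taken from the
    numerical Hessian of the closed-form REML log-likelihood.  Falls back
    to the OLS residual df when the subject variance is on the boundary.
    """
    c = np.asarray(contrast, dtype=float)
    blocks = _group_blocks(fit.X, fit.y, fit.groups)
    theta = np.array([max(fit.sigma_u2, 0.0), fit.sigma_e2])
    resid_df = fit.residual_df
    if fit.singular:
        return float(resid_df)

    def f(th):
        _, C = _beta_cov(th, blocks)
        return float(c @ C @ c)

    steps = 1e-4 * np.maximum(theta, 1e-8)
    grad = np.zeros(2)
    for j in range(2):
        e = np.zeros(2)
        e[j] = steps[j]
        grad[j] = (f(theta + e) - f(np.maximum(theta - e, 0.0))) / (steps[j] + min(theta[j], steps[j]))
    # Hessian of the REML log-likelihood by central differences
    H = np.zeros((2, 2))
    hsteps = 1e-3 * np.maximum(theta, 1e-8)
    ll0 = _reml_loglik(theta, blocks)
    for j in range(2):
        for k in range(j, 2):
            ej, ek = np.zeros(2), np.zeros(2)
            ej[j], ek[k] = hsteps[j], hsteps[k]
            if j == k:
                val = (_reml_loglik(theta + ej, blocks) - 2 * ll0 + _reml_loglik(theta - ej, blocks)) / hsteps[j] ** 2
            else:
                val = (
                    _reml_loglik(theta + ej + ek, blocks)
                    - _reml_loglik(theta + ej - ek, blocks)
                    - _reml_loglik(theta - ej + ek, blocks)
                    + _reml_loglik(theta - ej - ek, blocks)
                ) / (4 * hsteps[j] * hsteps[k])
            H[j, k] = H[k, j] = val
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float(resid_df)
    var_f = float(grad @ A @ grad)
    if var_f <= 0 or not np.isfinite(var_f):
        return float(resid_df)
    df = 2.0 * f(theta) ** 2 / var_f
    return float(np.clip(df, 1.0, resid_df))


def anova_fixed(fit: LmmFit) -> pd.DataFrame:
    """Type-III F table for the fixed effects with Satterthwaite df.

    With sum-to-zero coding each effect is a single contrast, so
    F = t^2 with 1 numerator df.
    """
    rows = []
    for j, name in enumerate(fit.columns):
        if name == "intercept":
            continue
        c = np.zeros(len(fit.columns))
        c[j] = 1.0
        se = float(np.sqrt(fit.cov_params[j, j]))
        den_df = satterthwaite_df(fit, c)
        F = float((fit.params[j] / se) ** 2)
        p = float(f_dist.sf(F, 1, den_df))
        rows.append({"effect": name, "num_df": 1, "den_df": den_df, "F": F, "p": p})
    return pd.DataFrame(rows)


def lsmeans_ci(fit: LmmFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Least-squares means per level of ``factor`` with 95% CIs.

    The marginal mean of a level fixes that factor's code and averages
    over the other factor, zeroing its main effect and the interaction.
    Flagged significant when the CI excludes zero.
    """
    if factor not in fit.levels:
        raise ValueError(f"unknown factor {factor!r}; have {list(fit.levels)}")
    j = fit.columns.index(factor)
    rows = []
    for level, code in zip(fit.levels[factor], (1.0, -1.0)):
        c = np.zeros(len(fit.columns))
        c[0] = 1.0
        c[j] = code
        mean = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        df = satterthwaite_df(fit, c)
        q = float(t_dist.ppf(1 - alpha / 2, df))
        lower, upper = mean - q * se, mean + q * se
        rows.append(
            {
                "level": level,
                "mean": mean,
                "lower": lower,
                "upper": upper,
                "df": df,
                "significant": bool(lower > 0 or upper < 0),
            }
        )
    return pd.DataFrame(rows)


def simulate_outcomes(
    n_subjects: int,
    n_per_cell: int,
    direction_effect: float = 0.0,
    foot_effect: float = 0.0,
    interaction_effect: float = 0.0,
    grand_mean: float = 0.0,
    subject_sd: float = 3.0,
    resid_sd: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Balanced synthetic outcome table from the random-intercept model.

    ``direction_effect`` is the away-minus-toward difference (and likewise
    ``foot_effect`` for left minus right), matching the +1/-1 coding used
    by the fit (half the difference lands on each level).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    u = rng.normal(0.0, subject_sd, size=n_subjects)
    for s in range(n_subjects):
        for foot, fc in (("left", 1.0), ("right", -1.0)):
            for direction, dc in (("away", 1.0), ("toward", -1.0)):
                mu = (
                    grand_mean
                    + 0.5 * foot_effect * fc
                    + 0.5 * direction_effect * dc
                    + 0.5 * interaction_effect * fc * dc
                    + u[s]
                )
                yvals = mu + rng.normal(0.0, resid_sd, size=n_per_cell)
                for yv in yvals:
                    rows.append(
                        {
                            "subject": f"S{s + 1:02d}",
                            "trigger_foot": foot,
                            "direction": direction,
                            "y": yv,
                        }
                    )
    return pd.DataFrame(rows)


def power_simulation(
    effect_size: float,
    n_subjects: int,
    n_per_cell: int = 10,
    subject_sd: float = 3.0,
    resid_sd: float = 5.0,
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    effect: str = "direction",
) -> float:
    """Monte-Carlo power (percent) for detecting a direction effect.

    Simulates balanced outcome tables with the given effect size (in
    outcome units, as the between-direction difference), refits the LMM
    and tests the effect at ``alpha``; power is the fraction of
    significant replicates.  ``effect_size`` must be positive; use
    0 indirectly via the calibration tests only.
    """
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = LmmSpec(outcome="y")
    hits = 0
    for _ in range(n_sims):
        df = simulate_outcomes(
            n_subjects,
            n_per_cell,
            direction_effect=effect_size,
            subject_sd=subject_sd,
            resid_sd=resid_sd,
            rng=rng,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(df, spec)
            table = anova_fixed(fit)
        p = float(table.loc[table["effect"] == effect, "p"].iloc[0])
        hits += p < alpha
    return 100.0 * hits / n_sims


def null_calibration(
    n_refits: int = 500,
    n_subjects: int = 10,
    n_per_cell: int = 5,
    grand_mean: float = 1.0,
    subject_sd: float = 2.0,
    resid_sd: float = 4.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Type-I error and LS-mean CI coverage under the null generator.

    Simulates outcome tables with no direction effect, refits the LMM
    each time, and reports (a) the fraction of direction-effect tests
    rejecting at ``alpha`` and (b) the fraction of LS-mean CIs covering
    the true marginal mean.
    """
    rng = np.random.default_rng(seed)
    spec = LmmSpec(outcome="y")
    rejections = 0
    covered = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_refits):
            df = simulate_outcomes(
                n_subjects,
                n_per_cell,
                direction_effect=0.0,
                grand_mean=grand_mean,
                subject_sd=subject_sd,
                resid_sd=resid_sd,
                rng=rng,
            )
            fit = fit_lmm(df, spec)
            table = anova_fixed(fit)
            p = float(table.loc[table["effect"] == "direction", "p"].iloc[0])
            rejections += p < alpha
            ls = lsmeans_ci(fit, "direction", alpha=alpha)
            row = ls[ls["level"] == "toward"].iloc[0]
            covered += row["lower"] <= grand_mean <= row["upper"]
    return rejections / n_refits, covered / n_refits


def required_sample_size(
    effect_size: float,
    target_power: float = 95.0,
    n_start: int = 2,
    n_max: int = 40,
    **kwargs,
) -> int | None:
    """Smallest number of subjects reaching ``target_power`` percent,
    scanning N upward; None if not reached by ``n_max``."""
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    for n in range(n_start, n_max + 1):
        if power_simulation(effect_size, n, **kwargs) >= target_power:
            return n
    return None
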