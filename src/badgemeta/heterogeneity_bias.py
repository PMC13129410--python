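"""Heterogeneity decomposition, prediction intervals, and small-study-effects tests.

Multilevel I^2 expresses each variance component as a share of the total
variance (heterogeneity plus a "typical" sampling variance v_bar), so the
level-wise values sum exactly to the total.  Prediction intervals widen the
confidence interval of the pooled mean by the total heterogeneity and give
the range in which the true effect of a new, comparable study is expected.
The small-study test regresses effect size on a precision moderator (the
inverse square root of the effective sample size, or the standard error)
inside the full phylogenetic multilevel model; the slope measures funnel
asymmetry and the intercept is the mean adjusted to infinite precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta_engine import MetaDataset, ModelFit, reml_fit, wald_inference

MODERATOR_KINDS = ("inv_sqrt_n_eff", "se_of_z", "se_of_r")


def typical_sampling_variance(v) -> float:
    """Typical (weight-based) sampling variance v_bar for multilevel I^2.

    v_bar = (k-1) * sum(w) / ((sum w)^2 - sum(w^2)), w_i = 1/v_i; it reduces
    to the common value when variances are homogeneous and always lies within
    [min v, max v].
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 effects")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((len(v) - 1) * sw / (sw**2 - (w**2).sum()))


def i2_multilevel(fit: ModelFit, v_bar: float) -> tuple[dict[str, float], float]:
    """Percent heterogeneity per random level and in total.

    I2_level = 100 * s2_level / (sum s2 + v_bar); the level values sum to the
    total by construction.
    """
    total_s2 = fit.sigma2_total
    denom = total_s2 + v_bar
    by_level = {name: 100.0 * s2 / denom for name, s2 in fit.sigma2.items()}
    return by_level, 100.0 * total_s2 / denom


def prediction_interval(fit: ModelFit, level: float = 0.95) -> tuple[float, float]:
    """Prediction interval for a new true effect: beta +- crit*sqrt(SE^2 + sum s2)."""
    if fit.p != 1:
        raise ValueError("prediction interval is defined for the intercept-only fit")
    alpha = 1.0 - level
    if fit.inference == "t":
        crit = stats.t.ppf(1 - alpha / 2, max(fit.k - fit.p, 1))
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
    half = crit * math.sqrt(fit.se[0] ** 2 + fit.sigma2_total)
    b = float(fit.beta[0])
    return b - half, b + half


def r2_marginal(fit: ModelFit) -> float:
    """Percent of variance explained by the fixed-effect moderators.

    R^2 = 100 * var(X beta) / (var(X beta) + sum s2_random); intercept-only
    fits have no moderator and raise.
    """
    if fit.p < 2 and np.allclose(np.var(fit.fitted), 0):
        raise ValueError("no moderator: R2_marginal needs a non-intercept fixed effect")
    s2_fixed = float(np.var(fit.fitted, ddof=1))
    denom = s2_fixed + fit.sigma2_total
    return 100.0 * s2_fixed / denom if denom > 0 else 0.0


@dataclass
class SmallStudyResult:
    """Funnel-asymmetry slope and the precision-adjusted mean."""

    moderator_kind: str
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    adjusted_mean: float
    adjusted_ci: tuple[float, float]
    adjusted_p: float
    r2_marginal: float
    fit: ModelFit

    def to_dict(self) -> dict:
        return {
            "moderator_kind": self.moderator_kind,
            "slope": self.slope, "slope_ci": list(self.slope_ci),
            "slope_p": self.slope_p,
            "adjusted_mean": self.adjusted_mean,
            "adjusted_ci": list(self.adjusted_ci), "adjusted_p": self.adjusted_p,
            "r2_marginal": self.r2_marginal,
        }


def small_study_moderator(dataset: MetaDataset, kind: str) -> np.ndarray:
    """Precision moderator per effect.

    ``inv_sqrt_n_eff``: sqrt(1/n_eff) with n_eff = 4*n1*n2/(n1+n2) for
    two-group effects and n otherwise; ``se_of_r``: sqrt(v_i); ``se_of_z``:
    sqrt(1/(n-3)), the Fisher-z standard error.
    """
    if kind not in MODERATOR_KINDS:
        raise ValueError(f"unknown moderator kind {kind!r}; choose from {MODERATOR_KINDS}")
    if kind == "inv_sqrt_n_eff":
        x = np.sqrt(1.0 / dataset.n_eff)
    elif kind == "se_of_r":
        x = np.sqrt(dataset.v)
    else:
        n = dataset.n_eff
        if np.any(n <= 3):
            raise ValueError("se_of_z moderator needs n > 3 for every effect")
        x = np.sqrt(1.0 / (n - 3))
    if np.var(x) == 0:
        raise ValueError("precision moderator is constant across effects")
    return x


def small_study_test(dataset: MetaDataset, moderator_kind: str = "inv_sqrt_n_eff",
                     seed: int = 0, level: float = 0.95,
                     inference: str = "z") -> SmallStudyResult:
    """Phylogenetic multilevel meta-regression on a precision moderator.

    The slope tests funnel asymmetry (small-study effects); the intercept is
    the meta-analytic mean extrapolated to infinite precision, i.e. adjusted
    for the asymmetry.
    """
    x = small_study_moderator(dataset, moderator_kind)
    X = np.column_stack([np.ones(dataset.k), x])
    fit = reml_fit(dataset.y, X, dataset.sampling_vcv, dataset.random_design(),
                   seed=seed, coef_names=["intercept", moderator_kind],
                   n_studies=dataset.n_studies, n_species=dataset.n_species,
                   inference=inference)
    table = wald_inference(fit, level=level)
    intercept, slope = table.iloc[0], table.iloc[1]
    return SmallStudyResult(
        moderator_kind=moderator_kind,
        slope=float(slope["estimate"]),
        slope_ci=(float(slope["ci_lower"]), float(slope["ci_upper"])),
        slope_p=float(slope["p"]),
        adjusted_mean=float(intercept["estimate"]),
        adjusted_ci=(float(intercept["ci_lower"]), float(intercept["ci_upper"])),
        adjusted_p=float(intercept["p"]),
        r2_marginal=r2_marginal(fit),
        fit=fit,
    )


def funnel_data(dataset: MetaDataset, moderator_kind: str = "inv_sqrt_n_eff"
                ) -> pd.DataFrame:
    """Effect, moderator value, and precision per effect, for external plotting."""
    x = small_study_moderator(dataset, moderator_kind)
    return pd.DataFrame({
        "effect_id": dataset.moderators["effect_id"],
        "r": dataset.y,
        "moderator": x,
        "precision": 1.0 / np.sqrt(dataset.v),
    })
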