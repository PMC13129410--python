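"""Phylogenetic multilevel random-effects meta-analysis by REML.

The model for the vector of correlation-scale effects y (length k) is

    y = X beta + u_study + u_species + u_phylo + u_unit + e,

with marginal covariance

    Sigma(theta) = V + s2_study Zs Zs' + s2_species Zp Zp'
                 + s2_phylo Zp A Zp' + s2_unit I,

where V is the known sampling variance-covariance matrix (per-effect
variances on the diagonal, rho*sqrt(vi*vj) between effects of the same
study), A the phylogenetic correlation matrix, and Zs/Zp the study and
species incidence matrices.  Variance components are estimated by restricted
maximum likelihood, maximizing

    l(theta) = -1/2 [ log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r ] + const,

with r = y - X beta_hat(theta), over log-variances with quasi-Newton
iterations and seeded multi-start; a log parameterization maps the common
boundary solutions (components at zero) to -inf, which the optimizer
approaches smoothly and which are snapped to zero on report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import PhyloCorrelation
from .effect_sizes import EffectSizeRecord

_LOG_S2_MIN, _LOG_S2_MAX = -30.0, 4.0
_SNAP_TOL = 1e-8

#: random-effect levels, in model order
LEVELS = ("study", "species", "phylogeny", "unit")


def build_sampling_vcv(v: np.ndarray, study_ids, rho: float = 0.5) -> np.ndarray:
    """Block sampling VCV: diagonal v_i, off-diagonal rho*sqrt(v_i v_j) within study."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    study_ids = np.asarray(study_ids)
    same = study_ids[:, None] == study_ids[None, :]
    sd = np.sqrt(v)
    V = rho * np.outer(sd, sd) * same
    np.fill_diagonal(V, v)
    return V


@dataclass
class MetaDataset:
    """Effect sizes with grouping labels and the sampling VCV."""

    y: np.ndarray
    v: np.ndarray
    study_ids: np.ndarray
    species: np.ndarray
    n_eff: np.ndarray                       # effective sample size per effect
    sampling_vcv: np.ndarray
    moderators: pd.DataFrame
    phylo_corr: PhyloCorrelation | None = None
    rho: float = 0.5

    def __post_init__(self) -> None:
        k = len(self.y)
        if self.sampling_vcv.shape != (k, k):
            raise ValueError("sampling VCV dimension must equal the number of effects")
        if not np.allclose(np.diag(self.sampling_vcv), self.v):
            raise ValueError("VCV diagonal must equal the per-effect variances")

    @property
    def k(self) -> int:
        return len(self.y)

    @property
    def n_studies(self) -> int:
        return len(set(self.study_ids.tolist()))

    @property
    def n_species(self) -> int:
        return len(set(self.species.tolist()))

    @classmethod
    def from_records(cls, records: list[EffectSizeRecord],
                     phylo_corr: PhyloCorrelation | None = None,
                     rho: float = 0.5) -> "MetaDataset":
        if not records:
            raise ValueError("no effect records")
        y = np.array([r.r for r in records])
        v = np.array([r.v for r in records])
        study = np.array([r.study_id for r in records])
        species = np.array([r.species for r in records])
        n_eff = np.array([_effective_n(r) for r in records], dtype=float)
        vcv = build_sampling_vcv(v, study, rho=rho)
        mods = pd.DataFrame({
            "origin": [r.origin.value for r in records],
            "effect_id": [r.effect_id for r in records],
        })
        return cls(y=y, v=v, study_ids=study, species=species, n_eff=n_eff,
                   sampling_vcv=vcv, moderators=mods, phylo_corr=phylo_corr, rho=rho)

    def random_design(self) -> dict[str, np.ndarray]:
        """k-by-k covariance kernel G for each random level (unit variance)."""
        same_study = (self.study_ids[:, None] == self.study_ids[None, :]).astype(float)
        same_species = (self.species[:, None] == self.species[None, :]).astype(float)
        out = {"study": same_study, "species": same_species}
        if self.phylo_corr is not None:
            out["phylogeny"] = self.phylo_corr.submatrix(list(self.species))
        out["unit"] = np.eye(self.k)
        return out


def _effective_n(rec: EffectSizeRecord) -> float:
    """Effective sample size: harmonic-style 4*n1*n2/(n1+n2) for two-group designs."""
    if rec.n_dark and rec.n_light:
        return 4.0 * rec.n_dark * rec.n_light / (rec.n_dark + rec.n_light)
    if rec.n_total:
        return float(rec.n_total)
    raise ValueError(f"effect {rec.effect_id}: no sample size available")


@dataclass
class ModelFit:
    """REML fit: fixed effects, variance components, and the REML log-likelihood."""

    beta: np.ndarray
    se: np.ndarray
    vcov_beta: np.ndarray
    sigma2: dict[str, float]
    loglik_reml: float
    converged: bool
    k: int
    p: int
    n_studies: int
    n_species: int
    coef_names: list[str]
    fitted: np.ndarray = field(repr=False, default=None)
    inference: str = "z"

    @property
    def sigma2_total(self) -> float:
        return float(sum(self.sigma2.values()))


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the best parameters found."""

    def __init__(self, message: str, sigma2: dict[str, float]):
        super().__init__(message)
        self.sigma2 = sigma2


def _chol_with_jitter(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor with escalating PSD jitter (1e-10 -> 1e-6) on failure."""
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            J = S if jitter == 0.0 else S + jitter * np.mean(np.diag(S)) * np.eye(len(S))
            return np.linalg.cholesky(J), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix not positive definite even with jitter")


def _reml_quantities(y, X, Sigma):
    """Cholesky-based REML log-likelihood pieces for a given Sigma."""
    L, _ = _chol_with_jitter(Sigma)
    logdet_S = 2.0 * np.sum(np.log(np.diag(L)))
    Si_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Si_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    XtSiX = X.T @ Si_X
    XtSiy = X.T @ Si_y
    Lx = np.linalg.cholesky(XtSiX)
    beta = np.linalg.solve(Lx.T, np.linalg.solve(Lx, XtSiy))
    logdet_XtSiX = 2.0 * np.sum(np.log(np.diag(Lx)))
    r = y - X @ beta
    Si_r = Si_y - Si_X @ beta
    quad = float(r @ Si_r)
    k, p = X.shape
    ll = -0.5 * ((k - p) * math.log(2 * math.pi) + logdet_S + logdet_XtSiX + quad)
    vcov_beta = np.linalg.inv(XtSiX)
    return ll, beta, vcov_beta, Si_r, Si_X, XtSiX


def reml_fit(y: np.ndarray, X: np.ndarray, sampling_vcv: np.ndarray,
             components: dict[str, np.ndarray],
             fixed_sigma2: dict[str, float] | None = None,
             n_starts: int = 3, seed: int = 0,
             coef_names: list[str] | None = None,
             n_studies: int | None = None, n_species: int | None = None,
             inference: str = "z") -> ModelFit:
    """Fit the multilevel model by REML over log-variance components.

    ``components`` maps level names to k-by-k unit-variance covariance kernels
    (see :meth:`MetaDataset.random_design`); ``fixed_sigma2`` pins selected
    components (e.g. all to 0 for the fixed-effect/GLS limit).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    k, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    fixed_sigma2 = dict(fixed_sigma2 or {})
    free_names = [name for name in components if name not in fixed_sigma2]
    Gs_free = [components[name] for name in free_names]
    base = sampling_vcv + sum(
        fixed_sigma2[name] * components[name] for name in fixed_sigma2
    ) if fixed_sigma2 else sampling_vcv

    def sigma_of(theta):
        S = base.copy()
        for t, G in zip(theta, Gs_free):
            S += math.exp(t) * G
        return S

    def nll_grad(theta):
        S = sigma_of(theta)
        ll, beta, vcov_beta, Si_r, Si_X, XtSiX = _reml_quantities(y, X, S)
        L, _ = _chol_with_jitter(S)
        Si = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(k)))
        B = np.linalg.solve(XtSiX, Si_X.T)          # (X'S^-1X)^-1 X'S^-1
        grad = np.empty(len(theta))
        for i, (t, G) in enumerate(zip(theta, Gs_free)):
            s2 = math.exp(t)
            tr_P_G = np.trace(Si @ G) - np.einsum("ij,ji->", Si_X @ B, G)
            quad = Si_r @ G @ Si_r
            dll_ds2 = -0.5 * (tr_P_G - quad)
            grad[i] = -dll_ds2 * s2                 # minimize; chain rule for log s2
        return -ll, grad

    if not free_names:
        ll, beta, vcov_beta, *_ = _reml_quantities(y, X, base)
        se = np.sqrt(np.diag(vcov_beta))
        return ModelFit(beta=beta, se=se, vcov_beta=vcov_beta,
                        sigma2=dict(fixed_sigma2), loglik_reml=ll, converged=True,
                        k=k, p=p, n_studies=n_studies or 0, n_species=n_species or 0,
                        coef_names=coef_names or [f"b{i}" for i in range(p)],
                        fitted=X @ beta, inference=inference)

    rng = np.random.default_rng(seed)
    # starts: spread the residual weighted variance across components
    w = 1.0 / np.diag(sampling_vcv)
    resid_var = max(float(np.var(y)) - 1.0 / np.mean(w), 1e-4)
    starts = [np.full(len(free_names), math.log(resid_var / max(len(free_names), 1)))]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.log(resid_var) + rng.uniform(-4, 1, size=len(free_names)))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(_LOG_S2_MIN, _LOG_S2_MAX)] * len(free_names),
            options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sigma2 = {name: (0.0 if math.exp(t) < _SNAP_TOL else math.exp(t))
              for name, t in zip(free_names, theta)}
    sigma2.update(fixed_sigma2)
    sigma2 = {name: sigma2[name] for name in components}

    grad_norm = float(np.max(np.abs(best.jac)))
    at_bound = np.any(theta <= _LOG_S2_MIN + 1e-6)
    converged = bool(best.success or grad_norm < 1e-5 or at_bound)
    if not converged and not best.success and grad_norm > 1e-2:
        raise ConvergenceError(
            f"REML did not converge (gradient norm {grad_norm:.2e})", sigma2)

    S = sigma_of(theta)
    ll, beta, vcov_beta, *_ = _reml_quantities(y, X, S)
    se = np.sqrt(np.diag(vcov_beta))
    return ModelFit(beta=beta, se=se, vcov_beta=vcov_beta, sigma2=sigma2,
                    loglik_reml=ll, converged=converged, k=k, p=p,
                    n_studies=n_studies or 0, n_species=n_species or 0,
                    coef_names=coef_names or [f"b{i}" for i in range(p)],
                    fitted=X @ beta, inference=inference)


def reml_loglik(y, X, sampling_vcv, components, sigma2: dict[str, float]) -> float:
    """REML log-likelihood at fixed variance components (for oracle checks)."""
    S = sampling_vcv + sum(sigma2[name] * G for name, G in components.items())
    ll, *_ = _reml_quantities(np.asarray(y, float), np.atleast_2d(np.asarray(X, float)),
                              S)
    return ll


def fit_intercept_model(dataset: MetaDataset, seed: int = 0,
                        fixed_sigma2: dict[str, float] | None = None,
                        inference: str = "z", n_starts: int = 3) -> ModelFit:
    """Intercept-only phylogenetic multilevel model (the overall-mean fit)."""
    X = np.ones((dataset.k, 1))
    return reml_fit(dataset.y, X, dataset.sampling_vcv, dataset.random_design(),
                    fixed_sigma2=fixed_sigma2, seed=seed, coef_names=["intercept"],
                    n_studies=dataset.n_studies, n_species=dataset.n_species,
                    inference=inference, n_starts=n_starts)


def design_matrix(dataset: MetaDataset, moderator: str
                  ) -> tuple[np.ndarray, list[str], bool]:
    """Design matrix for a uni-moderator meta-regression.

    Categorical moderators are coded without an intercept so coefficients are
    per-level means; real moderators get an intercept plus slope.
    """
    col = dataset.moderators[moderator]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.unique().tolist())
        if len(levels) < 2:
            raise ValueError(f"moderator {moderator!r} has a single level")
        X = np.column_stack([(col == lev).to_numpy(float) for lev in levels])
        return X, [str(l) for l in levels], True
    x = col.to_numpy(float)
    if np.var(x) == 0:
        raise ValueError(f"moderator {moderator!r} is constant")
    return np.column_stack([np.ones_like(x), x]), ["intercept", moderator], False


def meta_regression(dataset: MetaDataset, moderator: str, seed: int = 0,
                    inference: str = "z") -> ModelFit:
    """Uni-moderator phylogenetic multilevel meta-regression."""
    X, names, _ = design_matrix(dataset, moderator)
    return reml_fit(dataset.y, X, dataset.sampling_vcv, dataset.random_design(),
                    seed=seed, coef_names=names, n_studies=dataset.n_studies,
                    n_species=dataset.n_species, inference=inference)


def wald_inference(fit: ModelFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient estimate, CI, test statistic and two-sided p-value.

    Normal reference by default; ``fit.inference == "t"`` uses a t reference
    with k - p degrees of freedom as a small-sample sensitivity.
    """
    if not fit.converged:
        raise ValueError("inference requires a converged fit")
    alpha = 1.0 - level
    if fit.inference == "t":
        df = max(fit.k - fit.p, 1)
        crit = stats.t.ppf(1 - alpha / 2, df)
        pvals = 2 * stats.t.sf(np.abs(fit.beta / fit.se), df)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
        pvals = 2 * stats.norm.sf(np.abs(fit.beta / fit.se))
    return pd.DataFrame({
        "coef": fit.coef_names,
        "estimate": fit.beta,
        "se": fit.se,
        "ci_lower": fit.beta - crit * fit.se,
        "ci_upper": fit.beta + crit * fit.se,
        "stat": fit.beta / fit.se,
        "p": pvals,
    })


def cochran_q(y: np.ndarray, v: np.ndarray, X: np.ndarray | None = None
              ) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test against the fixed-effect(s) fit.

    Q = sum w_i (y_i - x_i' beta_FE)^2 with w_i = 1/v_i and beta_FE the
    weighted least-squares fit; df = k - p; p-value from chi-square(df).
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if X is None:
        X = np.ones((len(y), 1))
    X = np.atleast_2d(np.asarray(X, float))
    k, p = X.shape
    if k <= p:
        raise ValueError("Q test needs more effects than fixed-effect parameters")
    w = 1.0 / v
    XtWX = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ beta
    Q = float(np.sum(w * resid**2))
    df = k - p
    return Q, df, float(stats.chi2.sf(Q, df))
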