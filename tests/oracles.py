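"""Independent oracles for the REML engine.

The grid oracle maximizes the same REML log-likelihood by brute force (coarse
grid over variance components, then Nelder-Mead refinement on the raw
variance scale) and never touches the engine's quasi-Newton path.
"""

import itertools

import numpy as np
from scipy import optimize

from badgemeta.meta_engine import reml_loglik


def grid_reml_oracle(y, X, V, components, n_grid: int = 24, refine: bool = True):
    """Brute-force REML maximum: (loglik, sigma2 dict)."""
    names = list(components)
    grid = [0.0] + list(np.logspace(-6, 0.7, n_grid))
    best_ll, best_theta = -np.inf, None
    for combo in itertools.product(grid, repeat=len(names)):
        ll = reml_loglik(y, X, V, components, dict(zip(names, combo)))
        if ll > best_ll:
            best_ll, best_theta = ll, np.array(combo)
    if not refine:
        return best_ll, dict(zip(names, best_theta))

    def neg_ll(s2):
        s2 = np.clip(s2, 0.0, None)
        return -reml_loglik(y, X, V, components, dict(zip(names, s2)))

    res = optimize.minimize(neg_ll, best_theta, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-13,
                                     "maxiter": 4000, "maxfev": 6000})
    theta = np.clip(res.x, 0.0, None)
    ll = reml_loglik(y, X, V, components, dict(zip(names, theta)))
    if ll < best_ll:
        ll, theta = best_ll, best_theta
    return ll, dict(zip(names, theta))


def gls_beta(y, X, V):
    """Closed-form GLS estimate under a fixed covariance matrix."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    return np.linalg.solve(XtVi @ X, XtVi @ y)


def random_small_instance(rng, max_k: int = 15, n_components: int = 2):
    """Random small meta-analytic instance for oracle-equivalence checks."""
    k = int(rng.integers(6, max_k + 1))
    n_studies = int(rng.integers(2, max(3, k // 2)))
    study = rng.integers(0, n_studies, k)
    v = rng.uniform(0.01, 0.2, k)
    same = (study[:, None] == study[None, :]).astype(float)
    V = 0.5 * np.sqrt(np.outer(v, v)) * same
    np.fill_diagonal(V, v)
    comps = {"study": same}
    if n_components > 1:
        comps["unit"] = np.eye(k)
    s2_true = {name: float(rng.uniform(0, 0.15)) for name in comps}
    S = V + sum(s2_true[n] * G for n, G in comps.items())
    y = 0.2 + np.linalg.cholesky(S + 1e-12 * np.eye(k)) @ rng.standard_normal(k)
    X = np.ones((k, 1))
    return y, X, V, comps
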