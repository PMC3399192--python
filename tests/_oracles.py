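"""Independent reference implementations used only to check the package.

These deliberately share no code with the production likelihood: the REML
oracle assembles the full dense n x n covariance matrix and evaluates the
textbook restricted-likelihood formula directly; the balanced one-way
formulas are the classical ANOVA-based closed forms.
"""

import numpy as np
import pandas as pd


def dense_reml_loglik(design, vc) -> float:
    """Textbook REML log-likelihood with V assembled densely.

    logL = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ].
    Only sensible for small n.
    """
    n = design.n_obs
    V = np.zeros((n, n))
    rvals = np.array([vc.sigma2_resid, vc.sigma2_resid_fitness])
    V[np.arange(n), np.arange(n)] += rvals[design.resid_class]
    if design.include_year and vc.sigma2_year:
        Yr = np.zeros((n, design.n_years))
        m = design.year_codes >= 0
        Yr[np.nonzero(m)[0], design.year_codes[m]] = 1.0
        V += vc.sigma2_year * (Yr @ Yr.T)
    if design.q_coef and vc.G is not None:
        codes, _ = pd.factorize(design.ind_ids)
        for i in range(codes.max() + 1):
            rows = np.nonzero(codes == i)[0]
            Z = design.Zc[rows]
            V[np.ix_(rows, rows)] += Z @ vc.G @ Z.T
    X, y = design.X, design.y
    p = X.shape[1]
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    C = X.T @ Vi @ X
    signC, logdetC = np.linalg.slogdet(C)
    if signC <= 0:
        return -np.inf
    beta = np.linalg.solve(C, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetC + r @ Vi @ r))


def balanced_oneway_reml(y: np.ndarray) -> tuple[float, float]:
    """ANOVA-based REML estimates for a balanced one-way random-effects layout.

    ``y`` has shape (groups, per-group).  Returns (sigma2_group, sigma2_resid);
    for balanced data REML coincides with the ANOVA estimators
    sigma2_e = MSW, sigma2_g = (MSB - MSW) / n when the latter is positive.
    """
    g, n = y.shape
    gm = y.mean(axis=1)
    msb = n * np.sum((gm - y.mean()) ** 2) / (g - 1)
    msw = np.sum((y - gm[:, None]) ** 2) / (g * (n - 1))
    return max((msb - msw) / n, 0.0), msw


def balanced_oneway_blup(y: np.ndarray, s2g: float, s2e: float) -> np.ndarray:
    """Classical shrinkage predictor for balanced one-way group effects:
    u_i = (group mean - grand mean) * s2g / (s2g + s2e / n)."""
    g, n = y.shape
    shrink = s2g / (s2g + s2e / n)
    return (y.mean(axis=1) - y.mean()) * shrink


def mc_variance_of_curve(G: np.ndarray, t: float, n_draws: int, seed: int) -> float:
    """Monte-Carlo estimate of Var(z(t)'u) for u ~ N(0, G), z raw monomials."""
    rng = np.random.default_rng(seed)
    q = G.shape[0]
    u = rng.multivariate_normal(np.zeros(q), G, size=n_draws)
    z = np.array([t**k for k in range(q)])
    vals = u @ z
    return float(vals.var(ddof=1))
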