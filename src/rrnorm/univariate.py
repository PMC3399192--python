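"""Univariate random-regression workflow: order selection and variance function.

Fits the trait model at increasing polynomial orders, selects the most
parsimonious order by stepwise likelihood-ratio testing, and turns the
selected fit into the quantities usually plotted: the among-individual
variance of the response as a function of the covariate (with delta-method
confidence bands) and the per-individual predicted reaction norms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CovariateScale, fit_covariate_scale, legendre_basis, polynomial_basis
from .reml import FitResult, build_design, fit_reml, lrt

__all__ = [
    "OrderSelectionTable",
    "select_order",
    "select_order_from_loglik",
    "variance_function",
    "blup_reaction_norms",
]


@dataclass
class OrderSelectionTable:
    """Stepwise model sequence: fixed-only, +year, then orders 0..max.

    ``table`` mirrors the usual reporting layout (one row per model with
    residual and year variances, the diagonal of G, logL, and the LRT against
    the previous model); ``chosen_order`` is the last order whose LRT was
    significant at the given alpha.
    """

    table: pd.DataFrame
    chosen_order: int
    alpha: float
    fits: dict

    def chosen_fit(self) -> FitResult:
        return self.fits[f"order{self.chosen_order}"]


def select_order_from_loglik(logLs, dfs, alpha: float = 0.05) -> tuple[int, pd.DataFrame]:
    """Stepwise order selection from a log-likelihood sequence.

    ``logLs`` runs over the model ladder [fixed-only, +year, order 0, order 1,
    ...] and ``dfs`` gives the number of additional (co)variances for each
    consecutive comparison (len(logLs) - 1 entries).  Order x is retained if
    its LRT against the previous model is significant; selection stops at the
    first non-significant step and the last significant order is returned
    (order 0 is the floor).
    """
    logLs = list(map(float, logLs))
    if len(dfs) != len(logLs) - 1:
        raise ValueError("need one df per consecutive model pair")
    rows = [{"model": "fixed", "logL": logLs[0], "chi2": np.nan, "df": np.nan,
             "p": np.nan}]
    chosen = 0
    stopped = False
    for step, (lL, df) in enumerate(zip(logLs[1:], dfs)):
        label = "+year" if step == 0 else f"order{step - 1}"
        chi2, p = lrt(lL, logLs[step], df)
        rows.append({"model": label, "logL": lL, "chi2": chi2, "df": df, "p": p})
        if step >= 1:  # an order-x model
            order = step - 1
            if not stopped and p < alpha:
                chosen = order
            elif not stopped:
                stopped = True
    return chosen, pd.DataFrame(rows)


def select_order(records: pd.DataFrame, max_order: int, alpha: float = 0.05,
                 scale: CovariateScale | None = None, include_baselines: bool = True,
                 **fit_kwargs) -> OrderSelectionTable:
    """Fit the model ladder and select the most parsimonious polynomial order.

    Models fitted: fixed effects only; + year random effect; + individual
    polynomial coefficients of order 0, 1, ... up to ``max_order``.  Each
    step is tested against the previous by REML LRT (identical fixed effects
    throughout) with df equal to the number of new (co)variances (x + 1 new
    parameters when going from order x-1 to x).  Fitting stops at the first
    non-significant order.  Non-converged fits are annotated and skipped in
    the comparisons.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if scale is None:
        scale = fit_covariate_scale(records["covariate"].to_numpy())

    fits: dict[str, FitResult] = {}
    rows = []

    def fit_one(label, order, include_year, include_individual):
        design = build_design(records, None, order=max(order, 0), scale=scale,
                              include_year=include_year,
                              include_individual=include_individual)
        fit = fit_reml(design, **fit_kwargs)
        fits[label] = fit
        if not fit.converged:
            warnings.warn(f"model {label} did not converge; selection proceeds "
                          "on converged fits only", RuntimeWarning)
        return fit

    prev = None
    if include_baselines:
        ladder = [("fixed", -1, False, False), ("+year", -1, True, False)]
    else:
        ladder = []
    ladder += [(f"order{x}", x, True, True) for x in range(max_order + 1)]

    chosen = 0
    stopped = False
    for label, order, inc_year, inc_ind in ladder:
        fit = fit_one(label, order, inc_year, inc_ind)
        G = fit.varcomps.G
        row = {
            "model": label,
            "order": order if order >= 0 else np.nan,
            "resid": fit.varcomps.sigma2_resid,
            "year": fit.varcomps.sigma2_year,
            "logL": fit.logL,
            "n_params": fit.n_params,
            "converged": fit.converged,
        }
        for k in range(max_order + 1):
            row[f"ind_{k}"] = (G[k, k] if G is not None and k < G.shape[0] else np.nan)
        if prev is not None and fit.converged and fits[prev].converged:
            df = fit.n_params - fits[prev].n_params
            chi2, p = lrt(fit.logL, fits[prev].logL, df)
            row.update(chi2=chi2, df=df, p=p)
            if order >= 0:
                if not stopped and p < alpha:
                    chosen = order
                elif not stopped:
                    stopped = True
        else:
            row.update(chi2=np.nan, df=np.nan, p=np.nan)
        aic = -2 * fit.logL + 2 * fit.n_params
        row["AIC"] = aic
        row["BIC"] = -2 * fit.logL + fit.n_params * np.log(fit.n_obs)
        rows.append(row)
        if fit.converged:
            prev = label
        if stopped:
            break

    table = pd.DataFrame(rows)
    return OrderSelectionTable(table=table, chosen_order=chosen, alpha=alpha, fits=fits)


def _vech_gradient_of_quadratic(z: np.ndarray) -> np.ndarray:
    """Gradient of z'Gz with respect to vech(G) (lower triangle, row-wise)."""
    q = len(z)
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(z[i] * z[j] * (1.0 if i == j else 2.0))
    return np.array(out)


def variance_function(fit: FitResult, t_grid=None) -> pd.DataFrame:
    """Among-individual variance of the response across the covariate.

    variance(t) = z(t)' G z(t) with z the fit's polynomial basis; the
    approximate SE comes from the delta method applied to the sampling
    covariance of the elements of G, and the 95% CI is estimate +/- 1.96 SE
    with the lower bound floored at 0 in ``ci_lo`` (the raw value is kept in
    ``ci_lo_raw``).  Grid points left of -1 or right of the largest mapped
    covariate value are flagged as extrapolation.
    """
    if not fit.converged:
        warnings.warn("variance_function on a non-converged fit", RuntimeWarning)
    design = fit.design
    if not design.q_coef:
        raise ValueError("fit has no individual coefficient block")
    order = design.meta["order"]
    scale = design.meta["scale"]
    trait = design.trait_indicator == 0
    # trait-row standardized covariate range
    t_obs = scale.transform(design.meta.get("covariate_values")) \
        if design.meta.get("covariate_values") is not None else None
    if t_obs is None:
        # recover from the basis column of order 1 if available, else [-1, 1]
        t_obs = design.Zc[trait, 1] if order >= 1 else np.array([-1.0, 1.0])
    if t_grid is None:
        t_grid = np.linspace(float(np.min(t_obs)), float(np.max(t_obs)), 101)
    t_grid = np.asarray(t_grid, float)

    basis_fn = polynomial_basis if design.meta["basis"] == "monomial" else legendre_basis
    # drop the fitness-elevation column for bivariate fits
    qt = order + 1
    G = np.asarray(fit.varcomps.G)[:qt, :qt]
    Z = basis_fn(t_grid, order)
    var = np.einsum("gi,ij,gj->g", Z, G, Z)

    if fit.vc_sampling_cov is not None:
        # sampling cov of vech(G) sits in the leading block of the vc cov
        nveg = qt * (qt + 1) // 2
        Sigma = fit.vc_sampling_cov[:nveg, :nveg]
        se = np.array([
            float(np.sqrt(max(g @ Sigma @ g, 0.0)))
            for g in (_vech_gradient_of_quadratic(z) for z in Z)
        ])
    else:
        se = np.full_like(var, np.nan)

    lo_raw = var - 1.96 * se
    hi = var + 1.96 * se
    extrapolated = (t_grid < min(-1.0, float(np.min(t_obs)) - 1e-9)) | \
                   (t_grid > float(np.max(t_obs)) + 1e-9)
    if extrapolated.any():
        warnings.warn("variance_function evaluated outside the observed "
                      "covariate range (extrapolation)", RuntimeWarning)
    return pd.DataFrame({
        "t": t_grid,
        "variance": var,
        "se": se,
        "ci_lo": np.clip(lo_raw, 0.0, None),
        "ci_hi": hi,
        "ci_lo_raw": lo_raw,
        "extrapolated": extrapolated,
    })


def blup_reaction_norms(fit: FitResult, t_grid=None) -> pd.DataFrame:
    """Per-individual predicted response curves across the covariate.

    curve_i(t) = mu + b * d(t) + z(t)' BLUP_i, evaluated at the reference age
    class (age contrasts zero), where d(t) maps the standardized grid back to
    the day scale for the fixed covariate slope.  Long format: one row per
    (individual, t).
    """
    design = fit.design
    if fit.blups is None:
        raise ValueError("fit has no individual BLUPs")
    order = design.meta["order"]
    scale: CovariateScale = design.meta["scale"]
    if t_grid is None:
        trait = design.trait_indicator == 0
        t_obs = design.Zc[trait, 1] if order >= 1 else np.array([-1.0, 1.0])
        t_grid = np.linspace(float(np.min(t_obs)), float(np.max(t_obs)), 101)
    t_grid = np.asarray(t_grid, float)

    fx = fit.fixed.set_index("term")["estimate"]
    mu = float(fx.get("mu", 0.0))
    b = float(fx.get("laydate", 0.0))
    d_grid = scale.inverse(t_grid)
    fixed_curve = mu + b * d_grid

    basis_fn = polynomial_basis if design.meta["basis"] == "monomial" else legendre_basis
    Z = basis_fn(t_grid, order)
    qt = order + 1
    U = fit.blups.iloc[:, :qt].to_numpy()  # trait coefficients only
    curves = fixed_curve[None, :] + U @ Z.T

    inds = fit.blups.index.to_numpy()
    out = pd.DataFrame({
        "individual": np.repeat(inds, len(t_grid)),
        "t": np.tile(t_grid, len(inds)),
        "covariate": np.tile(d_grid, len(inds)),
        "predicted": curves.ravel(),
    })
    return out
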