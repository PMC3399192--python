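"""Selection on reaction-norm properties via bivariate random regression.

The trait random regression is fitted jointly with relative lifetime fitness.
Each individual's fitness record loads only on a "fitness elevation" random
effect, so the joint coefficient covariance is (k+2)x(k+2): trait
coefficients ind_0..ind_k plus the fitness elevation.  The fitness row of
that matrix contains the selection differentials S_p = cov(property, w); a
selection gradient divides S_p by the property's variance and a selection
intensity (standardized gradient) by its standard deviation.  Significance
of each differential comes from refitting with that single covariance
constrained to zero and a 1-df likelihood-ratio test.

Because each individual has a single fitness value, neither fitness slopes
nor a fitness residual variance are estimable; both are structurally absent
from the model rather than pinned to a small number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CovariateScale, fit_covariate_scale
from .reml import FitResult, build_design, fit_reml, lrt

__all__ = [
    "SelectionEstimates",
    "fit_selection_model",
    "selection_summary",
    "selection_summary_from_matrix",
    "test_selection",
    "blup_fitness_map",
]


@dataclass
class SelectionEstimates:
    """Per-property selection estimates plus the joint covariance matrix.

    ``summary`` has one row per reaction-norm property with the selection
    differential S (covariance with relative fitness), gradient (S / var),
    intensity (S / sd), and, when LRTs were run, chi2/df/p from the
    constrained refit.  ``covariance`` and ``correlation`` are the full joint
    matrices (properties + fitness elevation); ``covariance_se`` holds the
    approximate SEs when available.
    """

    summary: pd.DataFrame
    covariance: pd.DataFrame
    correlation: pd.DataFrame
    covariance_se: pd.DataFrame | None = None


def _init_from_univariate(uni_fit: FitResult, fitness: pd.DataFrame, order: int):
    """Joint-model starting values from a univariate fit: trait block from the
    univariate G, fitness elevation variance from var(w), covariances zero."""
    from .reml import VarianceComponents

    q = order + 1
    G = np.zeros((q + 1, q + 1))
    Gu = np.asarray(uni_fit.varcomps.G, float)
    m = min(q, Gu.shape[0])
    G[:m, :m] = Gu[:m, :m]
    for k in range(m, q):
        G[k, k] = 0.05 * max(np.trace(Gu) / Gu.shape[0], 1e-3)
    G[q, q] = max(float(np.var(fitness["relative_fitness"])), 1e-3)
    return VarianceComponents(G=G, sigma2_year=uni_fit.varcomps.sigma2_year,
                              sigma2_resid=uni_fit.varcomps.sigma2_resid)


def fit_selection_model(records: pd.DataFrame, fitness: pd.DataFrame, order: int,
                        scale: CovariateScale | None = None,
                        univariate_fit: FitResult | None = None,
                        **fit_kwargs) -> FitResult:
    """Joint REML fit of the trait random regression and relative fitness.

    ``order`` is the trait polynomial order (typically the order selected in
    the univariate stage).  Passing the univariate fit provides informed
    starting values (its variance components with zero trait-fitness
    covariances), which speeds convergence without constraining the optimum.
    Returns the FitResult whose varcomps.G is the joint (k+2)x(k+2)
    coefficient covariance with coefficient names ind_0..ind_k, w_elev.
    """
    if scale is None:
        scale = fit_covariate_scale(records["covariate"].to_numpy())
    design = build_design(records, fitness, order=order, scale=scale)
    if univariate_fit is not None and "init" not in fit_kwargs:
        fit_kwargs["init"] = _init_from_univariate(univariate_fit, fitness, order)
    return fit_reml(design, **fit_kwargs)


def selection_summary_from_matrix(C: np.ndarray, names=None,
                                  C_se: np.ndarray | None = None) -> SelectionEstimates:
    """Selection differentials, gradients, intensities from a joint matrix.

    ``C`` is the joint coefficient covariance with the fitness elevation as
    its last row/column.  Pure arithmetic on the matrix; use
    :func:`selection_summary` to include LRTs from a fit.
    """
    C = np.asarray(C, float)
    q = C.shape[0]
    if names is None:
        names = [f"ind_{k}" for k in range(q - 1)] + ["w_elev"]
    names = list(names)
    sd = np.sqrt(np.clip(np.diag(C), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = C / np.outer(sd, sd)
    rows = []
    for k in range(q - 1):
        S = C[q - 1, k]
        var_p = C[k, k]
        ok = var_p > 0
        rows.append({
            "property": names[k],
            "S": S,
            "gradient": S / var_p if ok else np.nan,
            "intensity": S / np.sqrt(var_p) if ok else np.nan,
            "var_property": var_p,
        })
        if not ok:
            warnings.warn(f"nonpositive variance for {names[k]}; gradient and "
                          "intensity undefined", RuntimeWarning)
    idx = pd.Index(names, name="coefficient")
    return SelectionEstimates(
        summary=pd.DataFrame(rows),
        covariance=pd.DataFrame(C, index=idx, columns=idx),
        correlation=pd.DataFrame(corr, index=idx, columns=idx),
        covariance_se=None if C_se is None else pd.DataFrame(C_se, index=idx, columns=idx),
    )


def selection_summary(fit: FitResult, lrt_results: dict | None = None) -> SelectionEstimates:
    """Selection estimates from a converged joint fit.

    ``lrt_results`` optionally maps property name -> (chi2, df, p) from
    :func:`test_selection`; the values are merged into the summary table.
    """
    if not fit.converged:
        warnings.warn("selection_summary on a non-converged fit", RuntimeWarning)
    if fit.design.coef_names[-1] != "w_elev":
        raise ValueError("fit is not a bivariate selection model")
    est = selection_summary_from_matrix(fit.varcomps.G, names=fit.design.coef_names,
                                        C_se=fit.vc_se_matrix())
    if lrt_results:
        est.summary["chi2"] = [lrt_results.get(p, (np.nan,) * 3)[0]
                               for p in est.summary["property"]]
        est.summary["df"] = [lrt_results.get(p, (np.nan,) * 3)[1]
                             for p in est.summary["property"]]
        est.summary["p"] = [lrt_results.get(p, (np.nan,) * 3)[2]
                            for p in est.summary["property"]]
    return est


def test_selection(records: pd.DataFrame, fitness: pd.DataFrame, order: int,
                   property: str, scale: CovariateScale | None = None,
                   full_fit: FitResult | None = None,
                   **fit_kwargs) -> tuple[float, int, float]:
    """LRT for the selection differential on one reaction-norm property.

    Refits the joint model with cov(property, fitness elevation) constrained
    to exactly zero (all other parameters free) and compares restricted
    likelihoods on 1 df.  ``full_fit`` may be passed to reuse an existing
    unconstrained fit.  Returns (chi2, df, p); p is NaN if the constrained
    fit fails to converge.
    """
    if scale is None:
        scale = fit_covariate_scale(records["covariate"].to_numpy())
    coef_names = [f"ind_{k}" for k in range(order + 1)]
    if property not in coef_names:
        raise ValueError(f"property must be one of {coef_names}, got {property!r}")
    if full_fit is None:
        full_fit = fit_selection_model(records, fitness, order, scale=scale, **fit_kwargs)
    k = coef_names.index(property)
    design = build_design(records, fitness, order=order, scale=scale)
    # start the constrained fit from the unconstrained optimum with the
    # constrained covariance projected out
    fit_kwargs.setdefault("init", full_fit.varcomps)
    fit_kwargs.setdefault("compute_se", False)
    constrained = fit_reml(design, zero_pair=(k, order + 1), **fit_kwargs)
    if not constrained.converged:
        warnings.warn(f"constrained fit for {property} did not converge; "
                      "p-value not computed", RuntimeWarning)
        return np.nan, 1, np.nan
    chi2, p = lrt(full_fit.logL, constrained.logL, df=1)
    return chi2, 1, p


def blup_fitness_map(univariate_fit: FitResult, fitness: pd.DataFrame,
                     overlay: str = "quadratic") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Graphical diagnostic for nonlinear selection: fitness vs BLUPs.

    Merges the univariate fit's per-individual BLUPs with relative fitness
    and fits a descriptive least-squares overlay (quadratic by default) of
    fitness on each property's BLUP.  This is a visual screen for curvature
    (e.g., stabilizing selection); the joint model estimates directional
    selection only, and this map does not constitute a formal test.
    Individuals without a fitness record are excluded with a warning.

    Returns (table, overlays): the per-individual table and one row per
    property with the overlay's intercept/slope/curvature.
    """
    if univariate_fit.blups is None:
        raise ValueError("univariate fit has no BLUPs")
    tab = univariate_fit.blups.reset_index().merge(
        fitness[["individual", "relative_fitness"]], on="individual", how="left")
    missing = tab["relative_fitness"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} individual(s) without a fitness "
                      "record excluded from the BLUP-fitness map", RuntimeWarning)
        tab = tab.loc[~missing].reset_index(drop=True)
    props = [c for c in univariate_fit.blups.columns if c != "w_elev"]
    rows = []
    w = tab["relative_fitness"].to_numpy()
    for prop in props:
        x = tab[prop].to_numpy()
        if overlay == "quadratic":
            c2, c1, c0 = np.polyfit(x, w, 2)
        else:
            c1, c0 = np.polyfit(x, w, 1)
            c2 = np.nan
        rows.append({"property": prop, "intercept": c0, "slope": c1,
                     "curvature": c2, "n": len(x)})
    return tab, pd.DataFrame(rows)
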