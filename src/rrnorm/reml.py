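"""Linear mixed-model machinery: design construction, REML, BLUP, LRT.

The model fitted here is the random-regression mixed model for repeated
life-history records,

    y_ij = mu + age effects + b * d_ij + year_j + z(t_ij)' u_i + e_ij,

where d is the covariate on its day scale, t its standardized (mean 0,
min -1) version, z(t) a polynomial basis, u_i ~ N(0, G) the individual's
reaction-norm coefficients, year_j ~ N(0, s2_year), and e ~ N(0, s2_resid).
The bivariate extension stacks one relative-fitness observation per
individual below the trait records; fitness rows carry their own fixed
effects (mean + cohort), load only on an extra "fitness elevation" column of
the joint coefficient matrix, and have no residual variance (each individual
has a single fitness record, so within-individual fitness variance is not
estimable and is structurally removed from the likelihood).

The restricted likelihood is evaluated by exploiting the covariance
structure: conditional on year effects, observations are independent across
individuals, so V = A + s2_year * Zy Zy' with A block-diagonal over
individuals.  Small per-individual blocks are factorized in batch and the
year term handled by a Woodbury correction, which keeps a likelihood
evaluation at O(sum_i n_i^3 + n_years^3) rather than O(n^3).

The coefficient covariance is optimized on a log-Cholesky scale (Cholesky
factor with logged diagonal), which keeps G positive semidefinite without
explicit constraints; a single covariance can be pinned to exactly zero for
constrained-model likelihood-ratio tests by reordering the coefficients so
the constrained pair leads and dropping the one Cholesky entry that carries
their covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import legendre_basis, polynomial_basis

__all__ = [
    "VarianceComponents",
    "ModelDesign",
    "FitResult",
    "build_design",
    "reml_loglik",
    "fit_reml",
    "solve_mme",
    "lrt",
    "vc_sampling_cov",
    "compare_fits",
    "NonPositiveDefiniteError",
]

_LOG2PI = float(np.log(2.0 * np.pi))
# lower bound on log-variance parameters: variances below exp(-13.8) ~ 1e-6
# of the working scale are treated as boundary cases
_LOG_LOWER = -13.8
_LOG_UPPER = 8.0


class NonPositiveDefiniteError(np.linalg.LinAlgError):
    """Implied covariance matrix is not positive definite."""


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Variance components of the (possibly bivariate) random-regression model.

    G is the coefficient covariance across individuals: (k+1)x(k+1) for a
    univariate fit of polynomial order k, with one extra row/column for the
    fitness elevation in the bivariate case.  ``None`` entries mean the
    corresponding term is absent from the model.
    """

    G: np.ndarray | None
    sigma2_year: float | None
    sigma2_resid: float
    sigma2_resid_fitness: float = 0.0

    def validate(self) -> None:
        if self.G is not None:
            G = np.asarray(self.G, float)
            if G.ndim != 2 or G.shape[0] != G.shape[1]:
                raise ValueError("G must be square")
            if not np.allclose(G, G.T, atol=1e-10):
                raise ValueError("G must be symmetric")
            if np.linalg.eigvalsh(G).min() < -1e-8 * max(1.0, np.abs(G).max()):
                raise ValueError("G must be positive semidefinite")
        if self.sigma2_year is not None and self.sigma2_year < 0:
            raise ValueError("sigma2_year must be >= 0")
        if self.sigma2_resid <= 0:
            raise ValueError("sigma2_resid must be > 0")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            G=None if self.G is None else np.array(self.G, float),
            sigma2_year=self.sigma2_year,
            sigma2_resid=self.sigma2_resid,
            sigma2_resid_fitness=self.sigma2_resid_fitness,
        )


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

class ModelDesign:
    """Stacked observation vector plus fixed/random design, pre-grouped by
    individual for fast block likelihood evaluation."""

    def __init__(self, y, X, fixed_names, Zc, coef_names, year_codes, year_levels,
                 ind_ids, resid_class, trait_indicator, meta=None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.fixed_names = list(fixed_names)
        self.Zc = np.asarray(Zc, float) if Zc is not None else None
        self.coef_names = list(coef_names)
        self.year_codes = np.asarray(year_codes, int)
        self.year_levels = list(year_levels)
        self.ind_ids = np.asarray(ind_ids)
        self.resid_class = np.asarray(resid_class, int)  # 0 = trait, 1 = fitness
        self.trait_indicator = np.asarray(trait_indicator, int)
        self.meta = dict(meta or {})

        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("response and fixed design row counts differ")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError(
                "fixed-effect design is rank deficient; aliased columns among "
                f"{self.fixed_names}"
            )
        self.n_obs = n
        self.n_fixed = p
        self.q_coef = 0 if self.Zc is None else self.Zc.shape[1]
        self.n_years = len(self.year_levels)
        self.include_year = self.n_years > 0

        # dense year one-hot (rows with code -1, e.g. fitness rows, load on no year)
        Yr = np.zeros((n, self.n_years))
        mask = self.year_codes >= 0
        Yr[np.nonzero(mask)[0], self.year_codes[mask]] = 1.0

        # group rows by individual, then individuals by block size
        codes, self.ind_levels = pd.factorize(self.ind_ids)
        self.n_individuals = len(self.ind_levels)
        order = np.argsort(codes, kind="stable")
        counts = np.bincount(codes, minlength=self.n_individuals)
        splits = np.split(order, np.cumsum(counts)[:-1])
        W = np.concatenate([self.X, Yr, self.y[:, None]], axis=1)
        self._w_cols = {"X": slice(0, p), "year": slice(p, p + self.n_years),
                        "y": p + self.n_years}
        by_size: dict[int, list[int]] = {}
        for i, rows in enumerate(splits):
            by_size.setdefault(len(rows), []).append(i)
        self._groups = []
        for size, inds in sorted(by_size.items()):
            row_idx = np.stack([splits[i] for i in inds])  # (m, size)
            grp = {
                "inds": np.asarray(inds),
                "rows": row_idx,
                "W": W[row_idx],                                    # (m, s, pw)
                "Z": None if self.Zc is None else self.Zc[row_idx],  # (m, s, q)
                "R": self.resid_class[row_idx],                      # (m, s)
            }
            self._groups.append(grp)

    # -- core likelihood pieces -------------------------------------------

    def _blocks(self, vc: VarianceComponents):
        """Per-group block covariances A_i = Z_i G Z_i' + diag(resid)."""
        rvals = np.array([vc.sigma2_resid, vc.sigma2_resid_fitness])
        for grp in self._groups:
            if self.q_coef and vc.G is not None:
                Z = grp["Z"]
                B = (Z @ vc.G) @ Z.transpose(0, 2, 1)
            else:
                m, s = grp["R"].shape
                B = np.zeros((m, s, s))
            d = np.arange(B.shape[1])
            B[:, d, d] += rvals[grp["R"]]
            yield grp, B

    def core(self, vc: VarianceComponents, keep_solves: bool = False):
        """Accumulate W'V^{-1}W and log|V| via blocks + year Woodbury.

        Returns (M_corrected blocks, logdetV, extras).  Raises
        NonPositiveDefiniteError if any implied covariance is not PD.
        """
        pw = self.n_fixed + self.n_years + 1
        M = np.zeros((pw, pw))
        logdetA = 0.0
        solves = [] if keep_solves else None
        for grp, B in self._blocks(vc):
            try:
                L = np.linalg.cholesky(B)
            except np.linalg.LinAlgError as exc:
                raise NonPositiveDefiniteError(str(exc)) from exc
            logdetA += 2.0 * np.log(np.einsum("mii->mi", L)).sum()
            AinvW = np.linalg.solve(B, grp["W"])
            M += np.tensordot(grp["W"], AinvW, axes=([0, 1], [0, 1]))
            if keep_solves:
                solves.append(AinvW)
        ix, iyr, iy = self._w_cols["X"], self._w_cols["year"], self._w_cols["y"]
        s2y = vc.sigma2_year if self.include_year else None
        if s2y is not None and s2y > 0:
            T = M[iyr, iyr]
            K = T + np.eye(self.n_years) / s2y
            try:
                cK = np.linalg.cholesky(K)
            except np.linalg.LinAlgError as exc:
                raise NonPositiveDefiniteError(str(exc)) from exc
            logdetV = (logdetA + self.n_years * np.log(s2y)
                       + 2.0 * np.log(np.diag(cK)).sum())
            KiMyr = np.linalg.solve(K, M[iyr, :])
            Mstar = M - M[:, iyr] @ KiMyr
        else:
            K = cK = None
            logdetV = logdetA
            Mstar = M
        extras = {"M": M, "K": K, "solves": solves}
        return Mstar, logdetV, extras


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _age_dummies(age: pd.Series, reference: str):
    levels = [lv for lv in age.cat.categories if (age == lv).any()]
    contrast_levels = [lv for lv in levels if lv != reference]
    cols = [(f"age[{lv}]", (age == lv).to_numpy(float)) for lv in contrast_levels]
    return cols


def build_design(records: pd.DataFrame, fitness: pd.DataFrame | None, order: int,
                 scale, include_year: bool = True, include_individual: bool = True,
                 basis: str = "monomial", age_reference: str = "3+",
                 epsilon_fitness_resid: float | None = None) -> ModelDesign:
    """Assemble the (uni- or bivariate) random-regression model design.

    ``records`` and ``fitness`` must be validated tables (see data_model);
    ``scale`` is the fitted CovariateScale.  The fixed covariate slope is on
    the day scale of ``records['covariate']``; the random-coefficient basis
    uses the standardized covariate.  When ``fitness`` is given, one
    relative-fitness row per individual is appended, with mean + cohort fixed
    effects and a single extra coefficient column ("w_elev") in the joint G.
    ``epsilon_fitness_resid``, if set, assigns the fitness rows that residual
    variance instead of the structural zero (for cross-checks against
    software that cannot constrain a residual to exactly zero).
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    if basis not in ("monomial", "legendre"):
        raise ValueError(f"unknown basis {basis!r}")
    basis_fn = polynomial_basis if basis == "monomial" else legendre_basis

    d = records["covariate"].to_numpy(float)
    t = scale.transform(d)
    y = records["response"].to_numpy(float)
    n = len(records)

    cols = [("mu", np.ones(n))]
    cols += _age_dummies(records["age"], age_reference)
    cols.append(("laydate", d))
    fixed_names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])

    if include_individual:
        Zc = basis_fn(t, order)
        coef_names = [f"ind_{k}" for k in range(order + 1)]
    else:
        Zc, coef_names = None, []

    year = records["year"].astype(str)
    if include_year:
        year_levels = sorted(year.unique())
        year_codes = year.map({lv: i for i, lv in enumerate(year_levels)}).to_numpy()
    else:
        year_levels, year_codes = [], np.full(n, -1)

    ind_ids = records["individual"].to_numpy()
    resid_class = np.zeros(n, int)
    trait_ind = np.zeros(n, int)

    meta = {"order": order, "basis": basis, "scale": scale, "bivariate": False,
            "age_reference": age_reference}

    if fitness is not None:
        if not include_individual:
            raise ValueError("bivariate design requires the individual coefficient block")
        rec_ids = set(records["individual"])
        fit_ids = set(fitness["individual"])
        if rec_ids != fit_ids:
            raise ValueError(
                "individuals must match one-to-one between records and fitness tables"
            )
        nf = len(fitness)
        w = fitness["relative_fitness"].to_numpy(float)
        cohort = fitness["cohort"].astype(str)
        cohort_levels = sorted(cohort.unique())
        ref = cohort_levels[0]
        ccols = [("mu_w", np.ones(nf))]
        ccols += [(f"cohort[{lv}]", (cohort == lv).to_numpy(float))
                  for lv in cohort_levels if lv != ref]
        Xw = np.column_stack([c[1] for c in ccols])
        # block-diagonal fixed design: trait columns zero on fitness rows
        X = np.block([[X, np.zeros((n, Xw.shape[1]))],
                      [np.zeros((nf, X.shape[1])), Xw]])
        fixed_names = fixed_names + [c[0] for c in ccols]
        y = np.concatenate([y, w])
        # joint coefficient block: trait basis + fitness elevation column
        Zc = np.block([[Zc, np.zeros((n, 1))],
                       [np.zeros((nf, order + 1)), np.ones((nf, 1))]])
        coef_names = coef_names + ["w_elev"]
        year_codes = np.concatenate([year_codes, np.full(nf, -1)])
        ind_ids = np.concatenate([ind_ids, fitness["individual"].to_numpy()])
        resid_class = np.concatenate([resid_class, np.ones(nf, int)])
        trait_ind = np.concatenate([trait_ind, np.ones(nf, int)])
        meta["bivariate"] = True
        meta["epsilon_fitness_resid"] = epsilon_fitness_resid

    return ModelDesign(y, X, fixed_names, Zc, coef_names, year_codes, year_levels,
                       ind_ids, resid_class, trait_ind, meta=meta)


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def reml_loglik(design: ModelDesign, vc: VarianceComponents) -> float:
    """Restricted log-likelihood of the design at the given components.

    Returns -inf (rather than raising) when the implied covariance is not
    positive definite, so optimizers can probe freely.
    """
    try:
        Mstar, logdetV, _ = design.core(vc)
    except NonPositiveDefiniteError:
        return -np.inf
    ix, iy = design._w_cols["X"], design._w_cols["y"]
    Cxx = Mstar[ix, ix]
    cxy = Mstar[ix, iy]
    cyy = Mstar[iy, iy]
    sign, logdetC = np.linalg.slogdet(Cxx)
    if sign <= 0:
        return -np.inf
    try:
        beta = np.linalg.solve(Cxx, cxy)
    except np.linalg.LinAlgError:
        return -np.inf
    yPy = cyy - cxy @ beta
    n, p = design.n_obs, design.n_fixed
    return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetC + yPy)


def solve_mme(design: ModelDesign, vc: VarianceComponents):
    """Generalized-least-squares fixed effects and BLUPs of random effects.

    Equivalent to solving Henderson's mixed-model equations at the given
    variance components.  Returns (beta, beta_cov, blups, u_year) where
    ``blups`` is a DataFrame of per-individual coefficient predictions in
    covariate-basis order and ``u_year`` a Series of year-effect predictions.
    """
    vc.validate()
    Mstar, _, extras = design.core(vc, keep_solves=True)
    ix, iyr, iy = (design._w_cols["X"], design._w_cols["year"], design._w_cols["y"])
    Cxx = Mstar[ix, ix]
    cxy = Mstar[ix, iy]
    try:
        beta_cov = np.linalg.inv(Cxx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular fixed-effect system; aliased terms among {design.fixed_names}"
        ) from exc
    beta = beta_cov @ cxy
    M, K = extras["M"], extras["K"]
    use_year = K is not None
    if use_year:
        b_yr = M[iyr, iy] - M[iyr, ix] @ beta
        alpha = np.linalg.solve(K, b_yr)
        u_year = pd.Series(alpha, index=design.year_levels, name="year_effect")
    else:
        alpha = None
        u_year = pd.Series(np.zeros(design.n_years), index=design.year_levels,
                           name="year_effect")

    u_ind = None
    if design.q_coef:
        u_ind = np.zeros((design.n_individuals, design.q_coef))
        for grp, AinvW in zip(design._groups, extras["solves"]):
            # A^{-1}(y - X beta) per row, then year Woodbury correction
            t_rows = AinvW[:, :, iy] - AinvW[:, :, ix] @ beta
            if use_year:
                t_rows = t_rows - AinvW[:, :, iyr] @ alpha
            u_ind[grp["inds"]] = np.einsum("msq,ms->mq", grp["Z"], t_rows) @ vc.G.T
    blups = None
    if u_ind is not None:
        blups = pd.DataFrame(u_ind, index=pd.Index(design.ind_levels, name="individual"),
                             columns=design.coef_names)
    return beta, beta_cov, blups, u_year


# ---------------------------------------------------------------------------
# parameterization (log-Cholesky)
# ---------------------------------------------------------------------------

class Parameterization:
    """Map between an unconstrained parameter vector and VarianceComponents.

    G is represented by its Cholesky factor with logged diagonal.  For
    constrained fits, ``zero_pair=(i, j)`` pins G[i, j] to exactly zero: the
    coefficients are internally reordered so i and j occupy the two leading
    positions, where the covariance is carried by the single factor entry
    L[1, 0], which is dropped from the parameter vector.
    """

    def __init__(self, q_coef: int, include_year: bool, zero_pair=None,
                 epsilon_fitness_resid: float | None = None):
        self.q = q_coef
        self.include_year = include_year
        self.zero_pair = tuple(zero_pair) if zero_pair is not None else None
        self.eps_fit = epsilon_fitness_resid
        if self.zero_pair is not None:
            i, j = self.zero_pair
            if i == j or not (0 <= i < q_coef and 0 <= j < q_coef):
                raise ValueError(f"invalid zero_pair {zero_pair}")
            rest = [k for k in range(q_coef) if k not in (i, j)]
            self.perm = np.array([i, j] + rest)
        else:
            self.perm = np.arange(q_coef)
        self._chol_index = [
            (i, j) for i in range(self.q) for j in range(i + 1)
            if not (self.zero_pair is not None and (i, j) == (1, 0))
        ]
        self.n_chol = len(self._chol_index)
        self.n_params = self.n_chol + int(include_year) + 1

    def names(self):
        out = [f"L[{i},{j}]" for i, j in self._chol_index]
        if self.include_year:
            out.append("log_s2_year")
        out.append("log_s2_resid")
        return out

    def log_scale_indices(self) -> list[int]:
        """Indices of parameters on a log scale (variance-like)."""
        idx = [k for k, (i, j) in enumerate(self._chol_index) if i == j]
        idx.extend(range(self.n_chol, self.n_params))
        return idx

    def bounds(self):
        b = []
        for i, j in self._chol_index:
            b.append((_LOG_LOWER / 2, _LOG_UPPER / 2) if i == j else (-60.0, 60.0))
        if self.include_year:
            b.append((_LOG_LOWER, _LOG_UPPER))
        b.append((_LOG_LOWER, _LOG_UPPER))
        return b

    def to_vc(self, theta: np.ndarray) -> VarianceComponents:
        theta = np.asarray(theta, float)
        k = self.n_chol
        if self.q:
            L = np.zeros((self.q, self.q))
            for val, (i, j) in zip(theta[:k], self._chol_index):
                L[i, j] = np.exp(val) if i == j else val
            Gp = L @ L.T
            G = np.empty_like(Gp)
            G[np.ix_(self.perm, self.perm)] = Gp
        else:
            G = None
        pos = k
        if self.include_year:
            s2y = float(np.exp(theta[pos]))
            pos += 1
        else:
            s2y = None
        s2e = float(np.exp(theta[pos]))
        return VarianceComponents(G=G, sigma2_year=s2y, sigma2_resid=s2e,
                                  sigma2_resid_fitness=self.eps_fit or 0.0)

    def from_vc(self, vc: VarianceComponents) -> np.ndarray:
        vals = []
        if self.q:
            G = np.asarray(vc.G, float)
            Gp = G[np.ix_(self.perm, self.perm)]
            jitter = 1e-8 * max(1.0, np.trace(Gp) / self.q)
            L = np.linalg.cholesky(Gp + jitter * np.eye(self.q))
            for i, j in self._chol_index:
                vals.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
        if self.include_year:
            vals.append(np.log(max(vc.sigma2_year, 1e-8)))
        vals.append(np.log(max(vc.sigma2_resid, 1e-8)))
        return np.array(vals)

    def vech_vc(self, theta: np.ndarray) -> np.ndarray:
        """Variance components as a flat vector (lower triangle of G row-wise,
        then year and residual variances) for delta-method SEs."""
        vc = self.to_vc(theta)
        out = []
        if self.q:
            out.extend(vc.G[i, j] for i in range(self.q) for j in range(i + 1))
        if self.include_year:
            out.append(vc.sigma2_year)
        out.append(vc.sigma2_resid)
        return np.array(out)

    def vech_names(self, coef_names: Sequence[str]) -> list[str]:
        out = []
        if self.q:
            out.extend(f"cov({coef_names[i]},{coef_names[j]})" if i != j
                       else f"var({coef_names[i]})"
                       for i in range(self.q) for j in range(i + 1))
        if self.include_year:
            out.append("var(year)")
        out.append("var(resid)")
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """REML fit: likelihood, estimates, BLUPs, and convergence metadata."""

    logL: float
    converged: bool
    n_params: int
    fixed: pd.DataFrame
    varcomps: VarianceComponents
    vc_se: np.ndarray
    vc_names: list[str]
    vc_sampling_cov: np.ndarray | None
    blups: pd.DataFrame | None
    u_year: pd.Series
    boundary: bool
    identifiable: bool
    n_obs: int
    n_individuals: int
    design: ModelDesign
    param: Parameterization
    theta: np.ndarray
    optimizer: dict = field(default_factory=dict)

    @property
    def order(self) -> int | None:
        return self.design.meta.get("order")

    def vc_se_matrix(self) -> np.ndarray | None:
        """Approximate SEs of G arranged as a symmetric matrix."""
        q = self.design.q_coef
        if not q:
            return None
        se = np.zeros((q, q))
        pos = 0
        for i in range(q):
            for j in range(i + 1):
                se[i, j] = se[j, i] = self.vc_se[pos]
                pos += 1
        return se

    def to_report(self) -> dict:
        vc = self.varcomps
        return {
            "logL": float(self.logL),
            "converged": bool(self.converged),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "n_individuals": int(self.n_individuals),
            "boundary": bool(self.boundary),
            "identifiable": bool(self.identifiable),
            "fixed_effects": self.fixed.to_dict(orient="records"),
            "variance_components": {
                "G": None if vc.G is None else np.asarray(vc.G).tolist(),
                "coef_names": self.design.coef_names,
                "sigma2_year": vc.sigma2_year,
                "sigma2_resid": vc.sigma2_resid,
            },
            "vc_table": [
                {"component": n, "estimate": float(v), "se": None if not np.isfinite(s) else float(s)}
                for n, v, s in zip(self.vc_names, self.param.vech_vc(self.theta), self.vc_se)
            ],
            "optimizer": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in self.optimizer.items()},
        }


def _moment_starts(design: ModelDesign, param: Parameterization, seed: int | None):
    """Three starting points: moment-based, near-zero G, and randomized."""
    trait = design.trait_indicator == 0
    beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta
    v = max(float(np.var(resid[trait])), 1e-4)
    q = param.q
    starts = []

    def build(gdiag_scale, year_frac, resid_frac):
        G = None
        if q:
            diag = np.full(q, gdiag_scale * v)
            if design.meta.get("bivariate"):
                w = design.y[design.trait_indicator == 1]
                diag[-1] = max(gdiag_scale * float(np.var(w)), 1e-4)
            G = np.diag(diag)
        s2y = year_frac * v if param.include_year else None
        return VarianceComponents(G=G, sigma2_year=s2y, sigma2_resid=resid_frac * v,
                                  sigma2_resid_fitness=param.eps_fit or 0.0)

    starts.append(param.from_vc(build(0.3, 0.2, 0.6)))
    starts.append(param.from_vc(build(0.02, 0.02, 1.0)))
    rng = np.random.default_rng(seed if seed is not None else 0)
    jitter = rng.uniform(-1.0, 1.0, size=param.n_params)
    starts.append(starts[0] + jitter)
    return starts


def _numerical_hessian(f, x0, rel_step=1e-4):
    m = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    H = np.zeros((m, m))
    f0 = f(x0)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        fp, fm = f(x0 + ei), f(x0 - ei)
        H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _numerical_jacobian(f, x0, rel_step=1e-6):
    h = rel_step * (1.0 + np.abs(x0))
    f0 = np.asarray(f(x0))
    J = np.zeros((len(f0), len(x0)))
    for i in range(len(x0)):
        ei = np.zeros(len(x0)); ei[i] = h[i]
        J[:, i] = (np.asarray(f(x0 + ei)) - np.asarray(f(x0 - ei))) / (2 * h[i])
    return J


def vc_sampling_cov(design: ModelDesign, param: Parameterization, theta: np.ndarray):
    """Sampling covariance of the variance-component estimates.

    Inverse of the numerical observed information of the restricted
    log-likelihood at the optimum, mapped to the (co)variance scale by the
    delta method.  Returns (cov, identifiable flag).
    """
    f = lambda th: reml_loglik(design, param.to_vc(th))
    H = _numerical_hessian(f, theta)
    info = -H
    eig = np.linalg.eigvalsh((info + info.T) / 2)
    identifiable = bool(eig.min() > 1e-6 * max(eig.max(), 1.0))
    if identifiable:
        cov_theta = np.linalg.inv(info)
    else:
        warnings.warn("observed information is singular; using pseudo-inverse "
                      "(model may be non-identifiable)", RuntimeWarning)
        cov_theta = np.linalg.pinv(info)
    J = _numerical_jacobian(param.vech_vc, theta)
    cov = J @ cov_theta @ J.T
    return (cov + cov.T) / 2, identifiable


def fit_reml(design: ModelDesign, init: VarianceComponents | None = None,
             zero_pair=None, n_starts: int = 3, max_iter: int = 500,
             compute_se: bool = True, seed: int | None = 0,
             epsilon_fitness_resid: float | None = None) -> FitResult:
    """Maximize the restricted likelihood and assemble the full fit.

    Multi-start quasi-Newton (L-BFGS-B with numerical gradients) on the
    log-Cholesky scale; ``zero_pair=(i, j)`` fits the model with G[i, j]
    constrained to zero (constrained-covariance LRTs).  Non-convergence is
    flagged on the result, not raised.
    """
    eps_fit = epsilon_fitness_resid
    if eps_fit is None:
        eps_fit = design.meta.get("epsilon_fitness_resid")
    param = Parameterization(design.q_coef, design.include_year, zero_pair=zero_pair,
                             epsilon_fitness_resid=eps_fit)
    if init is not None:
        starts = [param.from_vc(init)]
    else:
        starts = _moment_starts(design, param, seed)[: max(1, n_starts)]

    bounds = param.bounds()
    nll = lambda th: -reml_loglik(design, param.to_vc(th))
    best = None
    trace = []
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": max_iter, "ftol": 1e-11,
                                         "gtol": 1e-6, "eps": 1e-7})
        trace.append({"start_logL": -float(nll(x0)), "final_logL": -float(res.fun),
                      "nit": int(res.nit), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    vc = param.to_vc(theta)
    logL = -float(best.fun)
    # converged if the best point is finite and some successful start reached
    # it (a failed line search at an already-optimal point is not a failure)
    tol = 1e-6 * (1.0 + abs(logL))
    any_success_at_best = any(
        t["success"] and t["final_logL"] >= logL - tol for t in trace
    )
    converged = any_success_at_best and np.isfinite(logL)

    # boundary: any variance-like parameter pinned near its lower bound
    boundary = any(theta[k] < bounds[k][0] + 0.5 for k in param.log_scale_indices())

    beta, beta_cov, blups, u_year = solve_mme(design, vc)
    se_beta = np.sqrt(np.clip(np.diag(beta_cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (beta / se_beta) ** 2
    # denominator df cannot be estimated for this covariance structure and is
    # conservatively set to the number of individuals
    den_df = design.n_individuals
    fixed = pd.DataFrame({
        "term": design.fixed_names,
        "estimate": beta,
        "se": se_beta,
        "F": F,
        "den_df": den_df,
        "p": stats.f.sf(F, 1, den_df),
    })

    vc_names = param.vech_names(design.coef_names)
    if compute_se and converged:
        cov_vc, identifiable = vc_sampling_cov(design, param, theta)
        se = np.sqrt(np.clip(np.diag(cov_vc), 0, None))
        if boundary:
            se = np.full_like(se, np.nan)
    else:
        cov_vc, identifiable = None, True
        se = np.full(len(vc_names), np.nan)

    return FitResult(
        logL=logL, converged=converged, n_params=param.n_params, fixed=fixed,
        varcomps=vc, vc_se=se, vc_names=vc_names, vc_sampling_cov=cov_vc,
        blups=blups, u_year=u_year, boundary=boundary, identifiable=identifiable,
        n_obs=design.n_obs, n_individuals=design.n_individuals, design=design,
        param=param, theta=theta, optimizer={"starts": trace},
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(logL_full: float, logL_reduced: float, df: int,
        mixture: bool = False) -> tuple[float, float]:
    """Likelihood-ratio test between nested covariance structures.

    chi2 = 2 (logL_full - logL_reduced), referred to chi-square with ``df``
    equal to the number of additional (co)variances estimated.  Negative chi2
    (numerical noise) is clamped to 0 with a warning.  ``mixture=True`` uses
    the 50:50 mixture of chi-square(df-1) and chi-square(df) appropriate when
    a single variance sits on the boundary; the plain chi-square convention is
    the default because variance-structure tests in this literature usually
    report it (it is conservative).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    chi2 = 2.0 * (logL_full - logL_reduced)
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(f"negative LRT statistic ({chi2:.3g}) clamped to 0",
                          RuntimeWarning)
        chi2 = 0.0
    if mixture:
        p_hi = stats.chi2.sf(chi2, df)
        p_lo = stats.chi2.sf(chi2, df - 1) if df > 1 else float(chi2 == 0.0)
        p = 0.5 * (p_lo + p_hi)
    else:
        p = float(stats.chi2.sf(chi2, df))
    return float(chi2), p


def compare_fits(fit_full: FitResult, fit_reduced: FitResult, df: int, **kw):
    """LRT between two REML fits, refusing non-comparable fixed structures.

    REML likelihoods are only comparable when the fixed effects are
    identical; otherwise refit with ML before testing.
    """
    if fit_full.design.fixed_names != fit_reduced.design.fixed_names:
        raise ValueError(
            "REML fits with different fixed effects cannot be compared by LRT; "
            "use maximum likelihood for fixed-effect tests"
        )
    return lrt(fit_full.logL, fit_reduced.logL, df, **kw)
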