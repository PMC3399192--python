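"""Data containers, validation, covariate standardization, relative fitness.

Long-format breeding records (one row per breeding attempt: individual, year,
covariate such as laying date, response such as clutch size, age class) and a
per-individual fitness table (lifetime fledgling production, cohort of first
breeding) are held as pandas DataFrames with a fixed column contract.  This
module validates them, standardizes the covariate to the convention used by
the random-regression machinery (mean 0, minimum -1), and computes relative
fitness (individual lifetime fitness divided by its population mean, so mean
relative fitness is 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DegenerateCovariateError",
    "CovariateScale",
    "RECORD_COLUMNS",
    "FITNESS_COLUMNS",
    "AGE_LEVELS",
    "median_center",
    "fit_covariate_scale",
    "compute_relative_fitness",
    "polynomial_basis",
    "validate_records",
    "validate_fitness",
    "read_records_csv",
    "read_fitness_csv",
    "write_standardized",
]

#: column contract for the long table of repeated trait records
RECORD_COLUMNS = ("individual", "year", "covariate", "response", "age")
#: column contract for the per-individual fitness table
FITNESS_COLUMNS = ("individual", "lfp", "cohort")
#: age classes: first-year, second-year, and three-plus breeders
AGE_LEVELS = ("1", "2", "3+")


class ValidationError(ValueError):
    """Input table violates the data contract; message lists offending rows."""


class DegenerateCovariateError(ValueError):
    """All covariate values identical: the standardizing map is undefined."""


# ---------------------------------------------------------------------------
# covariate handling
# ---------------------------------------------------------------------------

def median_center(dates: Sequence[float], reference: float) -> np.ndarray:
    """Express day-numbers as signed offsets from a reference day.

    With the long-term median laying date as reference, the day after the
    reference maps to +1 and the day before to -1.
    """
    dates = np.asarray(dates, dtype=float)
    if dates.size == 0:
        raise ValidationError("median_center: empty date list")
    if not np.all(np.isfinite(dates)):
        raise ValidationError("median_center: non-finite dates")
    return dates - float(reference)


@dataclass(frozen=True)
class CovariateScale:
    """Affine map t(d) = (d - shift) / scale_factor standardizing a covariate.

    Fitted so the mapped values have mean 0 and minimum -1; one mapped unit
    therefore equals the difference between the mean and the minimum of the
    covariate values the scale was fitted on.  Random-regression coefficient
    variances are expressed on this internal scale.
    """

    shift: float
    scale_factor: float

    def __post_init__(self):
        if not (self.scale_factor > 0):
            raise DegenerateCovariateError(
                f"scale_factor must be > 0, got {self.scale_factor!r}"
            )

    def transform(self, d) -> np.ndarray:
        return (np.asarray(d, dtype=float) - self.shift) / self.scale_factor

    def inverse(self, t) -> np.ndarray:
        return np.asarray(t, dtype=float) * self.scale_factor + self.shift

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateScale":
        return cls(shift=float(d["shift"]), scale_factor=float(d["scale_factor"]))


def fit_covariate_scale(values: Iterable[float], weighted: bool = False) -> CovariateScale:
    """Fit the (mean 0, min -1) standardizing map to observed covariate values.

    By default the map is fitted on the *distinct* observed values, so the
    elevation of a reaction norm refers to the average of the covariate values
    rather than the observation-weighted average; pass ``weighted=True`` to
    center on the per-record mean instead.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("fit_covariate_scale: empty input")
    if not np.all(np.isfinite(vals)):
        raise ValidationError("fit_covariate_scale: non-finite covariate values")
    basis = vals if weighted else np.unique(vals)
    mean = float(np.mean(basis))
    lo = float(np.min(basis))
    if not (lo < mean):
        raise DegenerateCovariateError(
            "all covariate values identical; cannot standardize"
        )
    return CovariateScale(shift=mean, scale_factor=mean - lo)


def polynomial_basis(t, order: int) -> np.ndarray:
    """Raw monomial basis [1, t, t^2, ..., t^order] of the standardized covariate.

    Returned with basis index on the last axis.  At t = 0 (the covariate mean)
    the basis is the first standard basis vector, so the zeroth coefficient is
    always the expected response at the covariate mean ("elevation").
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    t = np.asarray(t, dtype=float)
    return np.stack([t**k for k in range(order + 1)], axis=-1)


def legendre_basis(t, order: int) -> np.ndarray:
    """Legendre-polynomial basis evaluated at the standardized covariate.

    Alternative to :func:`polynomial_basis` for numerical conditioning at
    higher orders; coefficients fitted on this basis can be mapped back to the
    monomial scale with :func:`legendre_to_monomial`.
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    t = np.asarray(t, dtype=float)
    cols = [np.polynomial.legendre.Legendre.basis(k)(t) for k in range(order + 1)]
    return np.stack(cols, axis=-1)


def legendre_to_monomial(order: int) -> np.ndarray:
    """Matrix M with z_legendre(t) = M @ z_monomial(t).

    A coefficient vector u on the Legendre basis corresponds to M.T @ u on the
    monomial basis, and a coefficient covariance G_leg to M.T @ G_leg @ M.
    """
    m = np.zeros((order + 1, order + 1))
    for k in range(order + 1):
        coef = np.polynomial.legendre.Legendre.basis(k).convert(kind=np.polynomial.Polynomial).coef
        m[k, : len(coef)] = coef
    return m


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def compute_relative_fitness(lfp: Sequence[float]) -> np.ndarray:
    """Relative fitness w_i = lifetime fitness / mean lifetime fitness.

    The output has mean exactly 1; all-zero fitness is rejected because the
    ratio is then undefined.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.size == 0:
        raise ValidationError("compute_relative_fitness: empty input")
    if np.any(lfp < 0) or not np.all(np.isfinite(lfp)):
        raise ValidationError("lifetime fitness must be finite and nonnegative")
    mean = lfp.mean()
    if mean <= 0:
        raise ValidationError("all lifetime fitness values are zero; relative fitness undefined")
    return lfp / mean


# ---------------------------------------------------------------------------
# table validation and I/O
# ---------------------------------------------------------------------------

def _report_bad_rows(df: pd.DataFrame, bad: pd.Series, what: str) -> None:
    if bad.any():
        idx = list(df.index[bad][:10])
        raise ValidationError(
            f"{int(bad.sum())} record(s) with {what} (rows {idx}{'...' if bad.sum() > 10 else ''})"
        )


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the long table of trait records; returns a typed copy.

    Rows with missing individual, year, covariate, response, or an unknown age
    class are rejected with an explicit report rather than silently dropped.
    """
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"records table missing columns: {missing}")
    out = df.loc[:, list(RECORD_COLUMNS)].copy()
    for col in ("individual", "year"):
        _report_bad_rows(out, out[col].isna(), f"missing {col}")
    for col in ("covariate", "response"):
        vals = pd.to_numeric(out[col], errors="coerce")
        _report_bad_rows(out, ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan)),
                         f"missing or non-numeric {col}")
        out[col] = vals.astype(float)
    age = out["age"].astype(str).str.strip()
    age = age.replace({"3": "3+", "3.0": "3+", "1.0": "1", "2.0": "2"})
    _report_bad_rows(out, ~age.isin(AGE_LEVELS), "age class outside {1, 2, 3+}")
    out["age"] = pd.Categorical(age, categories=AGE_LEVELS)
    out["individual"] = out["individual"].astype(str)
    out["year"] = out["year"].astype(str)
    return out.reset_index(drop=True)


def validate_fitness(df: pd.DataFrame, records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate the per-individual fitness table and add relative fitness.

    If a validated records table is supplied, requires a one-to-one match of
    individuals between the two tables (needed for the selection analysis).
    """
    missing = [c for c in FITNESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fitness table missing columns: {missing}")
    out = df.loc[:, list(FITNESS_COLUMNS)].copy()
    _report_bad_rows(out, out["individual"].isna(), "missing individual")
    _report_bad_rows(out, out["cohort"].isna(), "missing cohort")
    out["individual"] = out["individual"].astype(str)
    out["cohort"] = out["cohort"].astype(str)
    lfp = pd.to_numeric(out["lfp"], errors="coerce")
    _report_bad_rows(out, ~np.isfinite(lfp.to_numpy(dtype=float, na_value=np.nan)),
                     "missing or non-numeric lifetime fitness")
    out["lfp"] = lfp.astype(float)
    dup = out["individual"].duplicated()
    _report_bad_rows(out, dup, "duplicated individual in fitness table")
    out["relative_fitness"] = compute_relative_fitness(out["lfp"].to_numpy())
    if records is not None:
        rec_ids = set(records["individual"])
        fit_ids = set(out["individual"])
        if rec_ids != fit_ids:
            only_rec = sorted(rec_ids - fit_ids)[:5]
            only_fit = sorted(fit_ids - rec_ids)[:5]
            raise ValidationError(
                "individuals do not match one-to-one between records and fitness "
                f"tables (records-only: {only_rec}, fitness-only: {only_fit})"
            )
    return out.reset_index(drop=True)


def read_records_csv(path, delimiter: str = ",", decimal: str = ".") -> pd.DataFrame:
    """Read and validate the long records table from CSV (header required)."""
    df = pd.read_csv(path, sep=delimiter, decimal=decimal)
    return validate_records(df)


def read_fitness_csv(path, delimiter: str = ",", decimal: str = ".",
                     records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate the fitness table from CSV (header required)."""
    df = pd.read_csv(path, sep=delimiter, decimal=decimal)
    return validate_fitness(df, records=records)


def write_standardized(records: pd.DataFrame, scale: CovariateScale, out_dir,
                       fitness: pd.DataFrame | None = None) -> None:
    """Echo validated data with the standardized covariate added, plus a
    JSON sidecar recording the applied covariate scale for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = records.copy()
    rec["covariate_std"] = scale.transform(rec["covariate"].to_numpy())
    rec.to_csv(out_dir / "records_standardized.csv", index=False)
    if fitness is not None:
        fitness.to_csv(out_dir / "fitness_standardized.csv", index=False)
    with open(out_dir / "covariate_scale.json", "w") as fh:
        json.dump(scale.to_dict(), fh, indent=2)
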