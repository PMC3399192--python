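"""Synthetic-data generator for the random-regression selection analysis.

Generates owl-like long-format datasets from the same generative model the
package fits: individual reaction-norm coefficients (plus a fitness
elevation) drawn jointly from a configured covariance matrix, i.i.d. year
effects, Gaussian residuals, and per-individual lifetime fitness that
covaries with the coefficients.  Every latent draw and every parameter is
returned in a truth record so that recovery, power, and null tests can
compare estimates against known quantities.

Relative fitness is generated directly on the relative scale (mean 1) and
floored at 0; the truth record reports the flooring fraction and the
realized covariances between latent coefficients and final fitness, since
flooring attenuates the configured covariances slightly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import fit_covariate_scale, polynomial_basis, validate_fitness, validate_records

__all__ = ["SimulationConfig", "simulate_dataset", "owl_like_config", "write_dataset"]


# Joint coefficient covariance of the owl-like default: trait elevation,
# linear and quadratic slope variances from the most-parsimonious univariate
# fit of the motivating dataset; covariances and the fitness row from its
# bivariate stage.  Fitness elevation variance is the phenotypic fitness
# variance (0.539) minus the independent fitness noise below.
_OWL_JOINT_G = [
    [0.141, -0.074, 0.099, 0.104],
    [-0.074, 0.240, 0.089, -0.073],
    [0.099, 0.089, 0.975, 0.304],
    [0.104, -0.073, 0.304, 0.439],
]


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    ``joint_G`` is the (k+2)x(k+2) coefficient covariance: trait polynomial
    coefficients of order k plus the fitness elevation as the last row.
    Covariate values are laying dates in days relative to their long-term
    median; each individual has a Gaussian mean date (SD
    ``covariate_between_sd``) around which records scatter with SD
    ``covariate_within_sd``.  Ages progress 1 -> 2 -> 3+ along each
    individual's records, with the first record's age class sampled from
    ``first_age_probs``.
    """

    n_individuals: int = 361
    n_years: int = 31
    mean_records: float = 3.1
    records_dist: str = "zero-truncated-geometric"  # or "fixed"
    joint_G: list = field(default_factory=lambda: [row[:] for row in _OWL_JOINT_G])
    sigma2_year: float = 0.156
    sigma2_resid: float = 0.397
    mu_c: float = 3.38
    slope_per_day: float = -0.062
    age_effects: dict = field(default_factory=lambda: {"1": -0.22, "2": 0.032, "3+": 0.0})
    covariate_between_sd: float = 8.0
    covariate_within_sd: float = 6.0
    first_age_probs: tuple = (0.35, 0.30, 0.35)
    mu_w: float = 1.0
    fitness_noise_var: float = 0.10
    cohort_effect_sd: float = 0.10
    seed: int = 0

    @property
    def order(self) -> int:
        return len(self.joint_G) - 2

    def validate(self) -> None:
        G = np.asarray(self.joint_G, float)
        if G.ndim != 2 or G.shape[0] != G.shape[1] or G.shape[0] < 2:
            raise ValueError("joint_G must be square with at least 2 rows "
                             "(one trait coefficient + fitness elevation)")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("joint_G must be symmetric")
        if np.linalg.eigvalsh(G).min() < -1e-10 * max(1.0, np.abs(G).max()):
            raise ValueError("joint_G must be positive semidefinite")
        if self.records_dist not in ("zero-truncated-geometric", "fixed"):
            raise ValueError(f"unknown records_dist {self.records_dist!r}")
        if self.mean_records <= 1 and self.records_dist != "fixed":
            raise ValueError("mean records per individual must exceed 1 for "
                             "within-individual effects to be identifiable")
        if self.sigma2_resid <= 0 or self.sigma2_year < 0 or self.fitness_noise_var < 0:
            raise ValueError("variances must be nonnegative (residual positive)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["joint_G"] = np.asarray(self.joint_G, float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown simulation config keys: {sorted(extra)}")
        cfg = cls(**d)
        if isinstance(cfg.first_age_probs, list):
            cfg.first_age_probs = tuple(cfg.first_age_probs)
        return cfg


def owl_like_config(**overrides) -> SimulationConfig:
    """Default configuration matching the owl study's structure.

    361 females, 31 year levels, 3.1 records per individual on average
    (zero-truncated geometric), order-2 trait polynomial, and variance
    components taken from the motivating analysis.  Any field can be
    overridden by keyword.
    """
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def _draw_record_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.records_dist == "fixed":
        return np.full(cfg.n_individuals, int(round(cfg.mean_records)))
    # numpy's geometric is supported on {1, 2, ...} with mean 1/p
    p = 1.0 / cfg.mean_records
    n = rng.geometric(p, size=cfg.n_individuals)
    return np.minimum(n, cfg.n_years)


_AGE_SEQ = ("1", "2", "3+")


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None):
    """Draw one dataset: (records table, fitness table, truth record).

    Tables come back already validated (standard column contract, relative
    fitness computed).  The truth record stores the configuration, every
    latent draw (coefficients, year effects, fitness noise), the covariate
    standardization implied by the generated dates, the flooring fraction,
    and the realized covariance of each latent trait coefficient with final
    relative fitness.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.order
    G = np.asarray(cfg.joint_G, float)

    counts = _draw_record_counts(cfg, rng)
    n_rec = int(counts.sum())
    ind_ids = np.array([f"F{i+1:04d}" for i in range(cfg.n_individuals)])

    # cohort (first breeding year) uniform among years leaving room for the
    # individual's consecutive breeding attempts
    cohorts = np.array([rng.integers(0, max(1, cfg.n_years - c + 1)) for c in counts])
    rec_ind = np.repeat(np.arange(cfg.n_individuals), counts)
    within_idx = np.concatenate([np.arange(c) for c in counts])
    rec_year = cohorts[rec_ind] + within_idx

    # ages progress 1 -> 2 -> 3+ from a sampled first-record age class
    first_age = rng.choice(3, size=cfg.n_individuals, p=cfg.first_age_probs)
    age_idx = np.minimum(first_age[rec_ind] + within_idx, 2)
    ages = np.array(_AGE_SEQ)[age_idx]

    # covariate: individual mean date + within-individual scatter (days,
    # relative to the long-term median)
    ind_mean_date = rng.normal(0.0, cfg.covariate_between_sd, cfg.n_individuals)
    d = ind_mean_date[rec_ind] + rng.normal(0.0, cfg.covariate_within_sd, n_rec)
    scale = fit_covariate_scale(d)
    t = scale.transform(d)

    # latent draws
    # eigen-decomposition sampling tolerates semidefinite G (degenerate limits)
    coefs = rng.multivariate_normal(np.zeros(k + 2), G, size=cfg.n_individuals,
                                    method="eigh")
    u_trait, a_fit = coefs[:, : k + 1], coefs[:, k + 1]
    year_eff = rng.normal(0.0, np.sqrt(cfg.sigma2_year), cfg.n_years)
    resid = rng.normal(0.0, np.sqrt(cfg.sigma2_resid), n_rec)

    Z = polynomial_basis(t, k)
    age_fx = np.array([cfg.age_effects[a] for a in _AGE_SEQ])[age_idx]
    response = (cfg.mu_c + age_fx + cfg.slope_per_day * d
                + year_eff[rec_year] + np.einsum("rq,rq->r", Z, u_trait[rec_ind])
                + resid)

    records = pd.DataFrame({
        "individual": ind_ids[rec_ind],
        "year": [f"Y{y+1:02d}" for y in rec_year],
        "covariate": d,
        "response": response,
        "age": ages,
    })

    cohort_eff = rng.normal(0.0, cfg.cohort_effect_sd, cfg.n_years)
    noise = rng.normal(0.0, np.sqrt(cfg.fitness_noise_var), cfg.n_individuals)
    w_raw = cfg.mu_w + cohort_eff[cohorts] + a_fit + noise
    w_floored = np.clip(w_raw, 0.0, None)
    fitness = pd.DataFrame({
        "individual": ind_ids,
        "lfp": w_floored,
        "cohort": [f"Y{y+1:02d}" for y in cohorts],
    })

    records = validate_records(records)
    fitness = validate_fitness(fitness, records=records)

    w_final = fitness["relative_fitness"].to_numpy()
    realized_S = [float(np.cov(u_trait[:, q], w_final, ddof=1)[0, 1])
                  for q in range(k + 1)]
    truth = {
        "config": cfg.to_dict(),
        "seed": int(cfg.seed if seed is None else seed),
        "scale": scale.to_dict(),
        "n_records": n_rec,
        "mean_records": float(counts.mean()),
        "floor_fraction": float(np.mean(w_raw < 0)),
        "realized_S": realized_S,
        "latent": {
            "coefficients": coefs.tolist(),
            "year_effects": year_eff.tolist(),
            "cohort_effects": cohort_eff.tolist(),
            "fitness_noise": noise.tolist(),
            "individual_mean_date": ind_mean_date.tolist(),
        },
    }
    return records, fitness, truth


def write_dataset(records: pd.DataFrame, fitness: pd.DataFrame, truth: dict,
                  out_dir) -> None:
    """Write records.csv, fitness.csv and truth.json; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False, float_format="%.10g")
    fitness.to_csv(out / "fitness.csv", index=False, float_format="%.10g")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
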