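import numpy as np
import pytest

from rrnorm import (
    build_design,
    fit_covariate_scale,
    fit_reml,
    owl_like_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Down-scaled owl-like dataset: 60 individuals, 10 years, order 2 truth."""
    cfg = owl_like_config(n_individuals=60, n_years=10, seed=7)
    records, fitness, truth = simulate_dataset(cfg)
    scale = fit_covariate_scale(records["covariate"].to_numpy())
    return {"cfg": cfg, "records": records, "fitness": fitness, "truth": truth,
            "scale": scale}


@pytest.fixture(scope="session")
def small_order1_fit(small_dataset):
    """Converged order-1 univariate fit on the small dataset, with SEs."""
    d = small_dataset
    design = build_design(d["records"], None, order=1, scale=d["scale"])
    fit = fit_reml(design, n_starts=1, seed=0)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def tiny_designs():
    """A batch of tiny (n <= 30) random designs for oracle-equivalence checks."""
    out = []
    for i in range(6):
        cfg = owl_like_config(n_individuals=4 + i, n_years=3 + (i % 3),
                              mean_records=2.2, seed=100 + i)
        records, fitness, _ = simulate_dataset(cfg)
        records = records.iloc[:28]
        keep = set(records["individual"])
        fitness = fitness[fitness["individual"].isin(keep)].reset_index(drop=True)
        from rrnorm.data_model import compute_relative_fitness
        fitness = fitness.copy()
        fitness["relative_fitness"] = compute_relative_fitness(fitness["lfp"].to_numpy())
        scale = fit_covariate_scale(records["covariate"].to_numpy())
        order = i % 3
        out.append(build_design(records, None, order=order, scale=scale))
        if i % 2 == 0:
            out.append(build_design(records, fitness, order=min(order, 1), scale=scale))
    return out


def random_varcomps(q, rng, include_year=True):
    """Random valid variance components with a full-rank G of size q."""
    from rrnorm import VarianceComponents

    if q:
        L = np.tril(rng.normal(scale=0.4, size=(q, q)))
        L[np.diag_indices(q)] = np.exp(rng.normal(0.0, 0.3, q))
        G = L @ L.T
    else:
        G = None
    return VarianceComponents(
        G=G,
        sigma2_year=float(rng.uniform(0.05, 0.5)) if include_year else None,
        sigma2_resid=float(rng.uniform(0.2, 1.0)),
    )
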