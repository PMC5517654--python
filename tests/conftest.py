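import numpy as np
import pandas as pd
import pytest

import revaging as rv


@pytest.fixture(scope="session")
def small_config():
    """Two sources x two regions, quick to simulate and analyze."""
    return rv.SimulationConfig(
        n_sources=2,
        regions_per_source=2,
        n_individuals_dev=10,
        n_individuals_aging=10,
        n_genes=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return rv.generate_age_series(small_config)


@pytest.fixture(scope="session")
def null_config():
    """No planted signal at all."""
    return rv.SimulationConfig(
        n_sources=2,
        regions_per_source=2,
        n_individuals_dev=10,
        n_individuals_aging=10,
        n_genes=400,
        fraction_updown=0.0,
        fraction_downup=0.0,
        fraction_monotonic_up=0.0,
        fraction_monotonic_down=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_study(null_config):
    return rv.generate_age_series(null_config)


def make_dataset(expr: np.ndarray, ages_years, source="s1", region="r1",
                 individuals=None) -> rv.AgeSeriesDataset:
    """Small hand-built dataset helper for unit tests."""
    ages_days = np.asarray(ages_years, dtype=float) * 365.25
    n = len(ages_days)
    if individuals is None:
        individuals = [f"{source}_i{k}" for k in range(n)]
    samples = pd.Index([f"{source}.{region}.x{k}" for k in range(n)],
                       name="sample_id")
    genes = pd.Index([f"g{k}" for k in range(expr.shape[0])], name="gene_id")
    meta = pd.DataFrame(
        {"individual_id": individuals, "age_days": ages_days,
         "source": source, "region": region},
        index=samples,
    )
    return rv.AgeSeriesDataset(
        expr=pd.DataFrame(np.asarray(expr, dtype=float), index=genes,
                          columns=samples),
        meta=meta,
        name=f"{source}.{region}",
    )
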