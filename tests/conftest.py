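import numpy as np
import pandas as pd
import pytest

import methylspan as ms


@pytest.fixture(scope="session")
def cheap_train_config():
    """Fast elastic-net settings for small fixtures."""
    return ms.TrainConfig(cv_folds=3, n_alphas=8, max_iter=2000, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared by unit tests."""
    cfg = ms.SimulationConfig(
        n_species=30,
        n_cpgs=300,
        n_informative=30,
        n_unreliable_cpgs=20,
        samples_per_species=(2, 6),
        seed=42,
    )
    return ms.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def cpg_driven_design():
    """Design matrix whose trait signal lives only in planted CpGs
    (no phylogenetic methylome drift)."""
    cfg = ms.SimulationConfig(
        n_species=80,
        n_cpgs=600,
        n_informative=60,
        n_unreliable_cpgs=30,
        phylo_cpg_sd=0.0,
        trait_residual_sd=0.0,
        samples_per_species=(2, 6),
        seed=3,
    )
    ds = ms.simulate_dataset(cfg)
    kept = ms.filter_probes(ds.detection)
    corrected = ms.apply_correction(ds.traits)
    X = ms.aggregate(ds.methylation, "species").values[kept]
    y = pd.Series(
        np.log(corrected["max_lifespan_years"]).loc[X.index].to_numpy(),
        index=X.index,
    )
    return ds, X, y


@pytest.fixture(scope="session")
def small_design(small_dataset):
    """Filtered, corrected, species-aggregated design matrix + response."""
    ds = small_dataset
    kept = ms.filter_probes(ds.detection)
    corrected = ms.apply_correction(ds.traits)
    X = ms.aggregate(ds.methylation, "species").values[kept]
    y = pd.Series(
        np.log(corrected["max_lifespan_years"]).loc[X.index].to_numpy(),
        index=X.index,
    )
    return ds, X, y
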