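import numpy as np
import pandas as pd
import pytest

import mikana as mk
from mikana.datasets import META_COLUMNS


@pytest.fixture(scope="session")
def oracle_model():
    """Well-specified Hill-ODE instance (10 genes, 15 edges) with its
    reference state solved."""
    return mk.well_specified_instance(10, 15, seed=5)


@pytest.fixture(scope="session")
def oracle_basis(oracle_model):
    return mk.BasisConfig(
        hill_n=oracle_model.n,
        half_saturation_rule="fixed",
        k_fixed=oracle_model.k,
    )


@pytest.fixture(scope="session")
def oracle_data(oracle_model):
    """Noise-free steady-state + time-series data from the oracle instance."""
    ss = mk.simulate_steady_state_dataset(
        oracle_model, list(range(10)), seed=6)
    ts = mk.simulate_timeseries(
        oracle_model, 20, 2, seed=7, rho_range=(-0.5, 0.5))
    return ss, ts


@pytest.fixture(scope="session")
def kinetic_model():
    """Small saturating-kinetics instance with a settled reference state."""
    net = mk.generate_scale_free(mk.TopologyConfig(n_genes=10, k_av=3, seed=3))
    model = mk.sample_parameters(net, seed=4)
    mk.find_reference_state(model, seed=5)
    return model


def make_ss_dataset(values, genes, perturbed, deltas=None):
    """Hand-built steady-state dataset (one perturbed gene per sample)."""
    n = values.shape[1]
    deltas = deltas if deltas is not None else [0.5] * n
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "kind": ["steady_state"] * n,
        "replicate": [None] * n,
        "time_h": [None] * n,
        "perturbed_gene": perturbed,
        "knockdown_fraction": deltas,
        "noise_level": [0.0] * n,
    }, columns=META_COLUMNS)
    return mk.ExpressionDataset(values=values, genes=genes, meta=meta)


def make_ts_dataset(blocks, genes, times):
    """Hand-built time-series dataset from per-replicate value blocks."""
    cols, meta = [], []
    for r, block in enumerate(blocks):
        cols.append(np.asarray(block, dtype=float))
        for j, t in enumerate(times):
            meta.append({
                "sample_id": f"r{r}t{j}", "kind": "time_series",
                "replicate": r, "time_h": float(t), "perturbed_gene": None,
                "knockdown_fraction": None, "noise_level": 0.0,
            })
    return mk.ExpressionDataset(
        values=np.concatenate(cols, axis=1), genes=genes,
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
    )
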