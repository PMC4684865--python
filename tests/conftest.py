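"""Shared fixtures: one small simulated experiment reused across modules."""

import numpy as np
import pandas as pd
import pytest

import costim_synergy as cs


@pytest.fixture(scope="session")
def small_config() -> cs.SimConfig:
    """A reduced experiment: enough genes for stable statistics, fast."""
    return cs.SimConfig(
        n_genes=1500,
        frac_regulated_a=0.01,
        frac_regulated_b=0.05,
        frac_supra=0.05,
        noise_sd=0.1,
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    truth = cs.simulate_truth(small_config)
    tables, design = cs.simulate_arrays(truth, small_config)
    return truth, tables, design


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    _, tables, _ = small_experiment
    return cs.preprocess_arrays(tables)


@pytest.fixture(scope="session")
def de_results(small_experiment, small_matrix):
    _, _, design = small_experiment
    return {
        cond: cs.de_test(small_matrix, design, cond)
        for cond in ("ligand_a", "ligand_b", "combo")
    }


def make_spot_table(ref, sample, flags=None, array_id="a1") -> cs.SpotTable:
    ref = np.asarray(ref, float)
    n = len(ref)
    data = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "ch_reference": ref,
        "ch_sample": np.asarray(sample, float),
        "flag": np.zeros(n, bool) if flags is None else np.asarray(flags, bool),
    })
    return cs.SpotTable(array_id, data)
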