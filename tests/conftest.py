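import numpy as np
import pandas as pd
import pytest

from mrmref.config import PipelineConfig
from mrmref.io_formats import Panel, PanelEntry
from mrmref.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated experiment (30 samples, 25 proteins)."""
    cfg = SimConfig(n_samples=30, n_proteins=25, seed=7, dropout=(), noisy_proteins=())
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """No technical noise, no batch or sample shifts: measured = truth."""
    cfg = SimConfig(
        n_samples=20,
        n_proteins=12,
        seed=3,
        tech_cv=0.0,
        batch_shift_sd=0.0,
        sample_shift_sd=0.0,
        dropout=(),
        noisy_proteins=(),
        covariate_effects=(),
    )
    return simulate_experiment(cfg)


@pytest.fixture
def single_entry_panel():
    """One peptide, identity-friendly calibration (levels 1..4^6, SIS 1)."""
    concs = [1.0 * 4.0**i for i in range(7)]
    entry = PanelEntry(
        protein_id="P1",
        peptide_id="P1_pep",
        level_concs={lv: c for lv, c in zip("ABCDEFG", concs)},
        sis_conc=1.0,
        qc_concs={"QCA": 3.0, "QCB": 64.0, "QCC": 1365.0},
    )
    return Panel([entry])


def make_matrix(rng, n=12, p=8, index_prefix="S"):
    vals = 10.0 ** rng.uniform(0, 3, size=(n, p))
    return pd.DataFrame(
        vals,
        index=[f"{index_prefix}{i}" for i in range(n)],
        columns=[f"P{j}" for j in range(p)],
    )
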