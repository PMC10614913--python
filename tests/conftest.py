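import numpy as np
import pytest

from isopulse.synthetic_data import (
    Ms1Params,
    ProteomeConfig,
    select_peptides,
    simulate_proteome,
    synthesize_ms1_run,
)
from isopulse.quant_ms import QuantConfig, quantify_run


@pytest.fixture(scope="session")
def small_proteome():
    """25 proteins with default turnover mixture, seed 3."""
    cfg = ProteomeConfig(n_proteins=25)
    sequences, truth = simulate_proteome(cfg, seed=3)
    return sequences, truth


@pytest.fixture(scope="session")
def peptide_panel(small_proteome):
    sequences, _ = small_proteome
    return select_peptides(sequences, per_protein=4)[:100]


@pytest.fixture(scope="session")
def noiseless_run(small_proteome, peptide_panel):
    _, truth = small_proteome
    return synthesize_ms1_run(peptide_panel, truth, Ms1Params.noiseless(), seed=3)


@pytest.fixture(scope="session")
def noisy_run(small_proteome, peptide_panel):
    _, truth = small_proteome
    return synthesize_ms1_run(peptide_panel, truth, Ms1Params(), seed=3)


@pytest.fixture(scope="session")
def noisy_records(noisy_run):
    return quantify_run(noisy_run.run, noisy_run.identifications(), QuantConfig())


@pytest.fixture(scope="session")
def llp_benchmark_result():
    """The 200-protein LLP-calling benchmark (llp_fraction 0.15, seed 5)."""
    from isopulse.experiments import llp_benchmark

    return llp_benchmark(n_proteins=200, llp_fraction=0.15, seed=5, mode="tissue")


@pytest.fixture(scope="session")
def calibration_rates():
    """Type-I error rates of the package's tests over 2000 null simulations."""
    from isopulse.experiments import type_one_error_rates

    return type_one_error_rates(n_sims=2000, n=30, alpha=0.05, seed=13)
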