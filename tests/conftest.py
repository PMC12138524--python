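import pytest

from lncscreen.pipeline import PipelineConfig, run_pipeline
from lncscreen.simulate import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_run():
    """Default-size bundle in the noiseless limit, plus its pipeline result."""
    bundle = simulate_dataset(SimulationParams(noiseless=True), seed=1)
    result = run_pipeline(PipelineConfig(), bundle)
    return bundle, result


@pytest.fixture(scope="session")
def noisy_run():
    """Default bundle (NB dispersion 0.1, planted |log2fc| = 3), fixed seed."""
    bundle = simulate_dataset(SimulationParams(), seed=1)
    result = run_pipeline(PipelineConfig(), bundle)
    return bundle, result


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, reduced bundle for I/O and CLI tests."""
    params = SimulationParams(
        n_known_mrna=6, n_novel_mrna=16, n_lncrna=30, n_too_short=3,
        cis_pairs_per_subtype=1, n_trans_pairs=4, n_precursor_lnc=2,
        n_hairpins=3, n_qpcr_genes=4,
    )
    return simulate_dataset(params, seed=11)
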