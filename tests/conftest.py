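import numpy as np
import pytest

from riskpred.genotype_io import GenotypeDataset, SNPRecord, impute_mode
from riskpred.synthetic_data import SimulationSpec, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """Six samples, four SNPs, hand-written codes; SNP 2 tracks the label."""
    genotypes = np.array(
        [
            [0, 1, 0, 2],
            [1, 2, 0, 1],
            [0, 0, 0, 0],
            [2, 1, 2, 1],
            [1, 0, 2, 0],
            [0, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    labels = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
    return GenotypeDataset(
        genotypes,
        labels,
        [f"s{i}" for i in range(6)],
        [SNPRecord(f"rs{j}") for j in range(4)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick-to-simulate cohort with a clear planted signal, complete codes."""
    spec = SimulationSpec(
        n_cases=150,
        n_controls=150,
        n_snps=120,
        n_causal=4,
        effect_log_odds=1.2,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """One instance of the full benchmark cohort, mode-imputed (shared
    across tests because simulation is the expensive step)."""
    from riskpred.synthetic_data import default_benchmark_spec

    return impute_mode(simulate_genotypes(default_benchmark_spec(seed=5)))
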