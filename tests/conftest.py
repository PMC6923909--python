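import numpy as np
import pytest

from fmtlmm import ExperimentDesign, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def design_3x2():
    return ExperimentDesign.balanced_two_group(3, 2)


@pytest.fixture
def tiny_dataset():
    """Hand-checkable 2x2 nested design from the worked ANOVA decomposition."""
    design = ExperimentDesign.balanced_two_group(2, 2)
    # group1 subjects (1,3), (2,4); group2 subjects (5,7), (6,8)
    Y = np.array([[1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0]])
    return Y, design


def simulate_null_gene_matrix(rng, n_genes, design, sigma_e=0.3, sigma_r=0.5):
    """Null genes from the mixed model with fixed variance components."""
    Z = design.random_effects_matrix()
    S = rng.normal(0, np.sqrt(sigma_r), size=(n_genes, design.n_subjects))
    eps = rng.normal(0, np.sqrt(sigma_e), size=(n_genes, design.n_samples))
    return 7.0 + S @ Z.T + eps


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


# deterministic property-based testing in any environment
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")
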