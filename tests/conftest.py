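import numpy as np
import pytest

from matechoice import GenotypePanel, SimConfig, simulate_study


def random_panel(
    rng: np.random.Generator,
    n_individuals: int = 6,
    n_loci: int = 8,
    n_alleles: int = 4,
    missing_rate: float = 0.1,
    panel_id: str = "T",
) -> GenotypePanel:
    """Small random multi-allelic panel for oracle comparisons."""
    codes = rng.integers(0, n_alleles, size=(n_individuals, n_loci, 2)).astype(np.int32)
    mask = rng.random((n_individuals, n_loci)) < missing_rate
    codes[mask] = -1
    alleles = [[f"a{j}" for j in range(n_alleles)] for _ in range(n_loci)]
    ids = [f"ind{i}" for i in range(n_individuals)]
    loci = [f"L{l}" for l in range(n_loci)]
    return GenotypePanel(panel_id, ids, loci, codes, alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_study():
    """One reduced-scale synthetic study reused across read-only tests."""
    config = SimConfig(
        n_enclosure_years=4,
        n_females=6,
        n_males=6,
        n_snp_loci=120,
        n_msat_loci=6,
        seed=424242,
        breeding_prob=0.5,
    )
    return simulate_study(config)
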