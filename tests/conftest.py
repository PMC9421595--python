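import numpy as np
import pandas as pd
import pytest

from tauprs.genotypes import GenotypePanel


def make_panel(dosages, chrom="1", positions=None, ids=None):
    """Hand-built panel for worked examples (dosages: n x m array-like)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1_000_000 + 10_000 * j for j in range(m)]
    if ids is None:
        ids = [f"v{j}" for j in range(m)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chroms,
            "pos": positions,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypePanel(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def random_panel():
    """Moderate random panel shared by oracle-equivalence tests."""
    from tauprs.synthetic import simulate_genotypes

    # MAF drawn away from the QC boundary so sampling noise cannot push a
    # variant's realized frequency below the 5% retention threshold
    return simulate_genotypes(
        400, 30, maf_range=(0.1, 0.5), ld_block_size=3, ld_rho=0.5, seed=1234
    )
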