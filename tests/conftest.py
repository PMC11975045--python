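import numpy as np
import pytest

import srb


@pytest.fixture(scope="session")
def small_params() -> srb.ModelParams:
    """Reduced-alphabet parameters used by the evolution studies (|M| = 64)."""
    return srb.ModelParams(alphabet_size=4, peptide_length=10, xi=3, master_seed=11)


@pytest.fixture(scope="session")
def amino_params() -> srb.ModelParams:
    """General 20-letter alphabet parameters (|M| = 8000)."""
    return srb.ModelParams(alphabet_size=20, peptide_length=10, xi=3, master_seed=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_universe(small_params):
    """(motif map, coupling table, two 20-epitope proteins) at |A| = 4."""
    mm = srb.build_motif_map(small_params)
    table = srb.build_coupling_table(small_params, coupling_seed=99)
    gen = srb.stream(small_params.master_seed, "fixtures")
    P = srb.random_protein(small_params, 20, gen)
    B = srb.random_protein(small_params, 20, gen)
    return mm, table, P, B
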