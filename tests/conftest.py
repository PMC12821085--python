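import numpy as np
import pandas as pd
import pytest

from capcogs import synth
from capcogs.genome_model import ChicagoParams, FragmentMap


@pytest.fixture(scope="session")
def uniform_fragmap() -> FragmentMap:
    """50 fragments of 100 bp on chr1 plus 20 of 200 bp on chr2."""
    rows = [("chr1", i * 100, (i + 1) * 100) for i in range(50)]
    rows += [("chr2", i * 200, (i + 1) * 200) for i in range(20)]
    return FragmentMap(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture(scope="session")
def simple_params(uniform_fragmap) -> ChicagoParams:
    n = len(uniform_fragmap)
    knots = np.column_stack(
        [np.geomspace(100, 1e6, 20), 50.0 * np.geomspace(100, 1e6, 20) ** -0.8]
    )
    return ChicagoParams(
        bmean=5.0,
        s_i={i: 1.0 + 0.01 * i for i in range(n)},
        s_j={i: 2.0 - 0.01 * i for i in range(n)},
        f_knots=knots,
    )


@pytest.fixture(scope="session")
def default_fixture() -> synth.Fixture:
    """Full-size synthetic dataset (3 chromosomes x 2,000 fragments, 200
    genes, 20 LD blocks) shared by the slower end-to-end tests."""
    return synth.generate_fixture(20260927)


@pytest.fixture(scope="session")
def clean_pir_fixture() -> synth.Fixture:
    """Fixture whose single planted causal variant lies in the target
    gene's PIR and in no peak-derived feature (exact-score scenario)."""
    return synth.generate_fixture(20260927, n_planted=1,
                                  plant_enhancer_peaks=False)


@pytest.fixture(scope="session")
def small_genome() -> synth.Genome:
    return synth.make_genome(7, n_chrom=2, n_frag=300, n_genes=30)
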