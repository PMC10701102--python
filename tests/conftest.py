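import numpy as np
import pytest

from gpformer import GenotypeMatrix, MISSING, PhenotypeVector, SimConfig, simulate_genotypes, simulate_phenotype


@pytest.fixture
def tiny_geno() -> GenotypeMatrix:
    """Hand-written 4-sample x 5-marker matrix covering all call codes."""
    calls = np.array(
        [
            [0, 1, 2, 0, MISSING],
            [1, 1, 0, 0, 2],
            [2, 0, 1, 0, 2],
            [0, MISSING, 2, 0, 2],
        ]
    )
    return GenotypeMatrix(
        samples=["a", "b", "c", "d"],
        markers=[f"m{j}" for j in range(5)],
        calls=calls,
        chrom=np.array(["1", "1", "1", "2", "2"], dtype=object),
        pos=np.array([100, 250, 900, 50, 75]),
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimConfig(n_samples=120, n_markers=60, n_qtl=8, h2=0.8, seed=7)
    g = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(g, cfg)
    return g, y, truth, cfg


@pytest.fixture
def pheno(tiny_geno) -> PhenotypeVector:
    return PhenotypeVector(list(tiny_geno.samples), [0.5, 1.5, -0.5, 2.0], "toy")
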