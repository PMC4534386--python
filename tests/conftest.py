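import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from robust_gmdr import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def small_geno() -> GenotypeMatrix:
    return GenotypeMatrix(
        ["A", "B", "C", "D"],
        ["snp1", "snp2"],
        np.array([[0, 0], [0, 0], [1, 2], [2, 1]], dtype=np.int8),
    )


@pytest.fixture
def simple_pheno() -> PhenotypeTable:
    rng = np.random.default_rng(11)
    n = 40
    cov = rng.standard_normal(n)
    trait = 1.0 + 0.5 * cov + rng.standard_normal(n)
    return PhenotypeTable([f"s{i}" for i in range(n)], trait, cov[:, None], ["env"])


def random_geno(rng: np.random.Generator, n: int, p: int,
                missing_rate: float = 0.0) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, p)) < missing_rate] = -1
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], [f"rs{j}" for j in range(p)], calls
    )
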