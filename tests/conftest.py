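import numpy as np
import pytest

from hybridorigin.datatypes import GenotypeTable
from hybridorigin.synthetic_data import (
    GenealogicalClass,
    diagnostic_freqs,
    draw_parental_freqs,
    simulate_genotypes,
    simulate_study,
)


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two populations x two individuals x two biallelic loci."""
    g = np.array(
        [
            [(1, 1), (1, 2)],
            [(1, 2), (2, 2)],
            [(2, 2), (0, 0)],
            [(1, 2), (1, 1)],
        ]
    )
    return GenotypeTable(
        ["A_01", "A_02", "B_01", "B_02"],
        ["A", "A", "B", "B"],
        ["L1", "L2"],
        g,
    )


@pytest.fixture(scope="session")
def study_table():
    """Study-preset dataset at the elevated divergence used for clustering checks."""
    table, freqs = simulate_study(42, F=0.25)
    return table, freqs


def random_table(seed: int, n_pops: int = 2, n_per_pop: int = 5, n_loci: int = 3,
                 missing_rate: float = 0.1) -> GenotypeTable:
    """Random valid table whose ids carry the label-prefix convention."""
    rng = np.random.default_rng(seed)
    inds, pops, rows = [], [], []
    for p in range(n_pops):
        label = f"pop{p + 1}"
        for i in range(n_per_pop):
            inds.append(f"{label}_{i + 1:03d}")
            pops.append(label)
            row = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    row.append((0, 0))
                else:
                    a = sorted(rng.integers(1, 30, size=2).tolist())
                    row.append(tuple(a))
            rows.append(row)
    return GenotypeTable(inds, pops, [f"loc{j + 1}" for j in range(n_loci)],
                         np.array(rows))


@pytest.fixture
def diagnostic_pair():
    """Parental tables at 7 fully diagnostic loci (A carries allele 1, B allele 2)."""
    fr = diagnostic_freqs(7)
    a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 20, 101, population="A")
    b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 20, 102, population="B")
    return fr, a, b
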