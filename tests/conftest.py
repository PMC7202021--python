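import numpy as np
import pandas as pd
import pytest

from extgen import CytosineCallSet, SimConfig, SnpMatrix, simulate_dataset
from extgen.methylation_similarity import WindowMethylationMatrix


@pytest.fixture
def worked_snps() -> SnpMatrix:
    """3 clone groups x 2 SNPs; p = (2/3, 2/3); hand-solvable."""
    return SnpMatrix(
        pd.DataFrame(
            [[0.0, 1.0], [1.0, 1.0], [1.0, 0.0]],
            index=["A", "B", "C"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def worked_windows() -> WindowMethylationMatrix:
    """3 accessions x 4 windows, one missing cell; M and N solved by hand."""
    props = pd.DataFrame(
        {
            "chr1:0": [0.1, 0.5, 0.9],
            "chr1:200": [0.2, 0.4, 0.6],
            "chr1:400": [0.9, 0.1, 0.5],
            "chr1:600": [0.3, 0.7, np.nan],
        },
        index=["a1", "a2", "a3"],
    )
    coverage = props.notna() * 20
    meth = (props.fillna(0.0) * 20).round().astype(int)
    return WindowMethylationMatrix(
        proportions=props, coverage=coverage.astype(int), meth_counts=meth
    )


def random_callset(
    rng: np.random.Generator,
    sample_id: str = "s",
    n_sites: int = 50,
    contexts: tuple[str, ...] = ("CG",),
) -> CytosineCallSet:
    chroms = rng.choice(["chr1", "chr2"], size=n_sites)
    pos = np.zeros(n_sites, dtype=int)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = rng.choice(np.arange(1, 10_000), size=mask.sum(), replace=False)
    total = rng.integers(1, 30, size=n_sites)
    meth = rng.binomial(total, rng.random(n_sites))
    return CytosineCallSet(
        sample_id=sample_id,
        data=pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos,
                "strand": rng.choice(["+", "-"], size=n_sites),
                "meth": meth,
                "total": total,
                "context": rng.choice(list(contexts), size=n_sites),
            }
        ),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small end-to-end simulated clone-family dataset, shared across tests."""
    cfg = SimConfig(
        n_families=3,
        accessions_per_family=3,
        replicates=2,
        n_snps=120,
        n_windows=40,
        seed=11,
    )
    return simulate_dataset(cfg)
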