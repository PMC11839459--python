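import numpy as np
import pandas as pd
import pytest

from lesionphylo import PipelineConfig
from lesionphylo.phylo_model import Phylogeny, VariantCallMatrix, read_phylogeny

TREE_A = "((S1:10,S2:10)N2:10,(S3:10,S4:10)N3:10)R;"
TREE_B = "(((S1:10,S2:10)N3:10,S3:10)N2:10,S4:10)R;"
TREE_C = "((S1:10,(S2:10,(S3:10,S4:10)N4:10)N3:10)N2:10,S5:10)R;"


@pytest.fixture
def tree_a() -> Phylogeny:
    return read_phylogeny(TREE_A)


@pytest.fixture
def tree_b() -> Phylogeny:
    return read_phylogeny(TREE_B)


@pytest.fixture
def tree_c() -> Phylogeny:
    return read_phylogeny(TREE_C)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_counts(tree, mtr_by_tip, dep=30, n_variants=None, variants=None):
    """Single- or multi-variant count matrix from per-tip dictionaries."""
    samples = sorted(tree.tips)
    if isinstance(mtr_by_tip, dict):
        mtr_by_tip = [mtr_by_tip]
    nv = len(mtr_by_tip)
    mtr = np.zeros((nv, len(samples)), dtype=int)
    for i, row in enumerate(mtr_by_tip):
        for j, s in enumerate(samples):
            mtr[i, j] = row.get(s, 0)
    if np.isscalar(dep):
        depm = np.full((nv, len(samples)), dep, dtype=int)
    else:
        depm = np.zeros((nv, len(samples)), dtype=int)
        for i, row in enumerate(dep):
            for j, s in enumerate(samples):
                depm[i, j] = row.get(s, 0)
    if variants is None:
        variants = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 100 + i, "ref": "C", "alt": "T",
                 "vclass": "SNV"}
                for i in range(nv)
            ]
        )
    return VariantCallMatrix(
        variants=variants, mtr=mtr, dep=depm, samples=samples
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random rooted binary tree with integer branch lengths 1..20."""
    parts = [f"S{i + 1}:{rng.integers(1, 21)}" for i in range(n_tips)]
    counter = 0
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        counter += 1
        merged = (
            f"({parts[i]},{parts[j]})I{counter}:{rng.integers(1, 21)}"
        )
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(merged)
    newick = parts[0].rsplit(":", 1)[0] + ";"
    return read_phylogeny(newick)


@pytest.fixture(scope="session")
def adult_dataset():
    from lesionphylo.synthetic_data import generate_dataset

    return generate_dataset("adult-hspc", seed=11)
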