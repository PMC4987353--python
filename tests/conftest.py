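from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import settings

from gutenv.model import CountTable, PhyloTree, SampleFrame

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(io.StringIO(newick)))


@pytest.fixture
def balanced_tree() -> PhyloTree:
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def toy_table() -> CountTable:
    return CountTable(
        pd.DataFrame(
            {"s1": [3, 1, 0, 2], "s2": [0, 2, 5, 1], "s3": [1, 1, 1, 1]},
            index=["A", "B", "C", "D"],
        )
    )


@pytest.fixture
def toy_samples() -> SampleFrame:
    return SampleFrame(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "compartment": ["pika", "plant", "soil"],
                "site": ["x", "x", "x"],
                "host_species": ["sp1", "", ""],
            }
        )
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Small random bifurcating tree with uniform(0.1, 2) branch lengths,
    built independently of the package's simulator."""
    names = [f"T{i}" for i in range(n_tips)]
    nodes = [skbio.TreeNode(name=n, length=float(rng.uniform(0.1, 2))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(
            skbio.TreeNode(length=float(rng.uniform(0.1, 2)), children=[a, b])
        )
    nodes[0].length = 0.0
    return PhyloTree(nodes[0], warn_missing_lengths=False)


def random_table(rng: np.random.Generator, n_otus: int, n_samples: int,
                 max_count: int = 20) -> CountTable:
    counts = rng.integers(0, max_count + 1, size=(n_otus, n_samples))
    # guarantee no empty sample
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_otus), j] = 1
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"T{i}" for i in range(n_otus)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
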