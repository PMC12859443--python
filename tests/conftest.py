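import numpy as np
import pytest

from cogvec import (
    BitVectorMatrix,
    CognateDataset,
    build_model,
    random_tree,
    simulate_matrix,
)


@pytest.fixture
def toy_dataset() -> CognateDataset:
    """Three languages, four concepts: polymorphism, missing data, a κ=1 concept."""
    return CognateDataset(
        languages=["l1", "l2", "l3"],
        concepts=["hand", "water", "stone", "sun"],
        assignments={
            ("l1", "hand"): frozenset({"a", "b"}),
            ("l2", "hand"): frozenset({"a"}),
            ("l3", "hand"): frozenset({"c"}),
            ("l1", "water"): frozenset({"x"}),
            ("l2", "water"): frozenset({"y"}),
            # l3/water missing (ν = 0)
            ("l1", "stone"): frozenset({"s"}),
            ("l2", "stone"): frozenset({"s"}),
            ("l3", "stone"): frozenset({"s"}),
            ("l1", "sun"): frozenset({"p"}),
            ("l2", "sun"): frozenset({"q"}),
            ("l3", "sun"): frozenset({"r"}),
        },
    )


@pytest.fixture
def mk3_matrix() -> BitVectorMatrix:
    """A small simulated κ=3 matrix with strong signal."""
    tree = random_tree(6, 0.3, seed=11)
    model = build_model("MK", 3)
    return simulate_matrix(tree, model, 60, 0.05, seed=12)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
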