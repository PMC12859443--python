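"""Forward simulation of trees, character matrices, and cognate datasets.

The simulator exists so that every pipeline stage — encoding, likelihood,
model fitting, model comparison, cross-validation — can be exercised on data
with a known generating process.  Its defaults emulate the statistical shape
of published cognate collections: per-pair class counts ν heavily skewed
towards 1, a modest missing-data fraction, and κ-subsets that shrink as κ
grows.  Missing data are modelled by exogenous independent tip masking; no
mechanistic loss process is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import BitVectorMatrix, symbol_to_state
from .errors import CogvecError
from .likelihood import random_topology
from .models import SubstitutionModel, build_model
from .tree import PhyloTree
from .wordlist import CognateDataset

#: default per-κ concept counts, shrinking with κ like observed κ-subset sizes
DEFAULT_CONCEPTS_PER_KAPPA = {2: 40, 3: 25, 4: 12, 5: 8, 6: 5}


def random_tree(n_taxa: int, branch_mean: float = 0.25, seed: int | None = None) -> PhyloTree:
    """Uniform unrooted topology with i.i.d. exponential branch lengths."""
    if n_taxa < 3:
        raise CogvecError("a tree needs at least 3 taxa")
    if branch_mean <= 0:
        raise CogvecError("branch_mean must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"L{i + 1}" for i in range(n_taxa)]
    tree = random_topology(taxa, rng)
    for edge in tree.edges():
        edge.length = float(rng.exponential(branch_mean))
    tree.clamp_lengths()
    return tree


def simulate_matrix(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_columns: int,
    missing_prob: float = 0.0,
    seed: int | None = None,
) -> BitVectorMatrix:
    """Evolve ``n_columns`` independent characters down ``tree``.

    Each column draws its root state from the stationary frequencies Q and
    propagates it along every branch through P(t); each tip entry is then
    independently masked to missing with probability ``missing_prob``.
    """
    if n_columns < 1:
        raise CogvecError("n_columns must be at least 1")
    if not 0 <= missing_prob <= 1:
        raise CogvecError("missing_prob must lie in [0, 1]")
    if model.kind == "BIN":
        raise CogvecError("simulate_matrix produces bit-vector matrices; use a multistate model")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(model.n_states, size=n_columns, p=model.freqs)
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is not None:
            p = model.transition_matrix(node.length)
            cum = np.cumsum(p, axis=1)
            parent_states = states[id(node.parent)]
            u = rng.random(n_columns)
            child = (u[:, None] > cum[parent_states]).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf:
            tips[node.name] = states[id(node)]
    taxa = sorted(tips)
    data = np.stack([tips[t] for t in taxa]).astype(np.int16)
    if missing_prob > 0:
        mask = rng.random(data.shape) < missing_prob
        data[mask] = -1
    concepts = [f"c{j + 1}" for j in range(n_columns)]
    return BitVectorMatrix(taxa, concepts, model.kappa, data)


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic cognate dataset."""

    seed: int
    n_taxa: int = 16
    branch_mean: float = 0.25
    tree: PhyloTree | None = None
    concepts_per_kappa: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_CONCEPTS_PER_KAPPA)
    )
    model_kind: str = "COG"
    model_params: dict[int, dict] | None = None
    missing_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CogvecError("a simulation seed is mandatory")
        if any(n < 0 for n in self.concepts_per_kappa.values()):
            raise CogvecError("concept counts must be non-negative")
        if not 0 <= self.missing_prob <= 1:
            raise CogvecError("missing_prob must lie in [0, 1]")

    def model_for(self, kappa: int) -> SubstitutionModel:
        params = (self.model_params or {}).get(kappa)
        if params is None and self.model_kind in ("COG", "COGs"):
            # π_ν skewed towards small states, mirroring the empirical
            # observation that most language-concept pairs carry one class
            pi = [4.0 ** -(nu - 1) for nu in range(1, kappa + 1)]
            if self.model_kind == "COG":
                params = {"pi": pi, "lambda": [1.0] * (kappa - 1)}
            else:
                params = {"pi": pi, "lambda_plus": 1.0, "lambda_0": 0.1}
        return build_model(self.model_kind, kappa, params)


def simulate_cognate_dataset(config: SimulationConfig) -> tuple[CognateDataset, PhyloTree]:
    """Simulate a wordlist whose κ-subsets evolved under the configured model.

    Symbols are decoded back into concept-scoped cognate-class sets
    (labels ``c<i>_a``, ``c<i>_b``, …), so re-encoding the dataset reproduces
    the simulated symbol matrices exactly up to class-label renaming.
    """
    rng_seq = np.random.SeedSequence(config.seed)
    tree_seed, *column_seeds = rng_seq.spawn(1 + len(config.concepts_per_kappa))
    tree = config.tree
    if tree is None:
        tree = random_tree(
            config.n_taxa,
            config.branch_mean,
            int(tree_seed.generate_state(1)[0] % 2**31),
        )
    languages = tree.taxa
    concepts: list[str] = []
    assignments: dict[tuple[str, str], frozenset[str]] = {}
    concept_counter = 0
    for (kappa, count), sub_seed in zip(
        sorted(config.concepts_per_kappa.items()), column_seeds
    ):
        if count == 0:
            continue
        model = config.model_for(kappa)
        matrix = simulate_matrix(
            tree, model, count, config.missing_prob,
            int(sub_seed.generate_state(1)[0] % 2**31),
        )
        letters = "abcdef"
        for j in range(count):
            concept_counter += 1
            name = f"c{concept_counter}"
            concepts.append(name)
            order = tuple(f"{name}_{letters[i]}" for i in range(kappa))
            for i, lang in enumerate(matrix.taxa):
                sym = int(matrix.data[i, j])
                if sym >= 0:
                    assignments[(lang, name)] = symbol_to_state(sym, order)
    dataset = CognateDataset(list(languages), concepts, assignments)
    return dataset, tree
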