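"""Model comparison, cross-validation, and dataset diagnostics.

AIC = 2k − 2·log-likelihood compares models fitted to the *same* data
representation; fits on binary matrices (BIN) are never comparable with fits
on bit-vector matrices.  The cross-validation study quantifies
overparameterization: a model is fitted on a random 60% column subset, the
held-out 40% is scored with the fitted tree and parameters without any
re-optimization, and the relative error

    e = (llh_test_rel − llh_train_rel) / llh_train_rel

(per-column-normalized log-likelihoods) measures how much worse the model
generalizes than it fits.  Large positive e flags overfitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import (
    MISSING_CODE,
    BinaryMatrix,
    BitVectorMatrix,
    ConceptInventory,
    encode_bitvector,
    kappa_partition,
)
from .errors import ComparabilityError, EmptyDatasetError, TooFewColumnsError
from .likelihood import FitResult, LikelihoodWorkspace, run_search
from .models import build_model, free_parameter_count
from .wordlist import CognateDataset

Matrix = BinaryMatrix | BitVectorMatrix


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion; lower scores indicate a superior fit."""
    if not math.isfinite(loglik):
        raise ValueError("AIC needs a finite log-likelihood")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    return 2.0 * k - 2.0 * loglik


@dataclass
class ModelComparison:
    """Per-model search results on a shared bit-vector matrix."""

    table: pd.DataFrame
    fits: dict[str, FitResult] = field(default_factory=dict)

    def best(self) -> str:
        return str(self.table.sort_values("aic").iloc[0]["model"])


def compare_models(
    matrix: BitVectorMatrix,
    kinds: list[str],
    seed: int | None = None,
    n_random: int = 10,
    n_parsimony: int = 10,
) -> ModelComparison:
    """Fit each model kind by tree search and tabulate llh, k, and AIC.

    BIN is rejected: it runs on binary matrices, and AIC scores across data
    representations are not comparable.
    """
    if "BIN" in kinds:
        raise ComparabilityError(
            "BIN fits binary matrices; its AIC is not comparable with "
            "bit-vector models on this representation"
        )
    rows = []
    fits: dict[str, FitResult] = {}
    for kind in kinds:
        model = build_model(kind, matrix.kappa)
        fit = run_search(
            matrix, model, n_random=n_random, n_parsimony=n_parsimony, seed=seed
        )
        fits[kind] = fit
        rows.append(
            {
                "model": kind,
                "loglik": fit.loglik,
                "k": free_parameter_count(kind, matrix.kappa),
                "aic": fit.aic,
            }
        )
    return ModelComparison(pd.DataFrame(rows), fits)


def relative_error(llh_train_rel: float, llh_test_rel: float) -> float:
    """Cross-validation relative error e."""
    return (llh_test_rel - llh_train_rel) / llh_train_rel


@dataclass(frozen=True)
class CrossvalRecord:
    fold: int
    split_seed: int
    train_columns: tuple[str, ...]
    llh_train_rel: float
    llh_test_rel: float
    error: float


@dataclass
class CrossvalResult:
    records: list[CrossvalRecord]

    @property
    def mean_error(self) -> float:
        return float(np.mean([r.error for r in self.records]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def crossval(
    matrix: Matrix,
    kind: str,
    ratio: float = 0.6,
    folds: int = 10,
    min_columns: int = 10,
    seed: int | None = None,
    n_random: int = 10,
    n_parsimony: int = 10,
) -> CrossvalResult:
    """Random-split cross-validation of one model kind.

    Each fold samples ⌊ratio·ncols⌋ columns without replacement as the
    training matrix, fits tree and parameters by full search, and evaluates
    the held-out columns on the fitted tree and parameters verbatim.
    Matrices below ``min_columns`` columns are excluded, mirroring the
    benchmark filter for too-small κ-subsets.
    """
    n = matrix.n_columns
    if n < min_columns:
        raise TooFewColumnsError(
            f"matrix has {n} columns; at least {min_columns} are required "
            "for a meaningful split"
        )
    n_train = int(ratio * n)
    if n_train < 1 or n_train >= n:
        raise TooFewColumnsError(f"ratio={ratio} leaves an empty train or test set")
    kappa = matrix.kappa if isinstance(matrix, BitVectorMatrix) else None
    seq = np.random.SeedSequence(seed if seed is not None else 0)
    records: list[CrossvalRecord] = []
    for fold, child in enumerate(seq.spawn(folds)):
        fold_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child)
        train_idx = sorted(rng.choice(n, size=n_train, replace=False).tolist())
        test_idx = [i for i in range(n) if i not in set(train_idx)]
        train = matrix.subset_columns(train_idx)
        test = matrix.subset_columns(test_idx)
        model = build_model(kind, kappa)
        fit = run_search(
            train, model, n_random=n_random, n_parsimony=n_parsimony, seed=fold_seed
        )
        test_llh = LikelihoodWorkspace(test, fit.model).log_likelihood(
            fit.tree, fit.model
        )
        llh_train_rel = fit.loglik / train.n_columns
        llh_test_rel = test_llh / test.n_columns
        if isinstance(matrix, BitVectorMatrix):
            names = tuple(matrix.concepts[i] for i in train_idx)
        else:
            names = tuple(f"{c}:{v}" for c, v in (matrix.columns[i] for i in train_idx))
        records.append(
            CrossvalRecord(
                fold=fold,
                split_seed=fold_seed,
                train_columns=names,
                llh_train_rel=llh_train_rel,
                llh_test_rel=llh_test_rel,
                error=relative_error(llh_train_rel, llh_test_rel),
            )
        )
    return CrossvalResult(records)


@dataclass
class EntropyProfile:
    """Per-column Shannon entropies (bits) and their sum."""

    per_column: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_column.sum())


def matrix_entropy(matrix: Matrix, base: float = 2.0) -> EntropyProfile:
    """Empirical per-column Shannon entropy over non-missing symbols.

    Missing entries are excluded from the column distribution; an all-missing
    column contributes zero.
    """
    if matrix.n_columns == 0:
        raise EmptyDatasetError("entropy of an empty matrix is undefined")
    data = matrix.data
    values = []
    for j in range(matrix.n_columns):
        col = data[:, j]
        col = col[col != MISSING_CODE]
        if col.size == 0:
            values.append(0.0)
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        values.append(float(-(p * (np.log(p) / np.log(base))).sum()))
    profile = EntropyProfile(np.asarray(values))
    if np.all(data == MISSING_CODE):
        import warnings

        warnings.warn("matrix is entirely missing; total entropy is 0", stacklevel=2)
    return profile


@dataclass
class DiagnosticsReport:
    """Shape statistics of a cognate dataset and its κ-subsets."""

    nu_distribution: dict[int, float]
    kappa_subset_sizes: dict[int, int]
    concepts_over_languages: dict[int, float]
    symbol_counts: dict[int, np.ndarray]


def dataset_diagnostics(
    dataset: CognateDataset, inventory: ConceptInventory
) -> DiagnosticsReport:
    """ν-distribution, κ-subset sizes/ratios, and per-κ symbol counts."""
    counts: dict[int, int] = {}
    total_pairs = dataset.n_languages * dataset.n_concepts
    for lang in dataset.languages:
        for concept in dataset.concepts:
            nu = dataset.nu(lang, concept)
            counts[nu] = counts.get(nu, 0) + 1
    nu_distribution = {nu: c / total_pairs for nu, c in sorted(counts.items())}
    partition = kappa_partition(inventory)
    sizes = {k: len(v) for k, v in sorted(partition.subsets.items())}
    ratios = {k: size / dataset.n_languages for k, size in sizes.items()}
    symbol_counts: dict[int, np.ndarray] = {}
    for kappa in sizes:
        matrix = encode_bitvector(dataset, inventory, kappa)
        tally = np.zeros(matrix.n_states, dtype=np.int64)
        observed = matrix.data[matrix.data != MISSING_CODE]
        for sym, c in zip(*np.unique(observed, return_counts=True)):
            tally[int(sym)] = int(c)
        symbol_counts[kappa] = tally
    return DiagnosticsReport(nu_distribution, sizes, ratios, symbol_counts)
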