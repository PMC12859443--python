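"""Character-matrix encodings of cognate data.

Two encodings are supported.  The *binary* encoding expands every concept into
κ presence/absence columns, one per cognate class.  The *bit-vector* encoding
represents a concept by a single multistate column: the presence/absence
pattern over the concept's κ classes is a non-zero bit string b of length κ,
mapped to the symbol Σm[∫(b) − 1], where ∫(b) is the integer with binary
representation b (leftmost class = most significant bit) and Σm is an ordered
64-symbol alphabet.  The all-zero bit vector never receives a symbol — it
denotes missing data — so a concept with κ classes needs 2^κ − 1 symbols and
the 64-symbol alphabet caps κ at 6.

Because the number of states depends on κ, bit-vector matrices only ever mix
concepts with the same κ ("κ-subsets").
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlphabetCapacityError, EmptyDatasetError, FormatError
from .wordlist import CognateDataset

MISSING = "-"
#: entries in the integer matrices that mark missing data
MISSING_CODE = -1

KAPPA_MIN = 2
KAPPA_MAX = 6


@dataclass(frozen=True)
class SymbolAlphabet:
    """Ordered multistate alphabet Σm, at most 64 printable symbols."""

    symbols: str = string.digits + string.ascii_uppercase + string.ascii_lowercase + "!*"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise FormatError("alphabet symbols must be distinct")
        if MISSING in self.symbols:
            raise FormatError(f"{MISSING!r} is reserved for missing data")
        if len(self.symbols) > 64:
            raise AlphabetCapacityError("alphabet is limited to 64 symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def symbol(self, index: int) -> str:
        return self.symbols[index]

    def index(self, symbol: str) -> int:
        pos = self.symbols.find(symbol)
        if pos < 0:
            raise FormatError(f"symbol {symbol!r} is not in the alphabet")
        return pos

    def max_kappa(self) -> int:
        """Largest κ such that 2^κ − 1 states fit into the alphabet."""
        kappa = 1
        while 2 ** (kappa + 1) - 1 <= len(self.symbols):
            kappa += 1
        return kappa


DEFAULT_ALPHABET = SymbolAlphabet()


@dataclass
class ConceptInventory:
    """Per-concept cognate-class inventories V_c (lexicographic order) and κ = |V_c|."""

    classes: dict[str, tuple[str, ...]]
    concept_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.concept_order:
            self.concept_order = list(self.classes)

    def kappa(self, concept: str) -> int:
        return len(self.classes[concept])

    def __contains__(self, concept: str) -> bool:
        return concept in self.classes

    def __len__(self) -> int:
        return len(self.classes)


def build_inventory(dataset: CognateDataset) -> ConceptInventory:
    """Union each concept's classes over all languages; sort lexicographically.

    Concepts attested in no language carry no information and are dropped with
    a warning.
    """
    if dataset.n_concepts == 0:
        raise EmptyDatasetError("cannot build an inventory without concepts")
    classes: dict[str, tuple[str, ...]] = {}
    order: list[str] = []
    dropped: list[str] = []
    for concept in dataset.concepts:
        union: set[str] = set()
        for lang in dataset.languages:
            union |= dataset.classes(lang, concept)
        if union:
            classes[concept] = tuple(sorted(union))
            order.append(concept)
        else:
            dropped.append(concept)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} concept(s) attested in no language: {dropped[:5]}",
            stacklevel=2,
        )
    return ConceptInventory(classes, order)


@dataclass
class BinaryMatrix:
    """Presence/absence matrix A^b: rows = languages, one column per (concept, class).

    ``data`` holds 0/1 with MISSING_CODE for missing; if a language has no
    word for a concept (ν = 0) every class column of that concept is missing.
    """

    taxa: list[str]
    columns: list[tuple[str, str]]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.taxa), len(self.columns)):
            raise FormatError("binary matrix shape does not match taxa/columns")

    @property
    def n_states(self) -> int:
        return 2

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def column_strings(self) -> list[str]:
        lookup = {MISSING_CODE: MISSING, 0: "0", 1: "1"}
        return ["".join(lookup[int(v)] for v in row) for row in self.data]

    def subset_columns(self, indices: list[int]) -> "BinaryMatrix":
        return BinaryMatrix(
            list(self.taxa),
            [self.columns[i] for i in indices],
            self.data[:, indices].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.data, other.data)


@dataclass
class BitVectorMatrix:
    """Multistate matrix A^v for one κ-subset: one column per concept.

    ``data`` holds symbol indices in [0, 2^κ − 2] (MISSING_CODE for missing).
    ``class_orders`` records, per column, the lexicographic class order that
    fixes the bit layout, so symbols can be decoded back to class sets.
    """

    taxa: list[str]
    concepts: list[str]
    kappa: int
    data: np.ndarray
    class_orders: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if not KAPPA_MIN <= self.kappa <= KAPPA_MAX:
            raise AlphabetCapacityError(
                f"kappa={self.kappa} outside [{KAPPA_MIN}, {KAPPA_MAX}]"
            )
        if self.data.shape != (len(self.taxa), len(self.concepts)):
            raise FormatError("bit-vector matrix shape does not match taxa/concepts")
        valid = (self.data == MISSING_CODE) | (
            (self.data >= 0) & (self.data <= 2**self.kappa - 2)
        )
        if not valid.all():
            raise FormatError("symbol index outside [0, 2^kappa - 2]")
        if not self.class_orders:
            self.class_orders = [
                tuple(f"s{i}" for i in range(self.kappa)) for _ in self.concepts
            ]

    @property
    def n_states(self) -> int:
        return 2**self.kappa - 1

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def subset_columns(self, indices: list[int]) -> "BitVectorMatrix":
        return BitVectorMatrix(
            list(self.taxa),
            [self.concepts[i] for i in indices],
            self.kappa,
            self.data[:, indices].copy(),
            [self.class_orders[i] for i in indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BitVectorMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.kappa == other.kappa
            and np.array_equal(self.data, other.data)
        )


def state_to_symbol(
    state: frozenset[str] | set[str],
    class_order: tuple[str, ...],
    alphabet: SymbolAlphabet = DEFAULT_ALPHABET,
) -> int:
    """Map a non-empty class set to its 0-based symbol index ∫(b) − 1.

    The bit for the first class in ``class_order`` is the most significant;
    the all-zero vector (empty state) has no symbol and must be handled by the
    caller as missing data.
    """
    if not state:
        raise FormatError("empty state has no symbol; encode it as missing")
    unknown = set(state) - set(class_order)
    if unknown:
        raise FormatError(f"state contains classes outside the concept inventory: {unknown}")
    kappa = len(class_order)
    if 2**kappa - 1 > len(alphabet):
        raise AlphabetCapacityError(
            f"kappa={kappa} needs {2**kappa - 1} symbols, alphabet has {len(alphabet)}"
        )
    value = 0
    for i, cls in enumerate(class_order):
        if cls in state:
            value |= 1 << (kappa - 1 - i)
    return value - 1


def symbol_to_state(index: int, class_order: tuple[str, ...]) -> frozenset[str]:
    """Inverse of :func:`state_to_symbol` on non-zero bit vectors."""
    kappa = len(class_order)
    value = index + 1
    if not 1 <= value <= 2**kappa - 1:
        raise FormatError(f"symbol index {index} out of range for kappa={kappa}")
    return frozenset(
        cls for i, cls in enumerate(class_order) if value & (1 << (kappa - 1 - i))
    )


def encode_binary(dataset: CognateDataset, inventory: ConceptInventory) -> BinaryMatrix:
    """Build the binary presence/absence matrix A^b."""
    columns: list[tuple[str, str]] = []
    for concept in inventory.concept_order:
        columns.extend((concept, cls) for cls in inventory.classes[concept])
    data = np.full((dataset.n_languages, len(columns)), MISSING_CODE, dtype=np.int8)
    for i, lang in enumerate(dataset.languages):
        j = 0
        for concept in inventory.concept_order:
            classes = inventory.classes[concept]
            state = dataset.classes(lang, concept)
            if state:
                for cls in classes:
                    data[i, j] = 1 if cls in state else 0
                    j += 1
            else:
                j += len(classes)  # stays missing: ν = 0
    return BinaryMatrix(list(dataset.languages), columns, data)


@dataclass(frozen=True)
class KappaPartition:
    """Concepts grouped by κ ∈ [2, 6] plus the excluded concepts."""

    subsets: dict[int, list[str]]
    excluded_singleton: list[str]
    excluded_large: list[str]


def kappa_partition(inventory: ConceptInventory) -> KappaPartition:
    """Group concepts into κ-subsets.

    κ = 1 concepts carry no topological signal and κ > 6 concepts exceed the
    64-symbol alphabet; both are excluded and reported.
    """
    subsets: dict[int, list[str]] = {}
    singletons: list[str] = []
    large: list[str] = []
    for concept in inventory.concept_order:
        kappa = inventory.kappa(concept)
        if kappa == 1:
            singletons.append(concept)
        elif kappa > KAPPA_MAX:
            large.append(concept)
        else:
            subsets.setdefault(kappa, []).append(concept)
    return KappaPartition(subsets, singletons, large)


def encode_bitvector(
    dataset: CognateDataset,
    inventory: ConceptInventory,
    kappa: int,
    alphabet: SymbolAlphabet = DEFAULT_ALPHABET,
) -> BitVectorMatrix:
    """Build the bit-vector matrix A^v for the κ-subset of the dataset."""
    if not KAPPA_MIN <= kappa <= KAPPA_MAX:
        raise AlphabetCapacityError(
            f"kappa={kappa} rejected: {2**kappa - 1} symbols needed, "
            f"alphabet allows at most {2**KAPPA_MAX - 1} (|Σm| ≤ 64)"
        )
    concepts = [c for c in inventory.concept_order if inventory.kappa(c) == kappa]
    if not concepts:
        raise EmptyDatasetError(f"no concepts with kappa={kappa}")
    class_orders = [inventory.classes[c] for c in concepts]
    data = np.full((dataset.n_languages, len(concepts)), MISSING_CODE, dtype=np.int16)
    for i, lang in enumerate(dataset.languages):
        for j, (concept, order) in enumerate(zip(concepts, class_orders)):
            state = dataset.classes(lang, concept)
            if state:
                data[i, j] = state_to_symbol(state, order, alphabet)
    return BitVectorMatrix(list(dataset.languages), concepts, kappa, data, class_orders)


def write_phylip(matrix: BinaryMatrix | BitVectorMatrix, path: str | Path,
                 alphabet: SymbolAlphabet = DEFAULT_ALPHABET) -> None:
    """Write a matrix as relaxed PHYLIP (header "ntaxa ncols", name + row)."""
    if len(set(matrix.taxa)) != len(matrix.taxa):
        raise FormatError("duplicate taxon names")
    if any(any(ch.isspace() for ch in t) for t in matrix.taxa):
        raise FormatError("taxon names must be whitespace-free")
    lines = [f"{len(matrix.taxa)} {matrix.n_columns}"]
    if isinstance(matrix, BinaryMatrix):
        rows = matrix.column_strings()
    else:
        rows = [
            "".join(
                MISSING if v == MISSING_CODE else alphabet.symbol(int(v)) for v in row
            )
            for row in matrix.data
        ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, rows):
        lines.append(f"{taxon:<{width}}{row}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phylip(
    path: str | Path,
    kind: str,
    kappa: int | None = None,
    alphabet: SymbolAlphabet = DEFAULT_ALPHABET,
) -> BinaryMatrix | BitVectorMatrix:
    """Read a relaxed PHYLIP matrix.

    ``kind`` is "binary" or "bitvector".  For bit-vector matrices κ is taken
    from ``kappa`` or, if omitted, inferred as the smallest κ whose 2^κ − 1
    states cover every symbol present.
    """
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise EmptyDatasetError("empty PHYLIP file")
    try:
        ntaxa, ncols = (int(tok) for tok in lines[0].split())
    except ValueError as exc:
        raise FormatError("malformed PHYLIP header") from exc
    if len(lines) - 1 != ntaxa:
        raise FormatError(f"expected {ntaxa} rows, found {len(lines) - 1}")
    taxa: list[str] = []
    rows: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise FormatError(f"malformed PHYLIP row: {ln!r}")
        name, row = parts
        if len(row) != ncols:
            raise FormatError(f"row for {name!r} has {len(row)} columns, expected {ncols}")
        taxa.append(name)
        rows.append(row)
    if len(set(taxa)) != len(taxa):
        raise FormatError("duplicate taxon names")
    if kind == "binary":
        lookup = {MISSING: MISSING_CODE, "0": 0, "1": 1}
        try:
            data = np.array([[lookup[ch] for ch in row] for row in rows], dtype=np.int8)
        except KeyError as exc:
            raise FormatError(f"invalid binary symbol {exc.args[0]!r}") from exc
        columns = [(f"c{j}", "x") for j in range(ncols)]
        return BinaryMatrix(taxa, columns, data)
    if kind == "bitvector":
        data = np.empty((ntaxa, ncols), dtype=np.int16)
        for i, row in enumerate(rows):
            for j, ch in enumerate(row):
                data[i, j] = MISSING_CODE if ch == MISSING else alphabet.index(ch)
        max_index = int(data.max(initial=0))
        if kappa is None:
            kappa = KAPPA_MIN
            while 2**kappa - 2 < max_index:
                kappa += 1
        if max_index > 2**kappa - 2:
            raise FormatError(
                f"symbol index {max_index} exceeds the kappa={kappa} state space"
            )
        concepts = [f"c{j}" for j in range(ncols)]
        return BitVectorMatrix(taxa, concepts, kappa, data)
    raise FormatError(f"unknown matrix kind {kind!r}")
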