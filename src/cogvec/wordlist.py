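"""Cognate wordlists: reading, writing, coverage, and data-inclusion criteria.

A cognate dataset records, for every language ``l`` and elicitation concept
``c`` (a meaning slot such as "hand"), the set of cognate classes to which the
words of ``l`` for ``c`` belong.  The size of that set is called ν: ν = 1 is
the common case (one word, one class), ν > 1 marks polymorphism (synonyms in
different classes), and ν = 0 means no word is recorded, which is treated as
missing data throughout the package.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import EmptyDatasetError, FormatError

LONG_TSV_COLUMNS = ("Language_ID", "Parameter_ID", "Cognateset_ID")


@dataclass
class CognateDataset:
    """Languages L, concepts C, and the assignment M: (l, c) -> set of classes.

    ``assignments`` omits pairs with no recorded word; for those pairs ν = 0
    and the data are missing.  Class labels are scoped per concept: the same
    label under two different concepts denotes two unrelated cognate classes.
    """

    languages: list[str]
    concepts: list[str]
    assignments: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lang_set = set(self.languages)
        concept_set = set(self.concepts)
        if len(lang_set) != len(self.languages):
            raise FormatError("duplicate language identifiers")
        if len(concept_set) != len(self.concepts):
            raise FormatError("duplicate concept identifiers")
        clean: dict[tuple[str, str], frozenset[str]] = {}
        for (lang, concept), classes in self.assignments.items():
            if lang not in lang_set or concept not in concept_set:
                raise FormatError(f"assignment ({lang!r}, {concept!r}) outside L x C")
            classes = frozenset(classes)
            if any(not isinstance(v, str) or not v for v in classes):
                raise FormatError("cognate-class labels must be non-empty strings")
            if classes:
                clean[(lang, concept)] = classes
        self.assignments = clean

    def classes(self, language: str, concept: str) -> frozenset[str]:
        """Return M(l, c); the empty set encodes missing data (ν = 0)."""
        return self.assignments.get((language, concept), frozenset())

    def nu(self, language: str, concept: str) -> int:
        return len(self.classes(language, concept))

    @property
    def n_languages(self) -> int:
        return len(self.languages)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CognateDataset):
            return NotImplemented
        return (
            self.languages == other.languages
            and self.concepts == other.concepts
            and self.assignments == other.assignments
        )


def read_wordlist(path: str | Path, dialect: str = "long-tsv") -> CognateDataset:
    """Read a cognate dataset from a TSV file.

    ``long-tsv`` has one row per (language, concept, class) triple with header
    columns Language_ID, Parameter_ID, Cognateset_ID (CLDF FormTable naming).
    ``matrix-tsv`` has languages as rows, concepts as columns, and cells that
    hold comma-separated class labels; an empty cell is missing data.
    Languages and concepts keep first-appearance order; duplicate rows
    deduplicate under set semantics.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_wordlist(text, dialect=dialect)


def parse_wordlist(text: str, dialect: str = "long-tsv") -> CognateDataset:
    if dialect == "long-tsv":
        return _parse_long(text)
    if dialect == "matrix-tsv":
        return _parse_matrix(text)
    raise FormatError(f"unknown wordlist dialect {dialect!r}")


def _parse_long(text: str) -> CognateDataset:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None:
        raise EmptyDatasetError("empty wordlist file")
    missing = [c for c in LONG_TSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"long-tsv is missing required columns: {missing}")
    languages: list[str] = []
    concepts: list[str] = []
    assignments: dict[tuple[str, str], set[str]] = {}
    for row in reader:
        lang = row["Language_ID"]
        concept = row["Parameter_ID"]
        cls = row["Cognateset_ID"]
        if lang is None or concept is None or cls is None:
            raise FormatError("short row in long-tsv wordlist")
        if lang not in assignments_keys(languages):
            languages.append(lang)
        if concept not in assignments_keys(concepts):
            concepts.append(concept)
        if cls:
            assignments.setdefault((lang, concept), set()).add(cls)
    if not languages:
        raise EmptyDatasetError("wordlist contains no data rows")
    return CognateDataset(
        languages, concepts, {k: frozenset(v) for k, v in assignments.items()}
    )


def assignments_keys(seq: list[str]) -> set[str]:
    # first-appearance order with O(1) membership would need a dict; datasets
    # are small enough that set(seq) per row is acceptable and keeps this simple
    return set(seq)


def _parse_matrix(text: str) -> CognateDataset:
    rows = list(csv.reader(io.StringIO(text), delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if not rows:
        raise EmptyDatasetError("empty wordlist file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError("matrix-tsv needs at least one concept column")
    concepts = [c.strip() for c in header[1:]]
    languages: list[str] = []
    assignments: dict[tuple[str, str], frozenset[str]] = {}
    for row in rows[1:]:
        lang = row[0].strip()
        languages.append(lang)
        cells = row[1:]
        if len(cells) != len(concepts):
            raise FormatError(f"row for {lang!r} has {len(cells)} cells, expected {len(concepts)}")
        for concept, cell in zip(concepts, cells):
            labels = frozenset(v.strip() for v in cell.split(",") if v.strip())
            if labels:
                assignments[(lang, concept)] = labels
    if not languages:
        raise EmptyDatasetError("matrix-tsv has a header but no language rows")
    return CognateDataset(languages, concepts, dict(assignments))


def write_wordlist(dataset: CognateDataset, path: str | Path, dialect: str = "long-tsv") -> None:
    """Write a dataset in either TSV dialect; read∘write is the identity on M."""
    path = Path(path)
    if dialect == "long-tsv":
        lines = ["\t".join(LONG_TSV_COLUMNS)]
        for lang in dataset.languages:
            for concept in dataset.concepts:
                for cls in sorted(dataset.classes(lang, concept)):
                    lines.append(f"{lang}\t{concept}\t{cls}")
    elif dialect == "matrix-tsv":
        lines = ["\t".join(["Language_ID"] + dataset.concepts)]
        for lang in dataset.languages:
            cells = [
                ",".join(sorted(dataset.classes(lang, concept)))
                for concept in dataset.concepts
            ]
            lines.append("\t".join([lang] + cells))
    else:
        raise FormatError(f"unknown wordlist dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def average_coverage(dataset: CognateDataset) -> float:
    """Mean over languages of the fraction of concepts with at least one word."""
    if dataset.n_concepts == 0 or dataset.n_languages == 0:
        raise EmptyDatasetError("coverage is undefined for a dataset without concepts")
    total = 0.0
    for lang in dataset.languages:
        covered = sum(1 for c in dataset.concepts if dataset.nu(lang, c) >= 1)
        total += covered / dataset.n_concepts
    return total / dataset.n_languages


@dataclass(frozen=True)
class InclusionReport:
    """Per-criterion verdicts of the data-inclusion filter."""

    passed: bool
    criteria: Mapping[str, tuple[float, float, bool]]
    """criterion name -> (observed value, threshold, verdict)."""


def apply_inclusion_criteria(
    dataset: CognateDataset,
    min_languages: int = 4,
    min_concepts: int = 85,
    min_avg_coverage: float = 0.45,
    require_concepts_ge_languages: bool = True,
) -> InclusionReport:
    """Check the benchmark data-inclusion criteria.

    Defaults: at least 4 languages and 85 concepts, average coverage >= 0.45,
    and at least as many concepts as languages.
    """
    n_lang = dataset.n_languages
    n_concept = dataset.n_concepts
    coverage = average_coverage(dataset) if n_concept and n_lang else 0.0
    criteria = {
        "min_languages": (float(n_lang), float(min_languages), n_lang >= min_languages),
        "min_concepts": (float(n_concept), float(min_concepts), n_concept >= min_concepts),
        "min_avg_coverage": (coverage, min_avg_coverage, coverage >= min_avg_coverage),
    }
    if require_concepts_ge_languages:
        criteria["concepts_ge_languages"] = (
            float(n_concept),
            float(n_lang),
            n_concept >= n_lang,
        )
    passed = all(ok for _, _, ok in criteria.values())
    return InclusionReport(passed=passed, criteria=criteria)
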