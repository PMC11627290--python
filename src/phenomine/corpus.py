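"""Corpora, term dictionaries and sparse term-document matrices.

The in-memory containers here are deliberately small: an abstract is an
(id, text) pair, a dictionary maps surface forms to canonical terms, and a
term-document matrix is a ``scipy.sparse`` matrix with label registries.
On disk the package uses MEDLINE/PubMed XML (read-only), JSON-lines for
corpora, TSV for dictionaries and Matrix Market plus label sidecars for
matrices — all plain-text, language-neutral formats.
"""

from __future__ import annotations

import gzip
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from lxml import etree

__all__ = [
    "Abstract",
    "Corpus",
    "TermEntry",
    "TermDictionary",
    "TermDocMatrix",
    "DictionaryError",
    "CorpusError",
    "read_medline_xml",
    "read_jsonl_corpus",
    "write_jsonl_corpus",
    "read_dictionary_tsv",
    "write_matrix",
    "read_matrix",
]

_WS = re.compile(r"\s+")


def _normalize_ws(s: str) -> str:
    return _WS.sub(" ", s).strip()


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus input."""


class DictionaryError(ValueError):
    """Raised for malformed or ambiguous term dictionaries."""


@dataclass(frozen=True)
class Abstract:
    """One document: an opaque identifier (PMID for PubMed) and free text."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("abstract id must be non-empty")


class Corpus:
    """An ordered collection of abstracts with unique ids.

    Iteration order is stable and equals input order; duplicate ids are
    rejected at construction.
    """

    def __init__(self, abstracts: Iterable[Abstract], source_label: str = "") -> None:
        self.abstracts: list[Abstract] = list(abstracts)
        self.source_label = source_label
        seen: set[str] = set()
        for a in self.abstracts:
            if a.id in seen:
                raise CorpusError(f"duplicate abstract id: {a.id!r}")
            seen.add(a.id)
        self._index = {a.id: a for a in self.abstracts}

    def __len__(self) -> int:
        return len(self.abstracts)

    def __iter__(self) -> Iterator[Abstract]:
        return iter(self.abstracts)

    def __getitem__(self, abstract_id: str) -> Abstract:
        return self._index[abstract_id]

    def __contains__(self, abstract_id: str) -> bool:
        return abstract_id in self._index

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.abstracts]

    def subset(self, ids: Sequence[str]) -> "Corpus":
        """Sub-corpus restricted to ``ids``, in the given order."""
        return Corpus([self._index[i] for i in ids], source_label=self.source_label)


@dataclass
class TermEntry:
    """A canonical term with its synonyms / spelling analogues.

    Synonym matches are always counted toward the canonical label, so
    downstream matrices and statistics only ever see canonical terms.
    """

    canonical: str
    synonyms: list[str] = field(default_factory=list)
    concept_id: str | None = None
    semantic_tag: str | None = None

    @property
    def surface_forms(self) -> list[str]:
        return [self.canonical, *self.synonyms]


class TermDictionary:
    """A named set of term entries with an unambiguous surface-form map.

    Invariants enforced at construction: canonical labels are unique, every
    surface form is non-empty after whitespace normalization, and no surface
    form resolves to two different canonical terms.
    """

    def __init__(self, entries: Iterable[TermEntry], name: str = "") -> None:
        self.entries: list[TermEntry] = list(entries)
        self.name = name
        self._by_canonical: dict[str, TermEntry] = {}
        surface_owner: dict[str, str] = {}
        for e in self.entries:
            e.canonical = _normalize_ws(e.canonical)
            if not e.canonical:
                raise DictionaryError("empty canonical label")
            if e.canonical in self._by_canonical:
                raise DictionaryError(f"duplicate canonical label: {e.canonical!r}")
            self._by_canonical[e.canonical] = e
            e.synonyms = [_normalize_ws(s) for s in e.synonyms]
            if any(not s for s in e.synonyms):
                raise DictionaryError(f"empty synonym under {e.canonical!r}")
        for e in self.entries:
            for form in e.surface_forms:
                key = form.casefold()
                owner = surface_owner.get(key)
                if owner is not None and owner != e.canonical:
                    raise DictionaryError(
                        f"ambiguous surface form {form!r}: maps to both "
                        f"{owner!r} and {e.canonical!r}"
                    )
                surface_owner[key] = e.canonical
        self._surface_owner = surface_owner

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TermEntry]:
        return iter(self.entries)

    def __getitem__(self, canonical: str) -> TermEntry:
        return self._by_canonical[canonical]

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._by_canonical

    @property
    def canonical_terms(self) -> list[str]:
        return [e.canonical for e in self.entries]

    @property
    def n_surface_forms(self) -> int:
        return sum(len(e.surface_forms) for e in self.entries)

    def surface_to_canonical(self) -> dict[str, str]:
        """Case-folded surface form -> canonical label."""
        return dict(self._surface_owner)


@dataclass
class TermDocMatrix:
    """Sparse terms x abstracts matrix with label registries.

    ``mode`` is ``"presence"`` (cells in {0, 1}) or ``"count"`` (non-negative
    occurrence counts, repeats within an abstract included).
    """

    row_labels: list[str]
    col_labels: list[str]
    values: sp.csr_matrix
    mode: str = "presence"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.mode not in ("presence", "count"):
            raise ValueError(f"unknown matrix mode {self.mode!r}")
        r, c = self.values.shape
        if r != len(self.row_labels) or c != len(self.col_labels):
            raise ValueError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != r:
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != c:
            raise ValueError("duplicate column labels")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("matrix values must be non-negative")
        if self.mode == "presence" and self.values.nnz and self.values.data.max() > 1:
            raise ValueError("presence-mode matrix must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, label: str) -> int:
        try:
            return self.row_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown term {label!r}") from None

    def col_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.col_labels)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown abstract id {exc.args[0]!r}") from None

    def binarize(self) -> "TermDocMatrix":
        """Presence-mode copy (counts clipped to 0/1)."""
        v = self.values.copy()
        v.data = np.minimum(v.data, 1)
        return TermDocMatrix(list(self.row_labels), list(self.col_labels), v, "presence")


# ---------------------------------------------------------------------------
# MEDLINE / PubMed XML


def _open_maybe_gzip(path: str | Path) -> io.BufferedReader:
    fh = open(path, "rb")
    magic = fh.peek(2)[:2]
    if magic == b"\x1f\x8b":
        return gzip.open(fh, "rb")  # type: ignore[return-value]
    return fh


def read_medline_xml(path: str | Path, include_title: bool = True) -> Corpus:
    """Read a MEDLINE/PubMed XML citation file (plain or gzip-compressed).

    One :class:`Abstract` per ``PubmedArticle``/``MedlineCitation`` record;
    text is the article title followed by all ``AbstractText`` sections joined
    by single spaces (section labels discarded). Records without an abstract
    body fall back to the title alone. Parsing is streaming, so memory use is
    bounded per record.

    Whether titles were part of the searched text is a corpus-construction
    choice; ``include_title=False`` restricts text to the abstract body.
    """
    abstracts: list[Abstract] = []
    with _open_maybe_gzip(path) as fh:
        try:
            for _, elem in etree.iterparse(fh, tag="MedlineCitation"):
                pmid_el = elem.find("PMID")
                if pmid_el is None or not (pmid_el.text or "").strip():
                    raise CorpusError("MedlineCitation without PMID")
                pmid = pmid_el.text.strip()
                title = "".join(elem.find("Article/ArticleTitle").itertext()) \
                    if elem.find("Article/ArticleTitle") is not None else ""
                sections = [
                    _normalize_ws("".join(at.itertext()))
                    for at in elem.findall("Article/Abstract/AbstractText")
                ]
                parts = ([_normalize_ws(title)] if include_title else []) + \
                    [s for s in sections if s]
                abstracts.append(Abstract(pmid, _normalize_ws(" ".join(parts))))
                elem.clear()
                while elem.getprevious() is not None:
                    del elem.getparent()[0]
        except etree.XMLSyntaxError as exc:
            raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    return Corpus(abstracts, source_label=str(path))


# ---------------------------------------------------------------------------
# JSONL interchange


def read_jsonl_corpus(path: str | Path) -> Corpus:
    """Read a one-record-per-line JSON corpus with fields ``id`` and ``text``."""
    abstracts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            for key in ("id", "text"):
                if key not in rec:
                    raise CorpusError(f"{path}: line {lineno}: missing field {key!r}")
            abstracts.append(Abstract(str(rec["id"]), str(rec["text"])))
    return Corpus(abstracts, source_label=str(path))


def write_jsonl_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in corpus:
            fh.write(json.dumps({"id": a.id, "text": a.text}, ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Dictionary TSV


def read_dictionary_tsv(path: str | Path, name: str | None = None) -> TermDictionary:
    """Read a term dictionary from TSV.

    Columns (header required): ``canonical``, ``synonym`` (empty on the row
    declaring the canonical itself), optional ``concept_id`` and
    ``semantic_tag``. Synonym rows are grouped under their canonical; an
    ambiguous synonym (same surface form under two canonicals) is a load
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"canonical", "synonym"}
    if not required.issubset(df.columns):
        raise DictionaryError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    entries: dict[str, TermEntry] = {}
    for _, row in df.iterrows():
        canonical = _normalize_ws(row["canonical"])
        if not canonical:
            raise DictionaryError(f"{path}: empty canonical label")
        entry = entries.get(canonical)
        if entry is None:
            entry = TermEntry(canonical)
            entries[canonical] = entry
        synonym = _normalize_ws(row["synonym"])
        if synonym and synonym.casefold() != canonical.casefold():
            entry.synonyms.append(synonym)
        cid = _normalize_ws(row["concept_id"]) if "concept_id" in df.columns else ""
        tag = _normalize_ws(row["semantic_tag"]) if "semantic_tag" in df.columns else ""
        if cid and entry.concept_id is None:
            entry.concept_id = cid
        if tag and entry.semantic_tag is None:
            entry.semantic_tag = tag
    return TermDictionary(entries.values(), name=name or Path(path).stem)


# ---------------------------------------------------------------------------
# Matrix Market + label sidecars


def write_matrix(matrix: TermDocMatrix, prefix: str | Path) -> None:
    """Write a matrix as ``<prefix>.mtx`` plus ``<prefix>.rows.txt`` /
    ``<prefix>.cols.txt`` sidecars (one label per line, index order).

    The mode flag travels in the MTX comment header, so a round trip is
    lossless.
    """
    prefix = Path(prefix)
    scipy.io.mmwrite(
        str(prefix) + ".mtx",
        matrix.values.tocoo(),
        comment=f"phenomine mode={matrix.mode}",
        field="integer",
    )
    for suffix, labels in ((".rows.txt", matrix.row_labels), (".cols.txt", matrix.col_labels)):
        with open(str(prefix) + suffix, "w", encoding="utf-8") as fh:
            fh.write("\n".join(labels))
            if labels:
                fh.write("\n")


def _read_labels(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def read_matrix(prefix: str | Path) -> TermDocMatrix:
    prefix = Path(prefix)
    mtx_path = str(prefix) + ".mtx"
    values = sp.csr_matrix(scipy.io.mmread(mtx_path))
    mode = "count"
    with open(mtx_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("%"):
                break
            m = re.search(r"phenomine mode=(\w+)", line)
            if m:
                mode = m.group(1)
    rows = _read_labels(str(prefix) + ".rows.txt")
    cols = _read_labels(str(prefix) + ".cols.txt")
    if (len(rows), len(cols)) != values.shape:
        raise ValueError(
            f"label sidecars ({len(rows)}, {len(cols)}) do not match matrix "
            f"shape {values.shape}"
        )
    return TermDocMatrix(rows, cols, values, mode)
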