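"""Presence matrices, abstract-selection filters and candidate-term discovery.

The selection logic mirrors a two-stage corpus narrowing: abstracts are
kept when they contain at least ``min_terms`` distinct clinical terms and
(optionally) at least one aging keyword; the retained sub-corpus is then
mined against a large candidate vocabulary, keeping terms that are frequent
enough and whose ontology category is informative (administrative
categories such as "procedure" or "qualifier value", and '/'-containing
unit strings such as "mg/dl", are discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, TermDictionary, TermDocMatrix
from .matching import MatchProfile, compile_matcher, match_corpus

__all__ = [
    "FilterReport",
    "CandidateTerm",
    "DEFAULT_EXCLUDED_TAGS",
    "build_presence_matrix",
    "filter_abstracts",
    "discover_candidates",
]

#: Ontology semantic tags excluded by default from candidate discovery.
DEFAULT_EXCLUDED_TAGS: frozenset[str] = frozenset(
    {
        "procedure",
        "qualifier value",
        "body structure",
        "attribute",
        "organism",
        "person",
        "regime/therapy",
        "ethnic group",
        "environment",
        "physical object",
        "tumor staging",
        "geographic location",
    }
)


@dataclass
class FilterReport:
    """Counts and retained abstract-id sets for each selection stage.

    Invariant: ``n_keyword_and_min <= min(n_keyword, n_ge_min) <= n_ge1
    <= n_total``.
    """

    n_total: int
    n_ge1_terms: int
    n_ge_min_terms: int
    n_keyword: int
    n_keyword_and_min: int
    min_terms: int
    ids_ge1: list[str] = field(default_factory=list)
    ids_ge_min: list[str] = field(default_factory=list)
    ids_keyword: list[str] = field(default_factory=list)
    ids_retained: list[str] = field(default_factory=list)


@dataclass
class CandidateTerm:
    """One candidate term with its acceptance decision.

    ``rejected_reason`` is ``None`` when accepted, else the first failing
    filter in the fixed priority order: ``below_min_count`` (total mentions,
    repeats included, under the cutoff), ``excluded_tag`` (uninformative
    ontology category), ``unit_slash`` (some surface form contains '/').
    """

    canonical: str
    total_count: int
    semantic_tag: str | None
    rejected_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejected_reason is None


def build_presence_matrix(
    corpus: Corpus,
    dictionary: TermDictionary,
    profile: MatchProfile | None = None,
) -> TermDocMatrix:
    """Binary terms x abstracts matrix: 1 if the term is present, 0 if absent.

    Rows are dictionary-driven, so a term matched nowhere keeps an all-zero
    row; synonyms are collapsed to canonical terms by the matcher.
    """
    matcher = compile_matcher(dictionary, profile)
    return match_corpus(matcher, corpus, mode="presence")


def filter_abstracts(
    term_matrix: TermDocMatrix,
    keyword_matrix: TermDocMatrix,
    min_terms: int = 2,
    require_keyword: bool = True,
    count_distinct: bool = True,
) -> FilterReport:
    """Select abstracts by distinct-term count and keyword presence.

    ``min_terms`` counts distinct canonical terms present by default; with
    ``count_distinct=False`` it counts total mentions instead (only
    meaningful on a count-mode matrix). Both matrices must cover the same
    abstracts in the same order.
    """
    if term_matrix.col_labels != keyword_matrix.col_labels:
        raise ValueError("term and keyword matrices cover different abstract columns")
    ids = np.asarray(term_matrix.col_labels)

    presence = term_matrix.binarize().values if count_distinct else term_matrix.values
    term_sums = np.asarray(presence.sum(axis=0)).ravel()
    kw_sums = np.asarray(keyword_matrix.binarize().values.sum(axis=0)).ravel()

    ge1 = term_sums >= 1
    ge_min = term_sums >= min_terms
    kw = kw_sums >= 1
    retained = (ge_min & kw) if require_keyword else ge_min

    return FilterReport(
        n_total=len(ids),
        n_ge1_terms=int(ge1.sum()),
        n_ge_min_terms=int(ge_min.sum()),
        n_keyword=int(kw.sum()),
        n_keyword_and_min=int((ge_min & kw).sum()),
        min_terms=min_terms,
        ids_ge1=list(ids[ge1]),
        ids_ge_min=list(ids[ge_min]),
        ids_keyword=list(ids[kw]),
        ids_retained=list(ids[retained]),
    )


def discover_candidates(
    corpus_subset: Corpus,
    big_dictionary: TermDictionary,
    min_count: int = 100,
    excluded_tags: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TAGS,
    profile: MatchProfile | None = None,
) -> list[CandidateTerm]:
    """Mine a selected sub-corpus for candidate terms from a large vocabulary.

    ``total_count`` sums every mention, including repeats within one
    abstract. Filters apply in the fixed order count -> tag -> slash, and
    every term carries either its acceptance or its first rejection reason,
    so accepted and rejected candidates partition the matched vocabulary.
    Terms never matched at all are omitted.
    """
    matcher = compile_matcher(big_dictionary, profile)
    counts = match_corpus(matcher, corpus_subset, mode="count")
    totals = np.asarray(counts.values.sum(axis=1)).ravel()

    excluded = {t.casefold() for t in excluded_tags}
    out: list[CandidateTerm] = []
    for term, total in zip(counts.row_labels, totals):
        if total == 0:
            continue
        entry = big_dictionary[term]
        tag = entry.semantic_tag
        reason: str | None = None
        if total < min_count:
            reason = "below_min_count"
        elif tag is not None and tag.casefold() in excluded:
            reason = "excluded_tag"
        elif any("/" in form for form in entry.surface_forms):
            reason = "unit_slash"
        out.append(CandidateTerm(term, int(total), tag, reason))
    return out
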