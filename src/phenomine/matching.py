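"""Dictionary-driven term matching and matcher evaluation.

Finds every dictionary surface form in an abstract, collapses synonyms to
their canonical term, and scores matcher output against gold annotations
with precision / recall / F1.

Matching semantics are held in a :class:`MatchProfile` so every choice is
explicit and overridable: case folding, word-boundary enforcement at
letter/digit boundaries, and suppression of surface forms fully nested
inside a longer match (partially overlapping distinct terms both count).
The engine is an Aho–Corasick automaton over all surface forms, so a pass
over the text is linear in its length regardless of dictionary size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus import Abstract, Corpus, TermDictionary, TermDocMatrix

__all__ = [
    "MatchProfile",
    "AbstractMatches",
    "PRFScore",
    "Matcher",
    "compile_matcher",
    "match_abstract",
    "score_matches",
]


@dataclass(frozen=True)
class MatchProfile:
    """Matching semantics; fully determines matcher output for a given text.

    case_fold
        Compare text and surface forms case-insensitively (default on).
    boundary_rule
        Require that matched spans are not flanked by letters or digits,
        so "dementia" does not fire inside "haemodementiaX" (default on).
    suppress_nested
        Longest-match-wins for fully nested spans: a shorter surface form
        strictly contained in a longer match at the same location is
        dropped; partially overlapping matches are all kept (default on).
    """

    case_fold: bool = True
    boundary_rule: bool = True
    suppress_nested: bool = True


@dataclass
class AbstractMatches:
    """Canonical-term occurrence counts for one abstract (counts >= 1)."""

    abstract_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.counts)


@dataclass(frozen=True)
class PRFScore:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


class _Node:
    __slots__ = ("goto", "fail", "out")

    def __init__(self) -> None:
        self.goto: dict[str, "_Node"] = {}
        self.fail: "_Node" | None = None
        self.out: list[tuple[int, str]] = []  # (pattern length, canonical)


class Matcher:
    """Compiled multi-pattern automaton; a pure function of the input text."""

    def __init__(self, dictionary: TermDictionary, profile: MatchProfile) -> None:
        if len(dictionary) == 0:
            raise ValueError("cannot compile a matcher from an empty dictionary")
        self.profile = profile
        self.dictionary = dictionary
        self._root = _Node()
        for entry in dictionary:
            for form in entry.surface_forms:
                pattern = form.casefold() if profile.case_fold else form
                node = self._root
                for ch in pattern:
                    node = node.goto.setdefault(ch, _Node())
                node.out.append((len(pattern), entry.canonical))
        # BFS failure links (classic Aho-Corasick construction)
        queue: deque[_Node] = deque()
        for child in self._root.goto.values():
            child.fail = self._root
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in node.goto.items():
                queue.append(child)
                f = node.fail
                while f is not None and ch not in f.goto:
                    f = f.fail
                child.fail = f.goto[ch] if f is not None and ch in f.goto else self._root
                child.out.extend(child.fail.out)

    def _raw_spans(self, text: str) -> list[tuple[int, int, str]]:
        """All automaton hits as (start, end, canonical), end exclusive."""
        spans: list[tuple[int, int, str]] = []
        node = self._root
        for i, ch in enumerate(text):
            while node is not self._root and ch not in node.goto:
                node = node.fail
            node = node.goto.get(ch, self._root)
            for length, canonical in node.out:
                spans.append((i - length + 1, i + 1, canonical))
        return spans

    def find(self, text: str) -> list[tuple[int, int, str]]:
        """Matched spans in ``text`` after boundary and nesting filters."""
        if self.profile.case_fold:
            text = text.casefold()
        spans = self._raw_spans(text)
        if self.profile.boundary_rule:
            spans = [
                (s, e, t)
                for (s, e, t) in spans
                if (s == 0 or not text[s - 1].isalnum())
                and (e == len(text) or not text[e].isalnum())
            ]
        if self.profile.suppress_nested and spans:
            # sort by start asc, length desc; drop spans strictly inside a kept
            # longer span
            spans.sort(key=lambda x: (x[0], -(x[1] - x[0])))
            kept: list[tuple[int, int, str]] = []
            for s, e, t in spans:
                nested = any(
                    ks <= s and e <= ke and (ke - ks) > (e - s) for ks, ke, _ in kept
                )
                if not nested:
                    kept.append((s, e, t))
            spans = kept
        return sorted(spans)


def compile_matcher(dictionary: TermDictionary, profile: MatchProfile | None = None) -> Matcher:
    return Matcher(dictionary, profile or MatchProfile())


def match_abstract(matcher: Matcher, abstract: Abstract) -> AbstractMatches:
    """Count occurrences of every canonical term in one abstract.

    Counts include repeated occurrences; downstream stages binarize where a
    presence/absence representation is required.
    """
    counts: dict[str, int] = {}
    for _, _, canonical in matcher.find(abstract.text):
        counts[canonical] = counts.get(canonical, 0) + 1
    return AbstractMatches(abstract.id, counts)


def match_corpus(
    matcher: Matcher, corpus: Corpus, mode: str = "count"
) -> TermDocMatrix:
    """Term-document matrix over a whole corpus.

    Rows are the matcher dictionary's canonical terms (all of them — terms
    matched nowhere keep an all-zero row), columns the corpus abstract ids,
    in corpus order.
    """
    import scipy.sparse as sp

    terms = matcher.dictionary.canonical_terms
    row_of = {t: i for i, t in enumerate(terms)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for j, abstract in enumerate(corpus):
        for term, n in match_abstract(matcher, abstract).counts.items():
            rows.append(row_of[term])
            cols.append(j)
            data.append(n if mode == "count" else 1)
    values = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(terms), len(corpus)), dtype=int
    )
    return TermDocMatrix(terms, corpus.ids, values, mode)


def score_matches(
    gold: Mapping[str, Iterable[str]],
    predicted: Mapping[str, AbstractMatches],
    average: str = "micro",
) -> PRFScore:
    """Precision / recall / F1 of predicted terms against gold annotations.

    Scoring is at (abstract, term) presence level: a term predicted in an
    abstract where the gold annotation lists it is one true positive,
    regardless of how many times either side counted it. ``average`` is
    ``"micro"`` (pool tp/fp/fn over abstracts; the default) or ``"macro"``
    (mean of per-abstract F1).
    """
    if set(gold) != set(predicted):
        raise ValueError("gold and predicted cover different abstract id sets")
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")

    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    TP = FP = FN = 0
    macro_f: list[float] = []
    for aid in gold:
        g = set(gold[aid])
        p = predicted[aid].terms
        tp, fp, fn = len(g & p), len(p - g), len(g - p)
        TP, FP, FN = TP + tp, FP + fp, FN + fn
        macro_f.append(_prf(tp, fp, fn)[2])
    prec, rec, f1 = _prf(TP, FP, FN)
    if average == "macro":
        f1 = float(sum(macro_f) / len(macro_f)) if macro_f else 0.0
    return PRFScore(prec, rec, f1, TP, FP, FN)
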