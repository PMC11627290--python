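"""Matrix normalization, hallmark attribution and term-frequency ranking.

Two normalizations of the binary term x abstract matrix are supported:

* a per-term standard score. The scheme ``"zscore_inverted"`` uses the sign
  convention (mean - x) / sd, i.e. the negation of the conventional
  (x - mean) / sd, which is kept as ``"zscore_conventional"``. Both use the
  population (ddof=0) standard deviation. Euclidean distances downstream
  are identical under either sign, but raw-vector methods (t-SNE, k-means
  on the vectors themselves) are not, which is why both schemes exist.
* tf-idf with the smoothed inverse document frequency
  ln((1 + N) / (1 + df)) + 1 applied to binary term frequencies, followed
  by L2-normalization of document columns (the scikit-learn
  ``TfidfTransformer`` defaults, which this wraps).

Hallmark attribution distributes each term's co-occurrence mass over a
small set of hallmark concepts in three steps: count abstracts containing
both the term and the hallmark, scale each hallmark column by its total
count (so heavily-studied hallmarks do not dominate), then rescale each
term row to percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfTransformer

from .corpus import Corpus, TermDictionary, TermDocMatrix
from .matching import MatchProfile
from .cooccur import build_presence_matrix

__all__ = [
    "NormalizedMatrix",
    "HallmarkContribution",
    "TermFrequencyTable",
    "zscore_normalize",
    "tfidf_normalize",
    "hallmark_contribution",
    "term_frequency_rank",
]


@dataclass
class NormalizedMatrix:
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    scheme: str
    flagged_rows: list[str] = field(default_factory=list)


@dataclass
class HallmarkContribution:
    """Terms x hallmarks percentage matrix; each defined row sums to 100."""

    table: pd.DataFrame  # rows: terms, columns: hallmarks, values: percent
    flagged_terms: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.table.index)

    @property
    def hallmarks(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class TermFrequencyTable:
    """Presence counts of terms in a chosen abstract subset, ranked."""

    table: pd.DataFrame  # columns: term, count; descending count, ties by label

    @property
    def summary(self) -> dict[str, float]:
        c = self.table["count"]
        return {"min": float(c.min()), "max": float(c.max()), "mean": float(c.mean())}


def zscore_normalize(matrix: TermDocMatrix, scheme: str = "zscore_inverted") -> NormalizedMatrix:
    """Row-wise standard scores of a term-document matrix.

    Every non-constant row ends up with mean 0 and population sd 1.
    Constant (zero-variance) rows carry no co-occurrence signal; they are
    flagged, zero-filled and reported in ``flagged_rows``.
    """
    if scheme not in ("zscore_inverted", "zscore_conventional"):
        raise ValueError(f"unknown z-score scheme {scheme!r}")
    X = np.asarray(matrix.values.todense(), dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    constant = sd.ravel() == 0
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    if scheme == "zscore_inverted":
        Z = -Z
    Z[constant, :] = 0.0
    flagged = [matrix.row_labels[i] for i in np.flatnonzero(constant)]
    if flagged:
        warnings.warn(
            f"{len(flagged)} constant term row(s) zero-filled: {flagged[:5]}...",
            stacklevel=2,
        )
    return NormalizedMatrix(
        list(matrix.row_labels), list(matrix.col_labels), Z, scheme, flagged
    )


def tfidf_normalize(
    matrix: TermDocMatrix,
    smooth_idf: bool = True,
    norm: str | None = "l2",
) -> NormalizedMatrix:
    """tf-idf weighting of a presence matrix with unit-norm document columns.

    With ``smooth_idf`` the weight of a term with document frequency df in
    an N-document corpus is ln((1 + N) / (1 + df)) + 1; columns are then
    scaled to unit Euclidean norm unless ``norm=None``.
    """
    presence = matrix.binarize()
    transformer = TfidfTransformer(norm=norm, smooth_idf=smooth_idf, sublinear_tf=False)
    # transformer works on documents x terms; our layout is terms x documents
    W = transformer.fit_transform(presence.values.T.tocsr()).T
    return NormalizedMatrix(
        list(matrix.row_labels),
        list(matrix.col_labels),
        np.asarray(W.todense(), dtype=float),
        "tfidf",
    )


def hallmark_contribution(
    corpus: Corpus,
    hallmark_dictionary: TermDictionary,
    phenome_dictionary: TermDictionary,
    profile: MatchProfile | None = None,
) -> HallmarkContribution:
    """Percentage contribution of each hallmark concept to each term.

    Three steps on the sub-corpus of abstracts mentioning at least one
    hallmark: (1) count, per (term, hallmark) pair, the abstracts containing
    both; (2) divide each hallmark column by its column total; (3) rescale
    each term row to percentages summing to 100. Terms co-occurring with no
    hallmark are flagged and left at zero.
    """
    hm = build_presence_matrix(corpus, hallmark_dictionary, profile)
    hm_pos = np.asarray(hm.values.sum(axis=0)).ravel() >= 1
    if not hm_pos.any():
        raise ValueError("no abstract mentions any hallmark concept")
    keep_ids = [cid for cid, pos in zip(hm.col_labels, hm_pos) if pos]
    sub = corpus.subset(keep_ids)

    H = build_presence_matrix(sub, hallmark_dictionary, profile).values.toarray()
    T = build_presence_matrix(sub, phenome_dictionary, profile).values.toarray()
    counts = T @ H.T  # terms x hallmarks co-occurrence (abstract-level)

    col_tot = counts.sum(axis=0, keepdims=True).astype(float)
    col_tot[col_tot == 0] = 1.0
    normed = counts / col_tot

    row_tot = normed.sum(axis=1, keepdims=True)
    flagged = [
        phenome_dictionary.canonical_terms[i]
        for i in np.flatnonzero(row_tot.ravel() == 0)
    ]
    row_tot[row_tot == 0] = 1.0
    pct = 100.0 * normed / row_tot

    table = pd.DataFrame(
        pct,
        index=phenome_dictionary.canonical_terms,
        columns=hallmark_dictionary.canonical_terms,
    )
    return HallmarkContribution(table, flagged)


def term_frequency_rank(
    term_matrix: TermDocMatrix, keyword_positive_ids: list[str]
) -> TermFrequencyTable:
    """Rank terms by the number of keyword-positive abstracts containing them.

    Presence-based (a term counts once per abstract however often it is
    mentioned); descending by count with a stable alphabetical tie-break.
    """
    cols = term_matrix.col_indices(keyword_positive_ids)
    presence = term_matrix.binarize().values
    if len(cols):
        counts = np.asarray(presence[:, cols].sum(axis=1)).ravel().astype(int)
    else:
        counts = np.zeros(presence.shape[0], dtype=int)
    df = pd.DataFrame({"term": term_matrix.row_labels, "count": counts})
    df = df.sort_values(["count", "term"], ascending=[False, True], kind="stable")
    return TermFrequencyTable(df.reset_index(drop=True))
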